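import numpy as np
import pandas as pd
import pytest

from cnvpop.core import GenomeLayout, GenotypeMatrix
from cnvpop.synthetic import PopulationModel


@pytest.fixture
def small_layout():
    return GenomeLayout(chromosomes=(("chr1", 2_000_000), ("chr2", 1_000_000)))


@pytest.fixture
def two_pop_model():
    return PopulationModel(populations=(("A", 20), ("B", 20)), fst_target=0.05)


def make_matrix(dosage_rows, populations, svtypes=None, chrom="chr1"):
    """GenotypeMatrix from a dict of variant -> dosage list and a
    sample -> population dict; variant intervals are synthetic."""
    samples = list(populations)
    ids = list(dosage_rows)
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "start": [1000 * (i + 1) for i in range(len(ids))],
            "end": [1000 * (i + 1) + 500 for i in range(len(ids))],
            "svtype": [svtypes[v] if svtypes else "DEL" for v in ids],
        },
        index=pd.Index(ids, name="variant"),
    )
    dosages = pd.DataFrame(
        [dosage_rows[v] for v in ids], index=variants.index, columns=samples, dtype=float
    )
    return GenotypeMatrix(variants, dosages, pd.Series(populations))


@pytest.fixture
def hwe_cohort():
    """Null cohort: 2 populations x 50 samples, 200 HWE variants, AF 0.1-0.9."""
    rng = np.random.default_rng(42)
    pops = {f"A_{i}": "A" for i in range(50)} | {f"B_{i}": "B" for i in range(50)}
    af = rng.uniform(0.1, 0.9, 200)
    rows = {f"v{i}": rng.binomial(2, af[i], 100).astype(float) for i in range(200)}
    return make_matrix(rows, pops)
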