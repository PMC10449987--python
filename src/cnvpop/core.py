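"""Core containers shared across the pipeline.

Coordinates are 0-based half-open throughout the package; conversion to
1-based inclusive happens only at VCF boundaries.  Genotypes are dosage
codes (count of non-reference alleles per diploid: 0, 1, 2), with NaN for
missing.  Copy number is an affine map of dosage: ``2 - dosage`` for
deletions, ``2 + dosage`` for duplications.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEL = "DEL"
DUP = "DUP"
SV_TYPES = (DEL, DUP)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent random substream for a named pipeline stage.

    Keyed by (stage name, master seed) so that adding or reordering stages
    does not perturb the streams of the others.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(stage.encode()),))
    )


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths (bp) of the working genome."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> np.ndarray:
        return np.asarray([length for _, length in self.chromosomes], dtype=np.int64)

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())


@dataclass
class CNVCall:
    """A single raw call from one caller on one sample."""

    chrom: str
    start: int
    end: int
    svtype: str
    genotype: float  # dosage 0/1/2, NaN = missing
    caller: str
    sample: str
    qual: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.svtype not in SV_TYPES:
            raise ValueError(f"svtype must be one of {SV_TYPES}, got {self.svtype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ConsensusVariant:
    """Cohort-level merged CNV with provenance and per-sample dosages."""

    vid: str
    chrom: str
    start: int
    end: int
    svtype: str
    members: list[CNVCall]
    genotypes: dict[str, float]  # sample -> dosage; absent samples are 0
    n_callers: dict[str, int] = field(default_factory=dict)  # sample -> caller support

    @property
    def length(self) -> int:
        return self.end - self.start


class GenotypeMatrix:
    """Variants x samples dosage matrix with population assignment.

    The substrate for every downstream statistic.  ``variants`` is a frame
    indexed by variant id with columns chrom/start/end/svtype; ``dosages``
    is a float frame (same index, one column per sample, NaN = missing);
    ``populations`` maps sample -> population label.
    """

    def __init__(self, variants: pd.DataFrame, dosages: pd.DataFrame, populations: pd.Series):
        if not variants.index.equals(dosages.index):
            raise ValueError("variant metadata and dosage rows disagree")
        missing = [s for s in dosages.columns if s not in populations.index]
        if missing:
            raise ValueError(f"samples without population assignment: {missing}")
        self.variants = variants
        self.dosages = dosages.astype(float)
        self.populations = populations.reindex(dosages.columns)

    # -- basic geometry -------------------------------------------------
    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    @property
    def samples(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        return list(self.populations.index[self.populations == population])

    # -- frequencies ----------------------------------------------------
    def allele_frequencies(self) -> pd.Series:
        """Cohort AF per variant: dosage sum / (2 x non-missing samples).

        Variants with no non-missing genotype get NaN.
        """
        d = self.dosages.to_numpy()
        called = np.sum(~np.isnan(d), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.nansum(d, axis=1) / (2.0 * called)
        af[called == 0] = np.nan
        return pd.Series(af, index=self.dosages.index, name="af")

    def population_allele_frequencies(self) -> pd.DataFrame:
        """Per-population AF per variant (columns = populations)."""
        cols = {}
        for pop in self.population_labels:
            sub = self.dosages[self.samples_of(pop)].to_numpy()
            called = np.sum(~np.isnan(sub), axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                af = np.nansum(sub, axis=1) / (2.0 * called)
            af[called == 0] = np.nan
            cols[pop] = af
        return pd.DataFrame(cols, index=self.dosages.index)

    # -- subsetting -----------------------------------------------------
    def subset_variants(self, ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.variants.loc[ids], self.dosages.loc[ids], self.populations)

    def subset_samples(self, samples) -> "GenotypeMatrix":
        samples = list(samples)
        return GenotypeMatrix(self.variants, self.dosages[samples], self.populations.loc[samples])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.variants.copy(), self.dosages.copy(), self.populations.copy())

    def __repr__(self) -> str:  # pragma: no cover
        pops = ",".join(self.population_labels)
        return f"<GenotypeMatrix {self.n_variants} variants x {self.n_samples} samples [{pops}]>"
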