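"""Population-genetic statistics on CNV dosage matrices.

Frequency classification and sharing apportionment, per-genome burden
summaries, Weir-Cockerham (1984) F_ST with locus-bootstrap p-values,
per-CNV V_ST in pairwise population comparisons, the top-quintile
extraction of highly differentiated variants, and the Pearson contingency
chi-squared used for the frequency-class and location tables.

V_ST compares copy-number variance directly: V_ST = (V_T - V_S)/V_T where
V_T is the pooled variance over both populations and V_S the sample-size
weighted mean of the within-population variances (denominator n).  Copy
number is an affine transform of dosage (2-dosage for deletions,
2+dosage for duplications), so dosage can be used unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix

FREQ_CLASSES = ("common", "low", "rare")


# ---------------------------------------------------------------------------
# allele frequencies and classes
# ---------------------------------------------------------------------------

def allele_frequency(dosages) -> float:
    """AF of one variant row: dosage sum over 2x non-missing count."""
    d = np.asarray(dosages, dtype=float)
    called = np.sum(~np.isnan(d))
    if called == 0:
        raise ValueError("all genotypes missing; AF undefined")
    return float(np.nansum(d) / (2.0 * called))


def classify_frequency(af: float) -> str:
    """Frequency class: common (AF > 0.05), low (0.01 <= AF <= 0.05), rare (< 0.01)."""
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"AF out of range: {af}")
    if af > 0.05:
        return "common"
    if af >= 0.01:
        return "low"
    return "rare"


def sharing_apportionment(matrix: GenotypeMatrix, af_mode: str = "cohort") -> pd.DataFrame:
    """Population sharing of each variant and the class x sharing cross-tab.

    A variant is present in a population when its AF there is > 0.  Returns
    a frame indexed by variant with columns ``af``, ``freq_class``,
    ``n_populations`` and one presence column per population; the
    cross-tab is available via :func:`sharing_crosstab`.  ``af_mode``
    chooses whether the class label uses the cohort-wide AF (default) or
    the maximum per-population AF.
    """
    if len(matrix.population_labels) < 2:
        raise ValueError("sharing apportionment needs >= 2 populations")
    pop_af = matrix.population_allele_frequencies()
    presence = pop_af > 0
    if af_mode == "cohort":
        af = matrix.allele_frequencies()
    elif af_mode == "max_population":
        af = pop_af.max(axis=1)
    else:
        raise ValueError(f"unknown af_mode {af_mode!r}")
    out = pd.DataFrame({"af": af})
    out["freq_class"] = [classify_frequency(a) if not np.isnan(a) else "unclassified"
                         for a in af]
    out["n_populations"] = presence.sum(axis=1)
    for pop in presence.columns:
        out[f"in_{pop}"] = presence[pop]
    return out


def sharing_crosstab(apportionment: pd.DataFrame) -> pd.DataFrame:
    """Cross-tab of frequency class x number of sharing populations."""
    tab = pd.crosstab(apportionment["freq_class"], apportionment["n_populations"])
    return tab.reindex([c for c in FREQ_CLASSES if c in tab.index])


def frequency_class_by_population(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-population counts of common/low/rare variants (Table-1 shape).

    Classes use each population's own AF; variants absent from a
    population (AF = 0 there) are not counted for it.
    """
    pop_af = matrix.population_allele_frequencies()
    rows = {}
    for pop in pop_af.columns:
        af = pop_af[pop]
        carried = af[af > 0]
        classes = pd.Series([classify_frequency(a) for a in carried], index=carried.index)
        counts = classes.value_counts()
        rows[pop] = [int(counts.get(c, 0)) for c in FREQ_CLASSES]
    return pd.DataFrame(rows, index=list(FREQ_CLASSES)).T


# ---------------------------------------------------------------------------
# per-genome burden
# ---------------------------------------------------------------------------

def per_genome_counts(
    matrix: GenotypeMatrix,
    variant_groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Carried-variant counts and lengths per sample.

    A sample carries a variant when its dosage is >= 1.  With
    ``variant_groups`` (a variant-indexed label series, e.g. svtype or
    genomic location), counts are reported per group.  Returns a frame
    indexed by sample with columns population, count / count_<group>, and
    total carried length (bp).
    """
    carried = matrix.dosages.to_numpy() >= 1
    lengths = (matrix.variants["end"] - matrix.variants["start"]).to_numpy()
    out = pd.DataFrame(index=pd.Index(matrix.samples, name="sample"))
    out["population"] = matrix.populations.to_numpy()
    out["count"] = carried.sum(axis=0)
    out["total_length"] = (carried * lengths[:, None]).sum(axis=0)
    if variant_groups is not None:
        groups = variant_groups.reindex(matrix.dosages.index)
        for g in groups.dropna().unique():
            mask = (groups == g).to_numpy()
            out[f"count_{g}"] = carried[mask].sum(axis=0)
    return out


def burden_summary(counts: pd.DataFrame, column: str = "count") -> pd.DataFrame:
    """Mean +/- SD of a per-genome burden column by population."""
    g = counts.groupby("population")[column]
    return pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.size()})


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    """Genome-wide Weir-Cockerham theta for one population pair."""

    pair: tuple[str, str]
    theta: float
    a: np.ndarray  # per-locus among-population variance component
    b: np.ndarray  # per-locus among-individual component
    c: np.ndarray  # per-locus within-individual component
    n_loci: int
    bootstrap_p: float | None = None
    n_boot: int = 0


def _wc_components(matrix: GenotypeMatrix, pops: tuple[str, str]):
    """Per-locus Weir-Cockerham (1984) variance components a, b, c.

    Computed from dosage genotypes (allele counts and observed
    heterozygote frequencies), pairwise-complete per locus.  Monomorphic
    loci yield a = b = c = 0 and contribute nothing to the ratio of sums.
    """
    r = len(pops)
    sub = [matrix.dosages[matrix.samples_of(p)].to_numpy() for p in pops]
    n_i = np.stack([np.sum(~np.isnan(s), axis=1) for s in sub])          # (r, L)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.stack([np.nansum(s, axis=1) for s in sub]) / (2.0 * n_i)  # (r, L)
        h_i = np.stack([np.sum(s == 1, axis=1) for s in sub]) / n_i        # (r, L)
    valid = np.all(n_i >= 2, axis=0)

    n_bar = n_i.mean(axis=0)
    n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
    poly = valid & (p_bar > 0) & (p_bar < 1)
    a = np.where(poly, a, 0.0)
    b = np.where(poly, b, 0.0)
    c = np.where(poly, c, 0.0)
    return a, b, c, poly


def weir_cockerham_fst(matrix: GenotypeMatrix, pair: tuple[str, str]) -> FstResult:
    """Genome-wide Weir-Cockerham theta as the ratio of summed components."""
    for p in pair:
        if len(matrix.samples_of(p)) < 2:
            raise ValueError(f"population {p!r} needs >= 2 samples")
    a, b, c, poly = _wc_components(matrix, pair)
    denom = (a + b + c).sum()
    if not poly.any() or denom == 0:
        raise ValueError("no polymorphic loci; F_ST undefined")
    return FstResult(pair=tuple(pair), theta=float(a.sum() / denom),
                     a=a, b=b, c=c, n_loci=int(poly.sum()))


def bootstrap_fst_p(
    matrix: GenotypeMatrix,
    pair: tuple[str, str],
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
) -> FstResult:
    """Locus-bootstrap p-value for theta > 0.

    Loci are resampled with replacement ``n_boot`` times; p is the
    fraction of bootstrap thetas <= 0, floored at 1/(n_boot + 1).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if matrix.n_variants < 2:
        raise ValueError("bootstrap needs >= 2 loci")
    rng = rng or np.random.default_rng()
    res = weir_cockerham_fst(matrix, pair)
    abc = res.a + res.b + res.c
    L = len(res.a)
    idx = rng.integers(0, L, size=(n_boot, L))
    num = res.a[idx].sum(axis=1)
    den = abc[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        thetas = num / den
    n_nonpos = int(np.sum(thetas[den != 0] <= 0) + np.sum(den == 0))
    res.bootstrap_p = max(n_nonpos / n_boot, 1.0 / (n_boot + 1))
    res.n_boot = n_boot
    return res


def pairwise_fst(
    matrix: GenotypeMatrix,
    n_boot: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Theta (and bootstrap p when requested) for every population pair."""
    rows = []
    for pa, pb in combinations(matrix.population_labels, 2):
        if n_boot:
            res = bootstrap_fst_p(matrix, (pa, pb), n_boot=n_boot, rng=rng)
        else:
            res = weir_cockerham_fst(matrix, (pa, pb))
        rows.append({"pop_a": pa, "pop_b": pb, "fst": res.theta,
                     "bootstrap_p": res.bootstrap_p, "n_loci": res.n_loci})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# V_ST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VstResult:
    """Per-variant differentiation from copy-number variances."""

    variant: str
    pair: tuple[str, str]
    v_total: float
    v_within: float
    vst: float | None  # None when V_T = 0


def vst_from_values(values_a: np.ndarray, values_b: np.ndarray):
    """V_T, V_S and V_ST from two populations' copy-number values.

    Variances use denominator n (population variance), so identical groups
    give exactly 0; V_S weights the within-population variances by sample
    size.  V_T = 0 leaves V_ST undefined (None).
    """
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    va, vb = va[~np.isnan(va)], vb[~np.isnan(vb)]
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("each population needs >= 2 non-missing values")
    pooled = np.concatenate([va, vb])
    v_t = float(np.var(pooled))
    v_s = float((len(va) * np.var(va) + len(vb) * np.var(vb)) / (len(va) + len(vb)))
    vst = None if v_t == 0.0 else (v_t - v_s) / v_t
    return v_t, v_s, vst


def vst(
    matrix: GenotypeMatrix, variant: str, pair: tuple[str, str]
) -> VstResult:
    """V_ST of one variant for one population pair (dosage scale)."""
    row = matrix.dosages.loc[variant]
    va = row[matrix.samples_of(pair[0])].to_numpy()
    vb = row[matrix.samples_of(pair[1])].to_numpy()
    v_t, v_s, value = vst_from_values(va, vb)
    return VstResult(variant=variant, pair=tuple(pair), v_total=v_t,
                     v_within=v_s, vst=value)


def pairwise_vst(matrix: GenotypeMatrix) -> pd.DataFrame:
    """V_ST of every variant for every population pair (long format).

    Vectorised over variants; undefined values (V_T = 0) are NaN and are
    excluded from any downstream averaging.
    """
    frames = []
    for pa, pb in combinations(matrix.population_labels, 2):
        da = matrix.dosages[matrix.samples_of(pa)].to_numpy()
        db = matrix.dosages[matrix.samples_of(pb)].to_numpy()
        na = np.sum(~np.isnan(da), axis=1)
        nb = np.sum(~np.isnan(db), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            var_a = np.nanvar(da, axis=1)
            var_b = np.nanvar(db, axis=1)
            mean_a = np.nanmean(da, axis=1)
            mean_b = np.nanmean(db, axis=1)
        n = na + nb
        # pooled variance via the within/between decomposition
        grand = (na * mean_a + nb * mean_b) / n
        v_s = (na * var_a + nb * var_b) / n
        v_t = v_s + (na * (mean_a - grand) ** 2 + nb * (mean_b - grand) ** 2) / n
        with np.errstate(invalid="ignore", divide="ignore"):
            v = (v_t - v_s) / v_t
        v = np.where((v_t == 0) | (na < 2) | (nb < 2), np.nan, v)
        frames.append(pd.DataFrame({
            "variant": matrix.dosages.index, "pop_a": pa, "pop_b": pb,
            "v_total": v_t, "v_within": v_s, "vst": v,
        }))
    return pd.concat(frames, ignore_index=True)


def top_quintile(vst_table: pd.DataFrame, q: float = 80.0) -> pd.DataFrame:
    """Per population pair, the variants at or above the 80th V_ST percentile.

    The percentile uses linear interpolation between order statistics;
    ties at the boundary are all included.  Pairs with fewer than five
    defined values produce a warning and contribute nothing.
    """
    out = []
    for (pa, pb), group in vst_table.groupby(["pop_a", "pop_b"], sort=False):
        defined = group.dropna(subset=["vst"])
        if len(defined) < 5:
            warnings.warn(f"pair ({pa}, {pb}) has < 5 defined V_ST values; skipped")
            continue
        boundary = np.percentile(defined["vst"], q, method="linear")
        out.append(defined[defined["vst"] >= boundary])
    if not out:
        return vst_table.iloc[0:0]
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# contingency chi-squared
# ---------------------------------------------------------------------------

def contingency_chi_squared(table) -> tuple[float, int, float]:
    """Pearson chi-squared of independence on an r x c count table.

    Expected counts are row x column margins over the total; degrees of
    freedom (r-1)(c-1); no continuity correction.  Zero margins are an
    input error.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)
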