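"""Post-merge variant filtering ladder.

Stage order mirrors the analysis narrative: genotype-quality masking, then
SNP-evidence false-positive detection, then a per-population
Hardy-Weinberg chi-squared filter with Bonferroni correction, with a
minor-allele-frequency pre-filter applied where an analysis requires it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import DEL, DUP, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HWETestResult:
    """One Hardy-Weinberg chi-squared test (df=1, no continuity correction)."""

    chi2: float
    p: float
    counts: tuple[int, int, int]
    df: int = 1


@dataclass
class FilterReport:
    """Per-stage accounting of variants entering, removed and retained."""

    stages: list[dict] = field(default_factory=list)
    reasons: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, n_in: int, removed_ids: list[str], reason: str) -> None:
        self.stages.append(
            {"stage": stage, "input": n_in, "removed": len(removed_ids),
             "retained": n_in - len(removed_ids)}
        )
        for vid in removed_ids:
            self.reasons.setdefault(vid, reason)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "input", "removed", "retained"])

    def check_conservation(self) -> bool:
        return all(s["input"] == s["removed"] + s["retained"] for s in self.stages)


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def hwe_test(n0: int, n1: int, n2: int) -> HWETestResult:
    """Pearson chi-squared test of Hardy-Weinberg proportions.

    Genotype counts (n0, n1, n2) for dosages 0/1/2; the allele frequency is
    estimated from the counts, expected counts are (n q^2, 2 n p q, n p^2),
    and the statistic has one degree of freedom.  Monomorphic input returns
    chi2=0, p=1.
    """
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("need at least one genotype")
    p_hat = (n1 + 2 * n2) / (2 * n)
    if p_hat <= 0.0 or p_hat >= 1.0:
        return HWETestResult(chi2=0.0, p=1.0, counts=(n0, n1, n2))
    q_hat = 1.0 - p_hat
    expected = np.array([n * q_hat**2, 2 * n * p_hat * q_hat, n * p_hat**2])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return HWETestResult(chi2=chi2, p=p, counts=(n0, n1, n2))


def hwe_test_matrix(matrix: GenotypeMatrix) -> pd.DataFrame:
    """HWE chi-squared per (variant, population).

    Long-format frame with columns variant, population, n0, n1, n2, chi2,
    p, polymorphic.  Vectorised over variants within each population.
    """
    rows = []
    for pop in matrix.population_labels:
        sub = matrix.dosages[matrix.samples_of(pop)].to_numpy()
        n0 = np.sum(sub == 0, axis=1)
        n1 = np.sum(sub == 1, axis=1)
        n2 = np.sum(sub == 2, axis=1)
        n = n0 + n1 + n2
        with np.errstate(invalid="ignore", divide="ignore"):
            p_hat = (n1 + 2 * n2) / (2 * np.maximum(n, 1))
            q_hat = 1.0 - p_hat
            e0 = n * q_hat**2
            e1 = 2 * n * p_hat * q_hat
            e2 = n * p_hat**2
            chi2 = ((n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2)
        poly = (p_hat > 0) & (p_hat < 1) & (n > 0)
        chi2 = np.where(poly, chi2, 0.0)
        pvals = np.where(poly, stats.chi2.sf(chi2, df=1), 1.0)
        rows.append(pd.DataFrame({
            "variant": matrix.dosages.index, "population": pop,
            "n0": n0, "n1": n1, "n2": n2, "chi2": chi2, "p": pvals,
            "polymorphic": poly,
        }))
    return pd.concat(rows, ignore_index=True)


def hwe_filter(
    matrix: GenotypeMatrix,
    alpha: float = 0.05,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove variants out of Hardy-Weinberg equilibrium in any population.

    The test runs per (variant, population); within each population the
    Bonferroni threshold is ``alpha`` divided by the number of polymorphic
    variants tested there, and a variant is removed if it is significant in
    any population.
    """
    report = report or FilterReport()
    for pop in matrix.population_labels:
        if len(matrix.samples_of(pop)) < 5:
            warnings.warn(f"population {pop!r} has < 5 samples; HWE test is weak")
    tests = hwe_test_matrix(matrix)
    removed: set[str] = set()
    for pop, group in tests.groupby("population", sort=False):
        m = int(group["polymorphic"].sum())
        if m == 0:
            continue
        bad = group.loc[group["polymorphic"] & (group["p"] < alpha / m), "variant"]
        removed.update(bad)
    keep = [v for v in matrix.dosages.index if v not in removed]
    report.record("hwe", matrix.n_variants, sorted(removed), "HWE violation (Bonferroni)")
    return matrix.subset_variants(keep), report


# ---------------------------------------------------------------------------
# genotype quality
# ---------------------------------------------------------------------------

def genotype_quality_filter(
    matrix: GenotypeMatrix,
    member_quals: dict[tuple[str, str], dict[str, float]],
    thresholds: dict[str, float],
    min_call_rate: float = 0.0,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Mask genotypes whose member-call quality fields violate thresholds.

    ``member_quals`` maps (variant id, sample) to that call's quality
    fields; ``thresholds`` maps a field name to its minimum acceptable
    value.  A genotype becomes missing when any named field falls below its
    bound; variants whose call rate then drops below ``min_call_rate`` are
    removed.
    """
    report = report or FilterReport()
    out = matrix.copy()
    if thresholds:
        known = {name for q in member_quals.values() for name in q}
        unknown = set(thresholds) - known
        if member_quals and unknown:
            raise ValueError(f"threshold on unknown quality field(s): {sorted(unknown)}")
        for (vid, sample), qual in member_quals.items():
            if vid not in out.dosages.index or sample not in out.dosages.columns:
                continue
            for name, bound in thresholds.items():
                if name in qual and qual[name] < bound:
                    out.dosages.loc[vid, sample] = np.nan
                    break
    call_rate = out.dosages.notna().mean(axis=1)
    removed = list(out.dosages.index[call_rate < min_call_rate])
    keep = [v for v in out.dosages.index if v not in set(removed)]
    report.record("genotype_quality", out.n_variants, removed,
                  f"call rate < {min_call_rate}")
    return out.subset_variants(keep), report


# ---------------------------------------------------------------------------
# SNP-evidence false-positive detection
# ---------------------------------------------------------------------------

#: allele-balance values consistent with a heterozygous CNV, by type:
#: one-copy regions (het DEL) show hom-like SNP balances; three-copy
#: regions (het DUP) show 1/3 or 2/3.
_CONSISTENT_BALANCE = {DEL: (0.0, 1.0), DUP: (1 / 3, 2 / 3)}
_NO_CNV_BALANCE = 0.5


def snp_consistency_votes(
    svtype: str,
    balances: np.ndarray,
    tolerance: float = 0.15,
) -> tuple[int, int]:
    """Count SNPs supporting vs discarding a heterozygous CNV genotype.

    Each heterozygous SNP inside the variant votes "supporting" when its
    alt-allele balance lies within ``tolerance`` of a CNV-consistent value,
    else "discarding".
    """
    consistent = _CONSISTENT_BALANCE[svtype]
    supporting = discarding = 0
    for b in np.asarray(balances, dtype=float):
        if min(abs(b - v) for v in consistent) <= tolerance:
            supporting += 1
        else:
            discarding += 1
    return supporting, discarding


def snp_consistency_filter(
    matrix: GenotypeMatrix,
    snp_depths: dict[tuple[str, str], list[tuple[float, float]]],
    tolerance: float = 0.15,
    min_snps: int = 2,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, FilterReport]:
    """Flag false-positive heterozygous CNV genotypes from internal SNPs.

    ``snp_depths`` maps (variant id, sample) to (ref_depth, alt_depth)
    pairs of heterozygous SNPs mapping inside the variant.  Only
    heterozygous CNV genotypes are evaluated; a genotype is flagged false
    positive (set to missing) when discarding votes outnumber supporting
    votes over at least ``min_snps`` SNPs.  Returns the masked matrix, a
    verdict table (variant, sample, supporting, discarding, verdict) and
    the report.
    """
    report = report or FilterReport()
    out = matrix.copy()
    rows = []
    n_flagged = 0
    for (vid, sample), depths in snp_depths.items():
        if vid not in out.dosages.index or sample not in out.dosages.columns:
            continue
        if out.dosages.loc[vid, sample] != 1.0:
            continue  # only heterozygous genotypes are testable
        svtype = out.variants.loc[vid, "svtype"]
        if len(depths) < min_snps:
            rows.append((vid, sample, 0, 0, "uninformative"))
            continue
        depth_arr = np.asarray(depths, dtype=float)
        totals = depth_arr.sum(axis=1)
        balances = np.divide(depth_arr[:, 1], totals, out=np.full(len(totals), np.nan),
                             where=totals > 0)
        balances = balances[~np.isnan(balances)]
        supporting, discarding = snp_consistency_votes(svtype, balances, tolerance)
        if discarding > supporting:
            verdict = "false_positive"
            out.dosages.loc[vid, sample] = np.nan
            n_flagged += 1
        else:
            verdict = "keep"
        rows.append((vid, sample, supporting, discarding, verdict))
    verdicts = pd.DataFrame(
        rows, columns=["variant", "sample", "supporting", "discarding", "verdict"]
    )
    report.record("snp_consistency", matrix.n_variants, [], "")
    log.info("snp_consistency_filter flagged %d heterozygous genotypes", n_flagged)
    return out, verdicts, report


# ---------------------------------------------------------------------------
# minor allele frequency
# ---------------------------------------------------------------------------

def maf_filter(
    matrix: GenotypeMatrix,
    min_maf: float = 0.01,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop variants with minor allele frequency below ``min_maf`` (strict)."""
    report = report or FilterReport()
    af = matrix.allele_frequencies()
    maf = np.minimum(af, 1.0 - af)
    removed = list(matrix.dosages.index[(maf < min_maf) | af.isna()])
    keep = [v for v in matrix.dosages.index if v not in set(removed)]
    report.record("maf", matrix.n_variants, removed, f"MAF < {min_maf}")
    return matrix.subset_variants(keep), report
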