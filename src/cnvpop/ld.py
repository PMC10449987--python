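"""LD-proxy linkage of CNVs to trait-associated SNPs.

After standard SNP QC (sample missingness, SNP missingness, MAF, HWE),
each trait-catalog SNP is tested against every CNV whose nearest
breakpoint lies within a window of the SNP (default 1 Mb); pairs with
squared genotype correlation above the threshold (default r^2 > 0.8) are
emitted as linkage records, then summarized by genomic context and
proximity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import LocationCall
from .core import GenotypeMatrix
from .filters import FilterReport, hwe_test

log = logging.getLogger(__name__)


@dataclass
class LinkageRecord:
    cnv: str
    snp: str
    traits: tuple[str, ...]
    r2: float
    distance: int  # bp from SNP to nearest CNV breakpoint; 0 when inside
    category: str = ""  # CNV genomic location category
    shared_gene: bool = False
    haplotype_based: bool = False


# ---------------------------------------------------------------------------
# SNP QC
# ---------------------------------------------------------------------------

def snp_qc(
    snps: GenotypeMatrix,
    max_sample_missing: float = 0.1,
    max_snp_missing: float = 0.1,
    min_maf: float = 0.01,
    hwe_alpha: float = 0.001,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Standard SNP quality control, samples first then SNPs.

    Removes samples with missing genotype rate > ``max_sample_missing``,
    then SNPs with missing call rate > ``max_snp_missing``, MAF below
    ``min_maf`` (strict) or a Hardy-Weinberg chi-squared p-value below
    ``hwe_alpha`` on the pooled cohort.
    """
    report = FilterReport()
    sample_missing = snps.dosages.isna().mean(axis=0)
    keep_samples = list(sample_missing.index[sample_missing <= max_sample_missing])
    if not keep_samples:
        raise ValueError("SNP QC removed every sample")
    out = snps.subset_samples(keep_samples)

    snp_missing = out.dosages.isna().mean(axis=1)
    removed_missing = set(out.dosages.index[snp_missing > max_snp_missing])

    af = out.allele_frequencies()
    maf = np.minimum(af, 1 - af)
    removed_maf = set(out.dosages.index[(maf < min_maf) | af.isna()]) - removed_missing

    removed_hwe = set()
    for vid in out.dosages.index:
        if vid in removed_missing or vid in removed_maf:
            continue
        d = out.dosages.loc[vid]
        res = hwe_test(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))
        if res.p < hwe_alpha:
            removed_hwe.add(vid)

    n0 = out.n_variants
    report.record("snp_missing", n0, sorted(removed_missing),
                  f"missing call rate > {max_snp_missing}")
    report.record("snp_maf", n0 - len(removed_missing), sorted(removed_maf),
                  f"MAF < {min_maf}")
    report.record("snp_hwe", n0 - len(removed_missing) - len(removed_maf),
                  sorted(removed_hwe), f"HWE p < {hwe_alpha}")
    removed = removed_missing | removed_maf | removed_hwe
    keep = [v for v in out.dosages.index if v not in removed]
    return out.subset_variants(keep), report


# ---------------------------------------------------------------------------
# r-squared
# ---------------------------------------------------------------------------

def genotype_r2(vec_a, vec_b) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete entries; either vector constant on the
    joint support makes r^2 undefined (ValueError).  Symmetric, and
    invariant to allele relabeling (x -> 2 - x).
    """
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if len(a) < 2:
        raise ValueError("need >= 2 pairwise-complete samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant vector; r^2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def haplotype_r2(hap_a, hap_b) -> float:
    """r^2 on phased allele vectors (one entry per haplotype)."""
    return genotype_r2(hap_a, hap_b)


# ---------------------------------------------------------------------------
# linkage
# ---------------------------------------------------------------------------

def _edge_distance(pos: int, start: int, end: int) -> int:
    """bp from a point to the nearest edge of [start, end); 0 when inside."""
    if start <= pos < end:
        return 0
    return start - pos if pos < start else pos - end + 1


def link_cnvs_to_trait_snps(
    cnvs: GenotypeMatrix,
    snps: GenotypeMatrix,
    trait_table: pd.DataFrame,
    r2_min: float = 0.8,
    window: int = 1_000_000,
) -> list[LinkageRecord]:
    """Trait-SNP tagging of CNVs by r^2 and window criteria.

    Candidate pairs are (CNV, trait SNP) on the same chromosome with
    nearest-breakpoint distance <= ``window`` (inclusive, anchored on the
    SNP); a record is emitted iff genotype r^2 > ``r2_min`` (strict).  One
    record per (CNV, SNP) with all of the SNP's traits aggregated.
    """
    shared = [s for s in cnvs.samples if s in set(snps.samples)]
    if not shared:
        raise ValueError("no shared samples between CNV and SNP matrices")
    cnv_d = cnvs.dosages[shared]
    snp_d = snps.dosages[shared]

    traits_of: dict[str, list[str]] = {}
    snp_pos: dict[str, tuple[str, int]] = {}
    for _, row in trait_table.iterrows():
        traits_of.setdefault(row["snp_id"], []).append(row["trait"])
        snp_pos[row["snp_id"]] = (row["chrom"], int(row["pos"]))

    records: list[LinkageRecord] = []
    meta = cnvs.variants
    for snp_id, (chrom, pos) in snp_pos.items():
        if snp_id not in snp_d.index:
            continue
        on_chrom = meta.index[meta["chrom"] == chrom]
        for vid in on_chrom:
            start, end = int(meta.loc[vid, "start"]), int(meta.loc[vid, "end"])
            dist = _edge_distance(pos, start, end)
            if dist > window:
                continue
            try:
                r2 = genotype_r2(cnv_d.loc[vid], snp_d.loc[snp_id])
            except ValueError:
                log.debug("skipping constant pair (%s, %s)", vid, snp_id)
                continue
            if r2 > r2_min:
                records.append(LinkageRecord(
                    cnv=vid, snp=snp_id, traits=tuple(sorted(set(traits_of[snp_id]))),
                    r2=r2, distance=dist,
                ))
    return records


def annotate_linkage(
    records: list[LinkageRecord],
    location_calls: dict[str, LocationCall],
    snp_genes: dict[str, str] | None = None,
) -> list[LinkageRecord]:
    """Attach location category and shared-gene flags to linkage records."""
    for rec in records:
        call = location_calls.get(rec.cnv)
        if call is not None:
            rec.category = call.category
            if snp_genes and rec.snp in snp_genes:
                rec.shared_gene = snp_genes[rec.snp] in call.genes
    return records


@dataclass
class ProximitySummary:
    n_records: int
    n_unique_cnvs: int
    n_unique_snps: int
    by_category: dict[str, int] = field(default_factory=dict)
    distance_quantiles: dict[str, float] = field(default_factory=dict)
    shared_gene_count: int = 0
    near: list[LinkageRecord] = field(default_factory=list)  # within near_bp of a SNP


def proximity_summary(records: list[LinkageRecord], near_bp: int = 5000) -> ProximitySummary:
    """Deterministic tabulation of linkage records by context and distance."""
    if not records:
        return ProximitySummary(0, 0, 0)
    by_cat: dict[str, int] = {}
    for rec in records:
        by_cat[rec.category or "unknown"] = by_cat.get(rec.category or "unknown", 0) + 1
    dists = np.asarray([r.distance for r in records], dtype=float)
    quantiles = {
        "min": float(dists.min()),
        "q25": float(np.percentile(dists, 25)),
        "median": float(np.percentile(dists, 50)),
        "q75": float(np.percentile(dists, 75)),
        "max": float(dists.max()),
    }
    return ProximitySummary(
        n_records=len(records),
        n_unique_cnvs=len({r.cnv for r in records}),
        n_unique_snps=len({r.snp for r in records}),
        by_category=by_cat,
        distance_quantiles=quantiles,
        shared_gene_count=sum(r.shared_gene for r in records),
        near=[r for r in records if r.distance <= near_bp],
    )


def records_to_frame(records: list[LinkageRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"cnv": r.cnv, "snp": r.snp, "traits": ";".join(r.traits), "r2": r.r2,
             "distance": r.distance, "category": r.category,
             "shared_gene": r.shared_gene}
            for r in records
        ],
        columns=["cnv", "snp", "traits", "r2", "distance", "category", "shared_gene"],
    )
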