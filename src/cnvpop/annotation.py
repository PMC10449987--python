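"""Genomic annotation of CNVs against a gene model.

Classifies each variant as exonic, intronic, intergenic or multigene
(any exon overlap of >= 1 bp dominates intron; gene overlap dominates
intergenic), joins gene-level LoF-intolerance (LOEUF bins 0-9, <= 4 =
intolerant, > 4 or unscored = tolerant) and disease flags, and extracts
merged intron interval sets for region-permutation testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

LOEUF_INTOLERANT_MAX = 4  # LOEUF bin <= 4 -> LoF intolerant
CATEGORIES = ("exonic", "intronic", "intergenic", "multigene")

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    """A gene span with ordered disjoint exon blocks and gene-level scores."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    loeuf_bin: object = pd.NA  # int 0-9 or pandas NA (unscored)
    disease_flag: bool = False

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev_end = self.start
        for s, e in self.exons:
            if s < prev_end or e > self.end or s >= e:
                raise ValueError(f"gene {self.gene_id}: exons must be ordered, "
                                 "disjoint and within the gene span")
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gene span minus exons (may be empty for single-exon genes)."""
        out = []
        prev_end = self.exons[0][1]
        for s, e in self.exons[1:]:
            if s > prev_end:
                out.append((prev_end, s))
            prev_end = e
        return tuple(out)

    @property
    def intolerant(self) -> bool:
        """LoF intolerant iff a LOEUF bin is on record and <= 4."""
        return not pd.isna(self.loeuf_bin) and int(self.loeuf_bin) <= LOEUF_INTOLERANT_MAX


class GenomeAnnotation:
    """Gene model with interval indices for location queries."""

    def __init__(self, genes: list[GeneRecord]):
        self.genes = {g.gene_id: g for g in genes}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[GeneRecord]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(start, end), key=lambda iv: (iv.begin, iv.end))
        return [self.genes[iv.data] for iv in hits]

    def __len__(self) -> int:
        return len(self.genes)

    # -- scores ---------------------------------------------------------
    def apply_scores(self, scores: pd.DataFrame) -> None:
        """Attach loeuf_bin / disease_flag columns from a gene-keyed table.

        Genes absent from the table keep a missing bin (hence the
        LoF-tolerant class) and are logged once each.
        """
        import dataclasses

        for gid, g in list(self.genes.items()):
            if gid in scores.index:
                row = scores.loc[gid]
                bin_val = row.get("loeuf_bin", pd.NA)
                bin_val = pd.NA if pd.isna(bin_val) else int(bin_val)
                self.genes[gid] = dataclasses.replace(
                    g, loeuf_bin=bin_val, disease_flag=bool(row.get("disease_flag", False))
                )
            else:
                log.info("gene %s absent from score table; treated as unscored", gid)
                self.genes[gid] = dataclasses.replace(
                    g, loeuf_bin=pd.NA, disease_flag=False)
        # trees store ids only; records are looked up live, no rebuild needed


@dataclass
class LocationCall:
    """Genomic-location classification of one variant."""

    variant: str
    category: str  # exonic / intronic / intergenic / multigene
    genes: list[str]
    sub_calls: dict[str, str]  # gene id -> "exon" | "intron"
    intolerant: bool = False
    disease_flag: bool = False
    loeuf_bins: tuple = ()


def classify_location(
    variant: str, chrom: str, start: int, end: int, annotation: GenomeAnnotation
) -> LocationCall:
    """Exonic / intronic / intergenic / multigene call for one interval.

    Intergenic iff no gene span is overlapped; with exactly one gene, any
    >= 1 bp exon overlap makes the call exonic, else intronic; with more
    than one gene the category is multigene and each gene gets its own
    exon/intron sub-call.
    """
    hits = annotation.genes_overlapping(chrom, start, end)
    if not hits:
        return LocationCall(variant, "intergenic", [], {})
    sub_calls = {}
    for g in hits:
        exon_hit = any(s < end and start < e for s, e in g.exons)
        sub_calls[g.gene_id] = "exon" if exon_hit else "intron"
    category = ("exonic" if sub_calls[hits[0].gene_id] == "exon" else "intronic") \
        if len(hits) == 1 else "multigene"
    return LocationCall(variant, category, [g.gene_id for g in hits], sub_calls)


def classify_variants(variants: pd.DataFrame, annotation: GenomeAnnotation) -> list[LocationCall]:
    """Location calls for a variant metadata frame (chrom/start/end columns)."""
    return [
        classify_location(vid, row["chrom"], int(row["start"]), int(row["end"]), annotation)
        for vid, row in variants.iterrows()
    ]


def assign_gene_scores(
    calls: list[LocationCall], annotation: GenomeAnnotation
) -> list[LocationCall]:
    """Fill intolerance class, disease flag and LOEUF bins on location calls.

    A variant is LoF-intolerant when any hit gene has LOEUF bin <= 4;
    genes without a bin count as tolerant; the disease flag is true when
    any hit gene is flagged.
    """
    for call in calls:
        genes = [annotation.genes[g] for g in call.genes]
        call.intolerant = any(g.intolerant for g in genes)
        call.disease_flag = any(g.disease_flag for g in genes)
        call.loeuf_bins = tuple(g.loeuf_bin for g in genes)
    return calls


def location_table(calls: list[LocationCall]) -> pd.Series:
    """Counts of the four raw categories (exonic/intronic/intergenic/multigene)."""
    counts = pd.Series(0, index=list(CATEGORIES))
    for c in calls:
        counts[c.category] += 1
    return counts


def fold_multigene(call: LocationCall) -> str:
    """Collapse a multigene call by exon dominance: any exon hit -> exonic."""
    if call.category != "multigene":
        return call.category
    return "exonic" if "exon" in call.sub_calls.values() else "intronic"


def location_type_table(
    calls: list[LocationCall],
    svtypes: pd.Series,
    fold: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Type x location count table with row percentages (Table-2 shape).

    Rows DEL/DUP, columns exonic/intronic/intergenic; multigene variants
    are folded by exon dominance when ``fold`` is true, else excluded.
    Percentages are cell over row total at one decimal place.
    """
    cols = ["exonic", "intronic", "intergenic"]
    counts = pd.DataFrame(0, index=["DEL", "DUP"], columns=cols)
    for call in calls:
        cat = fold_multigene(call) if fold else call.category
        if cat not in cols:
            continue
        counts.loc[svtypes[call.variant], cat] += 1
    totals = counts.sum(axis=1)
    pct = counts.div(totals.where(totals > 0), axis=0) * 100.0
    return counts, pct.round(1)


def table_percentages(counts) -> pd.DataFrame:
    """Row percentages (1 d.p.) of an arbitrary count table."""
    t = pd.DataFrame(counts, dtype=float)
    return (t.div(t.sum(axis=1), axis=0) * 100.0).round(1)


def extract_intron_intervals(
    annotation: GenomeAnnotation, intolerant: bool
) -> dict[str, list[tuple[int, int]]]:
    """Merged, sorted intron intervals of one LoF class, per chromosome.

    ``intolerant=True`` selects genes with LOEUF bin <= 4; ``False``
    selects bins > 4 or unscored genes.  Overlapping or abutting intervals
    are merged.
    """
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in annotation.genes.values():
        if g.intolerant != intolerant:
            continue
        per_chrom.setdefault(g.chrom, []).extend(g.introns)
    return {chrom: merge_intervals(ivs) for chrom, ivs in per_chrom.items() if ivs}


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting half-open intervals; result sorted."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
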