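"""File-format boundaries.

Internal coordinates are 0-based half-open; VCF output converts to
1-based inclusive with an END INFO key.  TSV call files carry the columns
chrom, start, end, svtype, genotype, qual, sample, caller.  Gene models
round-trip through BED12 (blocks = exons).  SNP VCFs are read through
pysam.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneRecord, GenomeAnnotation
from .core import CNVCall, ConsensusVariant, GenotypeMatrix

CALL_COLUMNS = ["chrom", "start", "end", "svtype", "genotype", "qual", "sample", "caller"]


# ---------------------------------------------------------------------------
# call TSV
# ---------------------------------------------------------------------------

def write_calls_tsv(calls: list[CNVCall], path) -> None:
    rows = [
        {"chrom": c.chrom, "start": c.start, "end": c.end, "svtype": c.svtype,
         "genotype": "" if c.genotype is None or (isinstance(c.genotype, float)
                                                  and math.isnan(c.genotype))
         else int(c.genotype),
         "qual": c.qual.get("qual", ""), "sample": c.sample, "caller": c.caller}
        for c in calls
    ]
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> list[CNVCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str, "caller": str})
    calls = []
    for _, row in df.iterrows():
        gt = row["genotype"]
        gt = float("nan") if pd.isna(gt) else float(gt)
        qual = {} if pd.isna(row.get("qual")) else {"qual": float(row["qual"])}
        calls.append(CNVCall(row["chrom"], int(row["start"]), int(row["end"]),
                             row["svtype"], gt, sample=row["sample"],
                             caller=row["caller"], qual=qual))
    return calls


def write_sample_table(populations: pd.Series, path) -> None:
    populations.rename("population").rename_axis("sample").to_csv(path, sep="\t")


def read_sample_table(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample")
    return df["population"]


# ---------------------------------------------------------------------------
# cohort VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=DUP,Description="Duplication">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_cohort_vcf(variants: list[ConsensusVariant], samples: list[str], path) -> None:
    """Minimal VCF 4.2 with SVTYPE/END and per-sample dosage GT."""
    lines = [_VCF_HEADER.rstrip()]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for v in variants:
        info = f"SVTYPE={v.svtype};END={v.end}"
        gts = []
        for s in samples:
            g = v.genotypes.get(s, 0.0)
            gts.append("./." if g is None or (isinstance(g, float) and math.isnan(g))
                       else _GT_CODE[int(g)])
        # POS converts 0-based half-open start to 1-based
        lines.append("\t".join([v.chrom, str(v.start + 1), v.vid, "N",
                                f"<{v.svtype}>", ".", "PASS", info, "GT"] + gts))
    Path(path).write_text("\n".join(lines) + "\n")


def read_snp_vcf(path, populations: pd.Series) -> GenotypeMatrix:
    """Dosage matrix from a (plain-text) SNP VCF via pysam."""
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        ids, meta, rows = [], [], []
        for rec in vf:
            vid = rec.id or f"{rec.chrom}:{rec.pos}"
            dosages = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    dosages.append(np.nan)
                else:
                    dosages.append(float(sum(1 for a in gt if a != 0)))
            ids.append(vid)
            meta.append({"chrom": rec.chrom, "start": rec.pos - 1, "end": rec.pos,
                         "svtype": "SNP"})
            rows.append(dosages)
    variants = pd.DataFrame(meta, index=pd.Index(ids, name="variant"))
    dosages = pd.DataFrame(rows, index=variants.index, columns=samples, dtype=float)
    return GenotypeMatrix(variants, dosages, populations)


def write_snp_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a dosage matrix of SNPs as a minimal biallelic VCF."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples),
    ]
    for vid, row in matrix.variants.iterrows():
        gts = [
            "./." if math.isnan(g) else _GT_CODE[int(g)]
            for g in matrix.dosages.loc[vid]
        ]
        lines.append("\t".join([row["chrom"], str(int(row["start"]) + 1), str(vid),
                                "A", "G", ".", "PASS", ".", "GT"] + gts))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# gene model BED12 and score tables
# ---------------------------------------------------------------------------

def write_gene_model_bed12(annotation: GenomeAnnotation, path) -> None:
    lines = []
    genes = sorted(annotation.genes.values(), key=lambda g: (g.chrom, g.start, g.end))
    for g in genes:
        sizes = ",".join(str(e - s) for s, e in g.exons) + ","
        starts = ",".join(str(s - g.start) for s, _ in g.exons) + ","
        lines.append("\t".join([
            g.chrom, str(g.start), str(g.end), g.gene_id, "0", g.strand,
            str(g.start), str(g.end), "0", str(len(g.exons)), sizes, starts,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_model_bed12(path, scores: pd.DataFrame | None = None) -> GenomeAnnotation:
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        chrom, start, end, name, strand = f[0], int(f[1]), int(f[2]), f[3], f[5]
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
        genes.append(GeneRecord(name, chrom, start, end, strand, exons))
    ann = GenomeAnnotation(genes)
    if scores is not None:
        ann.apply_scores(scores)
    return ann


def write_gene_scores(annotation: GenomeAnnotation, path) -> None:
    rows = [
        {"gene": g.gene_id,
         "loeuf_bin": "" if pd.isna(g.loeuf_bin) else int(g.loeuf_bin),
         "disease_flag": int(g.disease_flag)}
        for g in sorted(annotation.genes.values(), key=lambda g: g.gene_id)
    ]
    pd.DataFrame(rows, columns=["gene", "loeuf_bin", "disease_flag"]).to_csv(
        path, sep="\t", index=False)


def read_gene_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    df["loeuf_bin"] = df["loeuf_bin"].astype("Int64")
    df["disease_flag"] = df["disease_flag"].astype(bool)
    return df.set_index("gene")


# ---------------------------------------------------------------------------
# BED and regions
# ---------------------------------------------------------------------------

def write_bed(regions: dict[str, list[tuple[int, int]]], path, name_prefix="region") -> None:
    lines = []
    i = 0
    for chrom in sorted(regions):
        for s, e in sorted(regions[chrom]):
            lines.append(f"{chrom}\t{s}\t{e}\t{name_prefix}_{i:05d}")
            i += 1
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    return out


# ---------------------------------------------------------------------------
# trait tables and GMT
# ---------------------------------------------------------------------------

def write_trait_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_trait_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str, "trait": str})


def read_gmt(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """GMT gene-set file -> (term -> genes, term -> description)."""
    term_map: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        term_map[f[0]] = set(f[2:])
        descriptions[f[0]] = f[1]
    return term_map, descriptions


def write_gmt(term_map: dict[str, set[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    lines = [
        "\t".join([term, descriptions.get(term, term)] + sorted(genes))
        for term, genes in term_map.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
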