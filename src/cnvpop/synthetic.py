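"""Synthetic CNV cohort generator with planted truth.

Emulates every input of the analysis pipeline: truth CNVs placed on a
small diploid genome, Balding-Nichols population allele frequencies,
Hardy-Weinberg genotypes, per-caller call sets with breakpoint jitter and
false positives/negatives, a gene model with exon/intron structure and
LoF-intolerance (LOEUF) bins, and SNPs in tunable LD with the CNVs.

Every generator takes an explicit master seed and derives an independent
substream per stage, so outputs are reproducible and stages do not perturb
each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DEL, DUP, CNVCall, GenomeLayout, GenotypeMatrix, stage_rng

MIN_SV_LENGTH = 50  # structural variants are > 50 bp by definition


# ---------------------------------------------------------------------------
# parameter objects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthCNV:
    """A planted copy-number variant with known population frequencies."""

    vid: str
    chrom: str
    start: int
    end: int
    svtype: str
    pop_af: dict[str, float] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CallerProfile:
    """Error model of one emulated SV caller.

    rank 1 is the most confident caller; jitter is the SD (bp) of the
    Gaussian breakpoint noise; fpr is the expected number of false calls
    per genome; fnr the per-call miss probability; genotype_error the
    probability of flipping het<->hom on an emitted call.
    """

    name: str
    rank: int
    breakpoint_jitter_sd: float = 0.0
    fpr: float = 0.0
    fnr: float = 0.0
    genotype_error: float = 0.0

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError("rank must be a positive integer")
        for attr in ("fnr", "genotype_error"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must lie in [0, 1]")
        if self.fpr < 0 or self.breakpoint_jitter_sd < 0:
            raise ValueError("fpr and jitter must be non-negative")


@dataclass(frozen=True)
class PopulationModel:
    """Balding-Nichols population structure.

    Population allele frequencies are drawn around an ancestral frequency p
    as Beta(p(1-F)/F, (1-p)(1-F)/F), giving E[AF] = p and
    Var[AF] = p(1-p)F.  ``ancestral_af_range`` is the uniform sampling law
    for ancestral frequencies.
    """

    populations: tuple[tuple[str, int], ...]
    fst_target: float = 0.05
    ancestral_af_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self):
        if not 0.0 < self.fst_target < 1.0:
            raise ValueError("fst_target must lie in (0, 1)")
        if any(n < 2 for _, n in self.populations):
            raise ValueError("each population needs >= 2 samples")

    @property
    def labels(self) -> list[str]:
        return [p for p, _ in self.populations]

    def sample_table(self) -> pd.Series:
        names, pops = [], []
        for label, n in self.populations:
            for i in range(n):
                names.append(f"{label}_{i:03d}")
                pops.append(label)
        return pd.Series(pops, index=pd.Index(names, name="sample"), name="population")


DEFAULT_LAYOUT = GenomeLayout(
    chromosomes=(("chr1", 30_000_000), ("chr2", 20_000_000), ("chr3", 10_000_000))
)

# Loosely calibrated caller set: ranks follow published benchmark-style
# orderings; error magnitudes are generic, not a portrait of any tool.
DEFAULT_CALLER_PROFILES = (
    CallerProfile("callerA", rank=1, breakpoint_jitter_sd=15.0, fpr=5.0, fnr=0.05,
                  genotype_error=0.01),
    CallerProfile("callerB", rank=2, breakpoint_jitter_sd=30.0, fpr=8.0, fnr=0.10,
                  genotype_error=0.03),
    CallerProfile("callerC", rank=3, breakpoint_jitter_sd=60.0, fpr=12.0, fnr=0.15,
                  genotype_error=0.05),
)


# ---------------------------------------------------------------------------
# length laws
# ---------------------------------------------------------------------------

def sample_lengths(rng: np.random.Generator, n: int, law: dict) -> np.ndarray:
    """Draw n variant lengths (bp) from a small distribution spec.

    Supported laws: {"name": "lognormal", "mean_log": m, "sd_log": s},
    {"name": "uniform", "low": a, "high": b}, {"name": "constant",
    "value": v}.  Lengths below the 50 bp SV floor are resampled upward by
    clipping.
    """
    name = law.get("name", "lognormal")
    if name == "lognormal":
        lengths = rng.lognormal(law.get("mean_log", 8.0), law.get("sd_log", 1.0), size=n)
    elif name == "uniform":
        lengths = rng.uniform(law["low"], law["high"], size=n)
    elif name == "constant":
        lengths = np.full(n, float(law["value"]))
    else:
        raise ValueError(f"unknown length law {name!r}")
    return np.maximum(np.round(lengths).astype(np.int64), MIN_SV_LENGTH)


# ---------------------------------------------------------------------------
# truth variants
# ---------------------------------------------------------------------------

def simulate_truth_cnvs(
    layout: GenomeLayout,
    n_variants: int,
    length_law: dict | None = None,
    del_dup_ratio: float = 0.9,
    seed: int = 0,
    max_tries: int = 1000,
) -> list[TruthCNV]:
    """Place non-overlapping (within type) truth CNVs uniformly on the genome.

    ``del_dup_ratio`` is the probability that a variant is a deletion.
    Placement rejects overlaps within the same type; a genome too small to
    host the requested number raises after ``max_tries`` rejections per
    variant.
    """
    if n_variants < 0:
        raise ValueError("n_variants must be >= 0")
    if n_variants == 0:
        return []
    rng = stage_rng(seed, "truth_cnvs")
    length_law = length_law or {"name": "lognormal", "mean_log": 8.0, "sd_log": 1.0}
    lengths = sample_lengths(rng, n_variants, length_law)
    types = np.where(rng.random(n_variants) < del_dup_ratio, DEL, DUP)
    chrom_p = layout.lengths / layout.total_length

    placed: dict[str, dict[str, list[tuple[int, int]]]] = {
        t: {c: [] for c in layout.names} for t in (DEL, DUP)
    }
    out: list[TruthCNV] = []
    for i in range(n_variants):
        length = int(lengths[i])
        svtype = str(types[i])
        for _ in range(max_tries):
            ci = rng.choice(len(layout.names), p=chrom_p)
            chrom, chrom_len = layout.chromosomes[ci]
            if chrom_len <= length:
                continue
            start = int(rng.integers(0, chrom_len - length + 1))
            end = start + length
            if all(end <= s or start >= e for s, e in placed[svtype][chrom]):
                placed[svtype][chrom].append((start, end))
                out.append(TruthCNV(f"truth_{i:05d}", chrom, start, end, svtype))
                break
        else:
            raise RuntimeError(
                f"could not place variant {i} of length {length} after {max_tries} tries"
            )
    return out


def simulate_population_frequencies(
    truth: list[TruthCNV], model: PopulationModel, seed: int = 0
) -> list[TruthCNV]:
    """Attach Balding-Nichols per-population allele frequencies to truth CNVs."""
    rng = stage_rng(seed, "population_frequencies")
    F = model.fst_target
    lo, hi = model.ancestral_af_range
    out = []
    for cnv in truth:
        p = float(rng.uniform(lo, hi))
        pop_af = {}
        for label in model.labels:
            if p <= 0.0 or p >= 1.0:
                pop_af[label] = float(p)
            else:
                a = p * (1.0 - F) / F
                b = (1.0 - p) * (1.0 - F) / F
                pop_af[label] = float(rng.beta(a, b))
        out.append(TruthCNV(cnv.vid, cnv.chrom, cnv.start, cnv.end, cnv.svtype, pop_af))
    return out


def balding_nichols_af(
    rng: np.random.Generator, p: np.ndarray, F: float, size=None
) -> np.ndarray:
    """Vectorised Balding-Nichols draw; fixed (0/1) ancestral AFs pass through."""
    p = np.asarray(p, dtype=float)
    out = np.where(
        (p > 0) & (p < 1),
        rng.beta(np.clip(p, 1e-12, None) * (1 - F) / F,
                 np.clip(1 - p, 1e-12, None) * (1 - F) / F,
                 size=size),
        p,
    )
    return out


def sample_genotypes(
    truth: list[TruthCNV], model: PopulationModel, seed: int = 0
) -> GenotypeMatrix:
    """HWE dosage genotypes: per individual, dosage ~ Binomial(2, pop AF)."""
    rng = stage_rng(seed, "genotypes")
    samples = model.sample_table()
    n_var = len(truth)
    dosage = np.zeros((n_var, len(samples)), dtype=float)
    col = 0
    for label, n in model.populations:
        af = np.array([t.pop_af[label] for t in truth], dtype=float)
        dosage[:, col:col + n] = rng.binomial(2, af[:, None], size=(n_var, n))
        col += n
    variants = pd.DataFrame(
        {
            "chrom": [t.chrom for t in truth],
            "start": [t.start for t in truth],
            "end": [t.end for t in truth],
            "svtype": [t.svtype for t in truth],
        },
        index=pd.Index([t.vid for t in truth], name="variant"),
    )
    dosages = pd.DataFrame(dosage, index=variants.index, columns=samples.index)
    return GenotypeMatrix(variants, dosages, samples)


# ---------------------------------------------------------------------------
# caller emulation
# ---------------------------------------------------------------------------

def emulate_caller(
    carried: list[TruthCNV],
    genotypes: dict[str, float],
    profile: CallerProfile,
    layout: GenomeLayout,
    sample: str,
    seed: int = 0,
    fp_length_law: dict | None = None,
) -> list[CNVCall]:
    """Emit one caller's call set for one sample.

    Each carried truth CNV (dosage >= 1) is emitted with probability
    1 - fnr; breakpoints are independently jittered by rounded
    Normal(0, jitter_sd) (ties to even), clipped to the chromosome and to
    keep start < end.  Poisson(fpr) false calls are placed uniformly.
    Genotypes flip het<->hom-alt with probability genotype_error.
    """
    rng = stage_rng(seed, f"caller:{profile.name}:{sample}")
    fp_length_law = fp_length_law or {"name": "lognormal", "mean_log": 7.0, "sd_log": 0.8}
    calls: list[CNVCall] = []
    for cnv in carried:
        if rng.random() < profile.fnr:
            continue
        jitter = rng.normal(0.0, profile.breakpoint_jitter_sd, size=2) \
            if profile.breakpoint_jitter_sd > 0 else np.zeros(2)
        chrom_len = layout.length_of(cnv.chrom)
        start = int(np.clip(np.rint(cnv.start + jitter[0]), 0, chrom_len - 1))
        end = int(np.clip(np.rint(cnv.end + jitter[1]), start + 1, chrom_len))
        gt = genotypes[cnv.vid]
        if profile.genotype_error > 0 and rng.random() < profile.genotype_error:
            gt = 2.0 if gt == 1.0 else 1.0
        calls.append(CNVCall(cnv.chrom, start, end, cnv.svtype, gt,
                             caller=profile.name, sample=sample,
                             qual={"qual": float(rng.uniform(20, 60))}))
    n_fp = rng.poisson(profile.fpr)
    if n_fp:
        lengths = sample_lengths(rng, n_fp, fp_length_law)
        chrom_p = layout.lengths / layout.total_length
        for length in lengths:
            ci = rng.choice(len(layout.names), p=chrom_p)
            chrom, chrom_len = layout.chromosomes[ci]
            length = int(min(length, chrom_len - 1))
            start = int(rng.integers(0, chrom_len - length))
            svtype = DEL if rng.random() < 0.9 else DUP
            calls.append(CNVCall(chrom, start, start + length, svtype, 1.0,
                                 caller=profile.name, sample=sample,
                                 qual={"qual": float(rng.uniform(5, 40))}))
    calls.sort(key=lambda c: (c.chrom, c.start, c.end))
    return calls


def emulate_cohort_calls(
    truth: list[TruthCNV],
    matrix: GenotypeMatrix,
    profiles: tuple[CallerProfile, ...] = DEFAULT_CALLER_PROFILES,
    layout: GenomeLayout = DEFAULT_LAYOUT,
    seed: int = 0,
) -> dict[str, dict[str, list[CNVCall]]]:
    """Per-sample, per-caller call sets for the whole cohort.

    Returns {sample: {caller: [CNVCall, ...]}}.
    """
    by_vid = {t.vid: t for t in truth}
    out: dict[str, dict[str, list[CNVCall]]] = {}
    for sample in matrix.samples:
        dosages = matrix.dosages[sample]
        carried = [by_vid[v] for v in dosages.index[dosages >= 1]]
        genotypes = dosages.to_dict()
        out[sample] = {
            p.name: emulate_caller(carried, genotypes, p, layout, sample, seed=seed)
            for p in profiles
        }
    return out


# ---------------------------------------------------------------------------
# gene model
# ---------------------------------------------------------------------------

def simulate_gene_model(
    layout: GenomeLayout,
    n_genes: int = 200,
    mean_exons_per_gene: float = 5.0,
    gene_length_law: dict | None = None,
    loeuf_missing_rate: float = 0.1,
    disease_flag_rate: float = 0.05,
    seed: int = 0,
    max_tries: int = 2000,
):
    """Non-overlapping genes with exon blocks, LOEUF bins and disease flags.

    Exon counts are 1 + Poisson(mean - 1); LOEUF bins are uniform over 0-9
    with ``loeuf_missing_rate`` of genes unscored (pandas NA), mirroring
    real catalogs where some genes lack a constraint estimate.  Returns a
    :class:`~cnvpop.annotation.GenomeAnnotation`.
    """
    from .annotation import GeneRecord, GenomeAnnotation

    rng = stage_rng(seed, "gene_model")
    gene_length_law = gene_length_law or {"name": "lognormal", "mean_log": 10.0, "sd_log": 0.6}
    lengths = sample_lengths(rng, n_genes, gene_length_law)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.names}
    chrom_p = layout.lengths / layout.total_length
    genes: list[GeneRecord] = []
    for i in range(n_genes):
        span = int(max(lengths[i], 200))
        for _ in range(max_tries):
            ci = rng.choice(len(layout.names), p=chrom_p)
            chrom, chrom_len = layout.chromosomes[ci]
            if chrom_len <= span:
                continue
            start = int(rng.integers(0, chrom_len - span))
            end = start + span
            if all(end <= s or start >= e for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                break
        else:
            raise RuntimeError(f"could not place gene {i} (span {span} bp)")
        n_exons = max(1, 1 + rng.poisson(max(mean_exons_per_gene - 1.0, 0.0)))
        n_exons = min(n_exons, span // 100) or 1
        # cut the span into 2*n_exons - 1 alternating exon/intron blocks
        cuts = np.sort(rng.choice(np.arange(1, span), size=2 * n_exons - 2, replace=False)) \
            if n_exons > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [span]])
        exons = tuple(
            (start + int(bounds[2 * k]), start + int(bounds[2 * k + 1]))
            for k in range(n_exons)
        )
        loeuf = pd.NA if rng.random() < loeuf_missing_rate else int(rng.integers(0, 10))
        disease = bool(rng.random() < disease_flag_rate)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(f"gene_{i:04d}", chrom, start, end, strand, exons,
                                loeuf_bin=loeuf, disease_flag=disease))
    return GenomeAnnotation(genes)


# ---------------------------------------------------------------------------
# linked SNPs
# ---------------------------------------------------------------------------

def swap_probability_for_r2(r2_target: float) -> float:
    """Per-allele replacement probability giving expected genotype r2.

    A SNP allele copies the CNV allele and is replaced by an independent
    draw from the same frequency with probability s; the allele correlation
    is then (1 - s), so r2 = (1 - s)^2 and s = 1 - sqrt(r2).
    """
    if not 0.0 <= r2_target <= 1.0:
        raise ValueError("r2_target must lie in [0, 1]")
    return 1.0 - math.sqrt(r2_target)


def simulate_linked_snps(
    matrix: GenotypeMatrix,
    truth: list[TruthCNV],
    n_snps_per_cnv: int = 1,
    r2_target: float = 0.9,
    window: int = 1_000_000,
    trait_fraction: float = 0.5,
    layout: GenomeLayout = DEFAULT_LAYOUT,
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """SNPs tagging each CNV at a tunable expected r2.

    Each SNP's two alleles copy the CNV's allele pair, with per-allele
    replacement probability s = 1 - sqrt(r2_target) by an independent
    Bernoulli(pop AF) draw; positions are uniform within +/- window of the
    CNV midpoint.  ``trait_fraction`` of SNPs receive a trait label.

    Returns (SNP GenotypeMatrix, trait table with columns snp_id, chrom,
    pos, trait).
    """
    rng = stage_rng(seed, "linked_snps")
    s = swap_probability_for_r2(r2_target)
    by_vid = {t.vid: t for t in truth}
    pops = matrix.populations
    pop_of = pops.to_numpy()
    traits = ("height", "type_2_diabetes", "LDL_cholesterol", "asthma", "schizophrenia")

    snp_rows, snp_meta, trait_rows = [], [], []
    for vid in matrix.dosages.index:
        cnv = by_vid[vid]
        chrom_len = layout.length_of(cnv.chrom)
        mid = (cnv.start + cnv.end) // 2
        dos = matrix.dosages.loc[vid].to_numpy()
        for j in range(n_snps_per_cnv):
            pos = int(np.clip(rng.integers(mid - window, mid + window + 1), 0, chrom_len - 1))
            # split dosage into an allele pair, then degrade each allele
            a1 = np.where(dos == 2, 1, np.where(dos == 1, rng.random(dos.size) < 0.5, 0)).astype(int)
            a2 = (dos - a1).astype(int)
            alleles = np.stack([a1, a2])
            af_by_pop = {p: cnv.pop_af.get(p, 0.5) for p in pops.unique()}
            af_vec = np.array([af_by_pop[p] for p in pop_of])
            for row in alleles:
                swap = rng.random(row.size) < s
                row[swap] = (rng.random(swap.sum()) < af_vec[swap]).astype(int)
            snp_id = f"rs_{vid}_{j}"
            snp_rows.append(alleles.sum(axis=0).astype(float))
            snp_meta.append((snp_id, cnv.chrom, pos))
            if rng.random() < trait_fraction:
                trait_rows.append((snp_id, cnv.chrom, pos, str(rng.choice(traits))))

    meta = pd.DataFrame(snp_meta, columns=["snp_id", "chrom", "pos"]).set_index("snp_id")
    variants = pd.DataFrame(
        {"chrom": meta["chrom"], "start": meta["pos"], "end": meta["pos"] + 1,
         "svtype": "SNP"},
        index=meta.index.rename("variant"),
    )
    dosages = pd.DataFrame(np.asarray(snp_rows), index=variants.index, columns=matrix.samples)
    snp_matrix = GenotypeMatrix(variants, dosages, pops)
    trait_table = pd.DataFrame(trait_rows, columns=["snp_id", "chrom", "pos", "trait"])
    return snp_matrix, trait_table
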