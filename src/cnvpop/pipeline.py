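"""End-to-end orchestration of the CNV cohort analysis.

Runs the stages in their analysis order: synthetic cohort generation (or
loading of user inputs), per-sample and cross-sample consensus merging,
the filter ladder, population-genetic statistics, genomic annotation,
intron-permutation testing, LD trait linkage and gene-set ORA, collecting
everything in a RunReport.  Reruns with the same config and seed are
deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import enrichment, filters, ld, merging, permutation, popgen, synthetic
from .core import GenotypeMatrix, stage_rng

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with the standard defaults.

    Defaults follow the analysis contract: 50% reciprocal overlap, HWE
    alpha 0.05 with per-population Bonferroni, AF class bounds 0.01/0.05,
    LOEUF intolerance cut at bin 4, 5000 region permutations, r^2 > 0.8
    within 1 Mb, FDR 0.05, 10,000 F_ST bootstraps.
    """

    seed: int = 0
    overlap_threshold: float = 0.5
    min_callers: int = 1
    hwe_alpha: float = 0.05
    min_maf: float = 0.01
    n_perm: int = 5000
    r2_min: float = 0.8
    ld_window: int = 1_000_000
    fdr: float = 0.05
    n_boot: int = 10_000
    synthetic: dict = field(default_factory=dict)

    _KNOWN_SYNTHETIC = {
        "n_variants", "n_genes", "populations", "fst_target", "n_snps_per_cnv",
        "r2_target", "trait_fraction", "del_dup_ratio",
    }

    def __post_init__(self):
        if not 0.0 < self.overlap_threshold <= 1.0:
            raise ValueError("overlap_threshold must lie in (0, 1]")
        if not 0.0 < self.hwe_alpha < 1.0 or not 0.0 < self.fdr < 1.0:
            raise ValueError("alpha/FDR levels must lie in (0, 1)")
        if self.n_perm < 1 or self.n_boot < 0 or self.min_callers < 1:
            raise ValueError("counts must be positive")
        unknown = set(self.synthetic) - self._KNOWN_SYNTHETIC
        if unknown:
            raise ValueError(f"unknown synthetic parameter(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class RunReport:
    """Everything the pipeline computes, in table-ready form."""

    config_hash: str
    seed: int
    filter_report: pd.DataFrame
    n_raw_calls: int
    n_consensus: int
    n_filtered: int
    freq_class_table: pd.DataFrame           # population x class counts
    freq_class_chi2: tuple[float, int, float]
    sharing_crosstab: pd.DataFrame
    location_type_counts: pd.DataFrame       # DEL/DUP x location
    location_type_pct: pd.DataFrame
    location_type_chi2: tuple[float, int, float] | None
    fst_table: pd.DataFrame
    vst_table: pd.DataFrame
    vst_top: pd.DataFrame
    burden: pd.DataFrame
    burden_tests: pd.DataFrame
    permutation: dict[str, permutation.PermutationResult]
    linkage: list[ld.LinkageRecord]
    ora: dict[str, pd.DataFrame]
    private_terms: pd.DataFrame | None

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, pd.DataFrame):
                return o.to_dict()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if hasattr(o, "__dict__"):
                return {k: v for k, v in o.__dict__.items() if not k.startswith("_")}
            return str(o)

        payload = {k: v for k, v in self.__dict__.items() if k != "linkage"}
        payload["linkage"] = [r.__dict__ for r in self.linkage]
        return json.dumps(payload, default=default, sort_keys=True, indent=1)


def _default_synthetic_cohort(config: PipelineConfig):
    """Generate the standard synthetic study inputs.

    A four-population cohort (the study design: one focal founder
    population plus three reference panels) on a 60 Mb three-chromosome
    toy genome, with 300 planted CNVs at 90% deletions, three emulated
    callers, 200 genes, and one tagging SNP per CNV.
    """
    syn = config.synthetic
    layout = synthetic.DEFAULT_LAYOUT
    pops = syn.get(
        "populations",
        [["Roma", 20], ["Europe", 15], ["MiddleEast", 12], ["SouthAsia", 20]],
    )
    model = synthetic.PopulationModel(
        populations=tuple((p, int(n)) for p, n in pops),
        fst_target=float(syn.get("fst_target", 0.05)),
    )
    truth = synthetic.simulate_truth_cnvs(
        layout, int(syn.get("n_variants", 300)),
        del_dup_ratio=float(syn.get("del_dup_ratio", 0.9)), seed=config.seed,
    )
    truth = synthetic.simulate_population_frequencies(truth, model, seed=config.seed)
    truth_matrix = synthetic.sample_genotypes(truth, model, seed=config.seed)
    calls = synthetic.emulate_cohort_calls(truth, truth_matrix, seed=config.seed)
    gene_model = synthetic.simulate_gene_model(
        layout, n_genes=int(syn.get("n_genes", 200)), seed=config.seed)
    snps, traits = synthetic.simulate_linked_snps(
        truth_matrix, truth,
        n_snps_per_cnv=int(syn.get("n_snps_per_cnv", 1)),
        r2_target=float(syn.get("r2_target", 0.9)),
        trait_fraction=float(syn.get("trait_fraction", 0.5)),
        layout=layout, seed=config.seed,
    )
    return layout, model, truth, truth_matrix, calls, gene_model, snps, traits


def run_pipeline(config: PipelineConfig, outdir=None) -> RunReport:
    """Execute merge -> filters -> stats -> annotation -> permutation ->
    linkage -> enrichment on the synthetic cohort defined by ``config``.
    """
    (layout, model, truth, truth_matrix, calls, gene_model,
     snps, trait_table) = _default_synthetic_cohort(config)
    ranking = merging.CallerRanking(
        coordinates=tuple(p.name for p in sorted(
            synthetic.DEFAULT_CALLER_PROFILES, key=lambda p: p.rank)))

    # --- merging -------------------------------------------------------
    n_raw = sum(len(cs) for per in calls.values() for cs in per.values())
    per_sample = {
        s: merging.merge_sample_calls(per, ranking, config.overlap_threshold,
                                      config.min_callers)
        for s, per in calls.items()
    }
    variants, matrix = merging.merge_cohort(
        per_sample, config.overlap_threshold, model.sample_table())
    n_consensus = len(variants)
    log.info("merged %d raw calls into %d consensus variants", n_raw, n_consensus)

    # --- filters -------------------------------------------------------
    report = filters.FilterReport()
    matrix, report = filters.hwe_filter(matrix, config.hwe_alpha, report)
    matrix, report = filters.maf_filter(matrix, config.min_maf, report)
    n_filtered = matrix.n_variants
    log.info("filter ladder retained %d variants", n_filtered)

    # --- statistics ----------------------------------------------------
    freq_table = popgen.frequency_class_by_population(matrix)
    nonzero = freq_table.loc[:, (freq_table != 0).any()]
    freq_chi2 = popgen.contingency_chi_squared(nonzero) \
        if nonzero.shape[0] >= 2 and nonzero.shape[1] >= 2 else (float("nan"), 0, float("nan"))
    share = popgen.sharing_apportionment(matrix)
    crosstab = popgen.sharing_crosstab(share)
    fst_rng = stage_rng(config.seed, "fst_bootstrap")
    fst_table = popgen.pairwise_fst(matrix, n_boot=config.n_boot, rng=fst_rng)
    vst_table = popgen.pairwise_vst(matrix)
    vst_top = popgen.top_quintile(vst_table)

    # --- annotation ----------------------------------------------------
    location_calls = ann.classify_variants(matrix.variants, gene_model)
    ann.assign_gene_scores(location_calls, gene_model)
    loc_of = pd.Series({c.variant: ann.fold_multigene(c) for c in location_calls})
    counts, pct = ann.location_type_table(location_calls, matrix.variants["svtype"])
    loc_nonzero = counts.loc[(counts != 0).any(axis=1), (counts != 0).any()]
    loc_chi2 = popgen.contingency_chi_squared(loc_nonzero) \
        if loc_nonzero.shape[0] >= 2 and loc_nonzero.shape[1] >= 2 else None

    burden = popgen.per_genome_counts(matrix, loc_of)
    burden_tests = _burden_tests(burden)

    # --- permutation ---------------------------------------------------
    perm_results: dict[str, permutation.PermutationResult] = {}
    genic_dels = {
        chrom: [
            (int(r["start"]), int(r["end"]))
            for vid, r in matrix.variants.iterrows()
            if r["chrom"] == chrom and r["svtype"] == "DEL"
            and loc_of[vid] in ("exonic", "intronic")
        ]
        for chrom in layout.names
    }
    genic_dels = {c: ivs for c, ivs in genic_dels.items() if ivs}
    perm_rng = stage_rng(config.seed, "permutation")
    for cls, label in ((True, "intolerant_introns"), (False, "tolerant_introns")):
        target = ann.extract_intron_intervals(gene_model, intolerant=cls)
        if genic_dels and target:
            perm_results[label] = permutation.permutation_test(
                genic_dels, target, layout, n_perm=config.n_perm,
                alternative="greater", rng=perm_rng)

    # --- LD linkage ----------------------------------------------------
    snps_qc, _ = ld.snp_qc(snps)
    linkage = ld.link_cnvs_to_trait_snps(
        matrix, snps_qc, trait_table, r2_min=config.r2_min, window=config.ld_window)
    ld.annotate_linkage(linkage, {c.variant: c for c in location_calls})

    # --- enrichment ----------------------------------------------------
    ora_results, private = _ora_stage(matrix, location_calls, gene_model, config)

    return RunReport(
        config_hash=config.config_hash(), seed=config.seed,
        filter_report=report.to_frame(),
        n_raw_calls=n_raw, n_consensus=n_consensus, n_filtered=n_filtered,
        freq_class_table=freq_table, freq_class_chi2=freq_chi2,
        sharing_crosstab=crosstab,
        location_type_counts=counts, location_type_pct=pct,
        location_type_chi2=loc_chi2,
        fst_table=fst_table, vst_table=vst_table, vst_top=vst_top,
        burden=burden, burden_tests=burden_tests,
        permutation=perm_results, linkage=linkage,
        ora={p: enrichment.results_to_frame(r) for p, r in ora_results.items()},
        private_terms=private,
    )


def _burden_tests(burden: pd.DataFrame) -> pd.DataFrame:
    """Standard group-mean comparisons (one-way ANOVA and Kruskal-Wallis)
    of per-genome burdens across populations; standard tests, reported as
    such."""
    from scipy import stats as sps

    rows = []
    groups = [g["count"].to_numpy() for _, g in burden.groupby("population")]
    if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
        f, p_anova = sps.f_oneway(*groups)
        h, p_kw = sps.kruskal(*groups)
        rows.append({"burden": "count", "anova_F": f, "anova_p": p_anova,
                     "kruskal_H": h, "kruskal_p": p_kw})
    return pd.DataFrame(rows, columns=["burden", "anova_F", "anova_p",
                                       "kruskal_H", "kruskal_p"])


def _ora_stage(matrix, location_calls, gene_model, config):
    """Population-wise ORA of intolerant intron-deletion genes against the
    background of all genes with intronic deletions."""
    pop_af = matrix.population_allele_frequencies()
    svtype = matrix.variants["svtype"]
    call_of = {c.variant: c for c in location_calls}

    reference: set[str] = set()
    per_pop_lists: dict[str, set[str]] = {p: set() for p in matrix.population_labels}
    for vid, call in call_of.items():
        if svtype[vid] != "DEL":
            continue
        intronic_genes = [g for g, sub in call.sub_calls.items() if sub == "intron"]
        if not intronic_genes:
            continue
        reference.update(intronic_genes)
        intolerant = [g for g in intronic_genes if gene_model.genes[g].intolerant]
        for pop in per_pop_lists:
            if pop_af.loc[vid, pop] > 0:
                per_pop_lists[pop].update(intolerant)

    term_map = _synthetic_term_map(sorted(gene_model.genes), config.seed)
    ora_results: dict[str, list] = {}
    significant: dict[str, set[str]] = {}
    for pop, genes in per_pop_lists.items():
        if not genes or not reference:
            continue
        res = enrichment.overrepresentation_test(genes, reference, term_map,
                                                 min_term_size=2)
        ora_results[pop] = res
        significant[pop] = enrichment.significant_terms(res, config.fdr)
    private = enrichment.private_term_analysis(significant) \
        if len(significant) >= 2 else None
    return ora_results, private


def _synthetic_term_map(genes: list[str], seed: int, n_terms: int = 40,
                        mean_size: int = 15) -> dict[str, set[str]]:
    """Random gene-set map standing in for a curated ontology (synthetic)."""
    rng = stage_rng(seed, "term_map")
    out = {}
    for i in range(n_terms):
        size = max(2, rng.poisson(mean_size))
        out[f"TERM:{i:04d}"] = set(rng.choice(genes, size=min(size, len(genes)),
                                              replace=False))
    return out


def make_tables(report: RunReport) -> dict[str, str]:
    """Render the frequency-class and location tables with their
    chi-squared annotations as TSV text blocks."""
    out = {}
    t1 = report.freq_class_table.copy()
    chi2, df, p = report.freq_class_chi2
    out["frequency_classes"] = (
        t1.to_csv(sep="\t")
        + f"# chi2={chi2:.1f}\tdf={df}\tp={p:.3g}\n"
    )
    t2 = report.location_type_counts.copy()
    if report.location_type_chi2 is not None:
        chi2, df, p = report.location_type_chi2
        annot = f"# chi2={chi2:.1f}\tdf={df}\tp={p:.3g}\n"
    else:
        annot = ""
    out["location_types"] = t2.to_csv(sep="\t") + annot
    return out
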