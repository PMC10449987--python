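"""Generator behaviour: determinism, placement constraints, Balding-Nichols
moments, HWE genotype sampling, caller error emulation and LD planting."""

import numpy as np
import pytest

from cnvpop.core import GenomeLayout
from cnvpop.filters import hwe_test_matrix
from cnvpop.ld import genotype_r2
from cnvpop.merging import reciprocal_overlap
from cnvpop.synthetic import (
    CallerProfile,
    PopulationModel,
    emulate_caller,
    sample_genotypes,
    simulate_gene_model,
    simulate_linked_snps,
    simulate_population_frequencies,
    simulate_truth_cnvs,
    swap_probability_for_r2,
)


class TestTruthCnvs:
    def test_zero_variants_empty(self, small_layout):
        assert simulate_truth_cnvs(small_layout, 0) == []

    def test_deterministic_for_fixed_seed(self, small_layout):
        a = simulate_truth_cnvs(small_layout, 50, seed=1)
        b = simulate_truth_cnvs(small_layout, 50, seed=1)
        assert a == b
        c = simulate_truth_cnvs(small_layout, 50, seed=2)
        assert a != c

    def test_non_overlapping_within_type_and_above_sv_floor(self, small_layout):
        cnvs = simulate_truth_cnvs(small_layout, 100, seed=0)
        for t in ("DEL", "DUP"):
            by_chrom = {}
            for c in cnvs:
                if c.svtype == t:
                    by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
            for ivs in by_chrom.values():
                ivs.sort()
                assert all(e1 <= s2 for (_, e1), (s2, _) in zip(ivs, ivs[1:]))
        assert all(c.length >= 50 for c in cnvs)
        lengths = {name: length for name, length in small_layout.chromosomes}
        assert all(c.end <= lengths[c.chrom] for c in cnvs)

    def test_del_fraction_follows_binomial_oracle(self, small_layout):
        # Binomial(100, 0.9): mean of 200 seeds within 3 SE of 90
        counts = [
            sum(c.svtype == "DEL" for c in simulate_truth_cnvs(
                small_layout, 100, {"name": "constant", "value": 100},
                del_dup_ratio=0.9, seed=s))
            for s in range(200)
        ]
        se = np.sqrt(100 * 0.9 * 0.1) / np.sqrt(200)
        assert abs(np.mean(counts) - 90) <= 3 * se

    def test_placement_failure_raises(self):
        tiny = GenomeLayout(chromosomes=(("chr1", 300),))
        with pytest.raises(RuntimeError, match="could not place"):
            simulate_truth_cnvs(tiny, 10, {"name": "constant", "value": 200},
                                seed=0, max_tries=50)


class TestPopulationFrequencies:
    def test_near_zero_divergence_tracks_ancestral(self, small_layout):
        model = PopulationModel(populations=(("A", 10), ("B", 10)), fst_target=1e-6)
        truth = simulate_population_frequencies(
            simulate_truth_cnvs(small_layout, 50, seed=0), model, seed=0)
        for cnv in truth:
            afs = list(cnv.pop_af.values())
            assert max(afs) - min(afs) < 0.02

    def test_beta_variance_closed_form(self):
        # Var[AF] = p(1-p)F = 0.0105 at p=0.3, F=0.05; 10,000 draws within 10%
        rng = np.random.default_rng(0)
        F, p = 0.05, 0.3
        draws = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F, 10_000)
        assert np.var(draws) == pytest.approx(0.0105, rel=0.1)
        model = PopulationModel(populations=(("A", 2),) , fst_target=F,
                                ancestral_af_range=(p, p))
        layout = GenomeLayout(chromosomes=(("chr1", 10_000_000),))
        truth = simulate_population_frequencies(
            simulate_truth_cnvs(layout, 2000, {"name": "constant", "value": 100},
                                seed=1), model, seed=1)
        afs = np.array([t.pop_af["A"] for t in truth])
        assert np.var(afs) == pytest.approx(0.0105, rel=0.1)

    def test_invalid_divergence_rejected(self):
        with pytest.raises(ValueError):
            PopulationModel(populations=(("A", 5),), fst_target=0.0)


class TestGenotypes:
    def test_fixed_frequencies_give_fixed_dosages(self, small_layout, two_pop_model):
        truth = simulate_truth_cnvs(small_layout, 10, seed=0)
        import dataclasses
        fixed0 = [dataclasses.replace(t, pop_af={"A": 0.0, "B": 0.0}) for t in truth[:5]]
        fixed1 = [dataclasses.replace(t, pop_af={"A": 1.0, "B": 1.0}) for t in truth[5:]]
        matrix = sample_genotypes(fixed0 + fixed1, two_pop_model, seed=0)
        assert (matrix.dosages.iloc[:5] == 0).all().all()
        assert (matrix.dosages.iloc[5:] == 2).all().all()

    def test_genotype_proportions_match_binomial_oracle(self, small_layout):
        import dataclasses
        model = PopulationModel(populations=(("A", 10_000),), fst_target=0.05)
        truth = [dataclasses.replace(simulate_truth_cnvs(small_layout, 1, seed=0)[0],
                                     pop_af={"A": 0.5})]
        matrix = sample_genotypes(truth, model, seed=0)
        d = matrix.dosages.iloc[0]
        se = np.sqrt(0.25 * 0.75 / 10_000)
        for dosage, expected in ((0, 0.25), (1, 0.5), (2, 0.25)):
            prop = float((d == dosage).mean())
            se_k = np.sqrt(expected * (1 - expected) / 10_000)
            assert abs(prop - expected) <= 3 * se_k

    def test_generated_matrices_pass_own_hwe_test_at_nominal_rate(self, small_layout):
        model = PopulationModel(populations=(("A", 100),), fst_target=0.05,
                                ancestral_af_range=(0.2, 0.8))
        truth = simulate_population_frequencies(
            simulate_truth_cnvs(small_layout, 1000, {"name": "constant", "value": 100},
                                seed=5), model, seed=5)
        matrix = sample_genotypes(truth, model, seed=5)
        tests = hwe_test_matrix(matrix)
        poly = tests[tests["polymorphic"]]
        rate = float((poly["p"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / len(poly))
        assert abs(rate - 0.05) <= 3 * se


class TestEmulateCaller:
    def _truth(self, small_layout, n=20, length=10_000):
        cnvs = simulate_truth_cnvs(small_layout, n, {"name": "constant", "value": length},
                                   seed=0)
        return cnvs, {c.vid: 1.0 for c in cnvs}

    def test_identity_profile_reproduces_truth(self, small_layout):
        cnvs, gts = self._truth(small_layout)
        profile = CallerProfile("perfect", rank=1)
        calls = emulate_caller(cnvs, gts, profile, small_layout, "s1", seed=0)
        assert sorted((c.start, c.end) for c in calls) == \
            sorted((c.start, c.end) for c in cnvs)

    def test_total_miss_leaves_only_false_positives(self, small_layout):
        cnvs, gts = self._truth(small_layout)
        profile = CallerProfile("blind", rank=1, fnr=1.0, fpr=3.0)
        calls = emulate_caller(cnvs, gts, profile, small_layout, "s1", seed=0)
        truth_ivs = {(c.start, c.end) for c in cnvs}
        assert all((c.start, c.end) not in truth_ivs for c in calls)

    def test_small_jitter_preserves_reciprocal_overlap(self, small_layout):
        # jitter sd 10 bp on 10 kb variants: >= 99% of calls keep >= 50% RO
        cnvs, gts = self._truth(small_layout, n=10)
        profile = CallerProfile("jittery", rank=1, breakpoint_jitter_sd=10.0)
        ok = total = 0
        ordered = sorted(cnvs, key=lambda c: (c.chrom, c.start, c.end))
        for rep in range(100):
            calls = emulate_caller(cnvs, gts, profile, small_layout, "s1", seed=rep)
            for call, cnv in zip(calls, ordered):
                fa, fb = reciprocal_overlap((call.chrom, call.start, call.end),
                                            (cnv.chrom, cnv.start, cnv.end))
                total += 1
                ok += fa >= 0.5 and fb >= 0.5
        assert ok / total >= 0.99

    def test_genotype_error_flips_het_to_hom(self, small_layout):
        cnvs, gts = self._truth(small_layout)
        profile = CallerProfile("sloppy", rank=1, genotype_error=1.0)
        calls = emulate_caller(cnvs, gts, profile, small_layout, "s1", seed=0)
        assert all(c.genotype == 2.0 for c in calls)


class TestGeneModel:
    def test_single_exon_genes_have_no_introns(self, small_layout):
        ann = simulate_gene_model(small_layout, n_genes=20, mean_exons_per_gene=1.0,
                                  seed=0)
        assert all(g.introns == () for g in ann.genes.values()
                   if len(g.exons) == 1)

    def test_deterministic_and_structurally_valid(self, small_layout):
        a = simulate_gene_model(small_layout, n_genes=30, seed=3)
        b = simulate_gene_model(small_layout, n_genes=30, seed=3)
        assert {g.gene_id: (g.start, g.end, g.exons) for g in a.genes.values()} == \
               {g.gene_id: (g.start, g.end, g.exons) for g in b.genes.values()}
        for g in a.genes.values():
            assert g.exons[0][0] == g.start and g.exons[-1][1] == g.end

    def test_loeuf_missing_fraction_matches_binomial_oracle(self, small_layout):
        big = GenomeLayout(chromosomes=(("chr1", 200_000_000),))
        ann = simulate_gene_model(big, n_genes=1000, loeuf_missing_rate=0.10, seed=1)
        import pandas as pd
        missing = sum(pd.isna(g.loeuf_bin) for g in ann.genes.values()) / 1000
        se = np.sqrt(0.1 * 0.9 / 1000)
        assert abs(missing - 0.10) <= 3 * se
        bins = [int(g.loeuf_bin) for g in ann.genes.values() if not pd.isna(g.loeuf_bin)]
        assert min(bins) == 0 and max(bins) == 9


class TestLinkedSnps:
    def _cohort(self, small_layout, n_var=30, n=100, fst=0.05):
        model = PopulationModel(populations=(("A", n // 2), ("B", n // 2)),
                                fst_target=fst)
        truth = simulate_population_frequencies(
            simulate_truth_cnvs(small_layout, n_var,
                                {"name": "constant", "value": 5000}, seed=2),
            model, seed=2)
        return truth, sample_genotypes(truth, model, seed=2)

    def test_zero_swap_probability_copies_dosage_exactly(self, small_layout):
        truth, matrix = self._cohort(small_layout)
        snps, _ = simulate_linked_snps(matrix, truth, r2_target=1.0,
                                       layout=small_layout, seed=0)
        for vid in matrix.dosages.index:
            snp_id = f"rs_{vid}_0"
            assert (snps.dosages.loc[snp_id] == matrix.dosages.loc[vid]).all()

    def test_independent_snps_have_null_r2(self, small_layout):
        truth, matrix = self._cohort(small_layout, n_var=100, n=200)
        snps, _ = simulate_linked_snps(matrix, truth, r2_target=0.0,
                                       layout=small_layout, seed=1)
        r2s = []
        for vid in matrix.dosages.index:
            try:
                r2s.append(genotype_r2(matrix.dosages.loc[vid],
                                       snps.dosages.loc[f"rs_{vid}_0"]))
            except ValueError:
                continue
        assert np.mean(r2s) < 0.02  # null expectation ~ 1/n = 0.005

    @pytest.mark.parametrize("target", [0.2, 0.5, 0.9])
    def test_mean_r2_tracks_target(self, small_layout, target):
        truth, matrix = self._cohort(small_layout, n_var=100, n=200)
        snps, _ = simulate_linked_snps(matrix, truth, r2_target=target,
                                       layout=small_layout, seed=3)
        r2s = []
        for vid in matrix.dosages.index:
            try:
                r2s.append(genotype_r2(matrix.dosages.loc[vid],
                                       snps.dosages.loc[f"rs_{vid}_0"]))
            except ValueError:
                continue
        assert np.mean(r2s) == pytest.approx(target, abs=0.05)

    def test_positions_within_window_of_midpoint(self, small_layout):
        truth, matrix = self._cohort(small_layout)
        window = 50_000
        snps, traits = simulate_linked_snps(matrix, truth, window=window,
                                            layout=small_layout, seed=4)
        mids = {t.vid: (t.start + t.end) // 2 for t in truth}
        for snp_id, row in snps.variants.iterrows():
            vid = "_".join(snp_id.split("_")[1:3])
            assert abs(row["start"] - mids[vid]) <= window

    def test_swap_probability_formula(self):
        assert swap_probability_for_r2(1.0) == 0.0
        assert swap_probability_for_r2(0.0) == 1.0
        assert swap_probability_for_r2(0.25) == pytest.approx(0.5)
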