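"""Population-genetic statistics: frequency classes, sharing, burdens,
Weir-Cockerham F_ST (including Balding-Nichols parameter recovery), per-CNV
V_ST with its heterozygosity-oracle identity, and the contingency
chi-squared."""

import numpy as np
import pandas as pd
import pytest

from cnvpop.core import GenotypeMatrix
from cnvpop.popgen import (
    allele_frequency,
    bootstrap_fst_p,
    burden_summary,
    classify_frequency,
    contingency_chi_squared,
    frequency_class_by_population,
    pairwise_vst,
    per_genome_counts,
    sharing_apportionment,
    sharing_crosstab,
    top_quintile,
    vst,
    vst_from_values,
    weir_cockerham_fst,
)
from cnvpop.synthetic import (
    PopulationModel,
    sample_genotypes,
    simulate_population_frequencies,
    simulate_truth_cnvs,
)
from cnvpop.core import GenomeLayout
from conftest import make_matrix


class TestAlleleFrequency:
    @pytest.mark.parametrize("dosages, expected", [
        ([0, 0, 0, 0], 0.0),
        ([2, 2], 1.0),
        ([0, 1, 1, 2], 0.5),
        ([0, 1, np.nan, np.nan], 0.25),  # pairwise-complete denominator
    ])
    def test_values(self, dosages, expected):
        assert allele_frequency(dosages) == pytest.approx(expected)

    def test_all_missing_undefined(self):
        with pytest.raises(ValueError):
            allele_frequency([np.nan, np.nan])


class TestClassifyFrequency:
    @pytest.mark.parametrize("af, expected", [
        (0.06, "common"), (0.051, "common"),
        (0.05, "low"), (0.01, "low"), (0.03, "low"),
        (0.005, "rare"), (0.0099, "rare"), (0.0, "rare"),
    ])
    def test_boundaries(self, af, expected):
        assert classify_frequency(af) == expected

    def test_classes_partition_any_af(self):
        for af in np.linspace(0, 1, 101):
            assert classify_frequency(af) in ("common", "low", "rare")


class TestSharing:
    def test_private_and_ubiquitous_counts(self):
        pops = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        matrix = make_matrix({"priv": [1, 1, 0, 0], "both": [1, 0, 1, 0]}, pops)
        share = sharing_apportionment(matrix)
        assert share.loc["priv", "n_populations"] == 1
        assert share.loc["both", "n_populations"] == 2

    def test_crosstab_totals_match_planted_structure(self):
        rng = np.random.default_rng(2)
        pops = {f"{p}{i}": p for p in "ABCD" for i in range(10)}
        rows = {}
        for i in range(30):  # carried in exactly 2 of 4 populations
            v = np.zeros(40)
            block = rng.choice(4, 2, replace=False)
            for b in block:
                v[b * 10: b * 10 + 10] = rng.binomial(2, 0.4, 10)
                v[b * 10] = max(v[b * 10], 1)  # guarantee presence
            rows[f"v{i}"] = v
        matrix = make_matrix(rows, pops)
        tab = sharing_crosstab(sharing_apportionment(matrix))
        assert tab[2].sum() == 30

    def test_needs_two_populations(self):
        with pytest.raises(ValueError):
            sharing_apportionment(make_matrix({"v": [1, 1]}, {"s1": "A", "s2": "A"}))


class TestPerGenomeCounts:
    def test_zero_dosage_sample_counts_zero(self):
        matrix = make_matrix({"v1": [0, 1], "v2": [0, 2]}, {"s1": "A", "s2": "B"})
        counts = per_genome_counts(matrix)
        assert counts.loc["s1", "count"] == 0 and counts.loc["s2", "count"] == 2

    def test_identical_samples_identical_counts(self):
        matrix = make_matrix({"v1": [1, 1], "v2": [2, 2]}, {"s1": "A", "s2": "B"})
        counts = per_genome_counts(matrix)
        assert counts.loc["s1", "count"] == counts.loc["s2", "count"]

    def test_planted_burden_difference_recovered(self):
        rng = np.random.default_rng(8)
        pops = {f"a{i}": "A" for i in range(25)} | {f"b{i}": "B" for i in range(25)}
        rows = {f"shared{i}": rng.binomial(2, 0.5, 50).astype(float) for i in range(100)}
        for i in range(50):  # 50 extra deletions carried only by population A
            rows[f"extra{i}"] = np.array([1.0] * 25 + [0.0] * 25)
        matrix = make_matrix(rows, pops)
        summary = burden_summary(per_genome_counts(matrix))
        diff = summary.loc["A", "mean"] - summary.loc["B", "mean"]
        se = np.sqrt(summary.loc["A", "sd"] ** 2 / 25 + summary.loc["B", "sd"] ** 2 / 25)
        assert abs(diff - 50) <= max(3 * se, 1e-9)

    def test_group_counts_split_by_label(self):
        matrix = make_matrix({"v1": [1, 1], "v2": [1, 0]}, {"s1": "A", "s2": "B"})
        groups = pd.Series({"v1": "exonic", "v2": "intronic"})
        counts = per_genome_counts(matrix, groups)
        assert counts.loc["s1", "count_exonic"] == 1
        assert counts.loc["s1", "count_intronic"] == 1
        assert counts.loc["s2", "count_intronic"] == 0


class TestWeirCockerhamFst:
    def test_undifferentiated_populations_near_zero(self):
        # two groups drawn independently from one panmictic population
        rng = np.random.default_rng(4)
        rows = {f"v{i}": rng.binomial(2, rng.uniform(0.1, 0.9), 100).astype(float)
                for i in range(2000)}
        pops = {f"a{i}": "A" for i in range(50)} | {f"b{i}": "B" for i in range(50)}
        res = weir_cockerham_fst(make_matrix(rows, pops), ("A", "B"))
        assert abs(res.theta) < 0.01

    def test_fixed_difference_is_one(self):
        rows = {f"v{i}": [0.0] * 10 + [2.0] * 10 for i in range(5)}
        pops = {f"a{i}": "A" for i in range(10)} | {f"b{i}": "B" for i in range(10)}
        res = weir_cockerham_fst(make_matrix(rows, pops), ("A", "B"))
        assert res.theta == pytest.approx(1.0)

    def test_balding_nichols_parameter_recovery(self, small_layout):
        # F in {0.01, 0.05, 0.1}: theta recovered within +/- 0.01
        for F in (0.01, 0.05, 0.1):
            model = PopulationModel(populations=(("A", 50), ("B", 50)), fst_target=F)
            truth = simulate_truth_cnvs(small_layout, 2000,
                                        {"name": "constant", "value": 100}, seed=3)
            truth = simulate_population_frequencies(truth, model, seed=3)
            matrix = sample_genotypes(truth, model, seed=3)
            res = weir_cockerham_fst(matrix, ("A", "B"))
            assert res.theta == pytest.approx(F, abs=0.01)

    def test_symmetric_in_pair_order(self, hwe_cohort):
        ab = weir_cockerham_fst(hwe_cohort, ("A", "B")).theta
        ba = weir_cockerham_fst(hwe_cohort, ("B", "A")).theta
        assert ab == pytest.approx(ba, abs=1e-12)

    def test_monomorphic_matrix_undefined(self):
        matrix = make_matrix({"v": [0.0] * 8}, {f"s{i}": "AB"[i % 2] for i in range(8)})
        with pytest.raises(ValueError, match="polymorphic"):
            weir_cockerham_fst(matrix, ("A", "B"))


class TestBootstrapFst:
    def test_differentiated_cohort_hits_floor(self):
        rows = {f"v{i}": [0.0] * 10 + [2.0] * 10 for i in range(50)}
        pops = {f"a{i}": "A" for i in range(10)} | {f"b{i}": "B" for i in range(10)}
        res = bootstrap_fst_p(make_matrix(rows, pops), ("A", "B"), n_boot=1000,
                              rng=np.random.default_rng(0))
        assert res.bootstrap_p == pytest.approx(1 / 1001)

    def test_null_cohort_rarely_significant(self, hwe_cohort):
        rng = np.random.default_rng(1)
        hits = sum(
            bootstrap_fst_p(hwe_cohort, ("A", "B"), n_boot=200, rng=rng).bootstrap_p < 0.05
            for _ in range(20)
        )
        assert hits <= 2

    def test_zero_bootstraps_rejected(self, hwe_cohort):
        with pytest.raises(ValueError):
            bootstrap_fst_p(hwe_cohort, ("A", "B"), n_boot=0)


class TestVst:
    def test_complete_separation_is_one(self):
        v_t, v_s, v = vst_from_values([2, 2, 2, 2], [0, 0, 0, 0])
        assert (v_t, v_s, v) == (1.0, 0.0, 1.0)

    def test_identical_groups_are_zero(self):
        v_t, v_s, v = vst_from_values([0, 2], [0, 2])
        assert v_t == 1.0 and v == 0.0

    def test_constant_variant_undefined(self):
        _, _, v = vst_from_values([1, 1, 1], [1, 1, 1])
        assert v is None

    def test_matches_heterozygosity_oracle_on_binary_copy_states(self):
        # Variants with two observed copy-number states (het carriers vs
        # non-carriers): V_ST must equal (H_T - H_S)/H_T computed from the
        # carrier frequencies, to 1e-9.
        rng = np.random.default_rng(6)
        for _ in range(50):
            n1, n2 = rng.integers(5, 80, 2)
            va = (rng.random(n1) < rng.uniform(0.05, 0.95)).astype(float)
            vb = (rng.random(n2) < rng.uniform(0.05, 0.95)).astype(float)
            _, _, v = vst_from_values(va, vb)
            f1, f2 = va.mean(), vb.mean()
            fbar = (n1 * f1 + n2 * f2) / (n1 + n2)
            h_t = 2 * fbar * (1 - fbar)
            h_s = (n1 * 2 * f1 * (1 - f1) + n2 * 2 * f2 * (1 - f2)) / (n1 + n2)
            if h_t == 0:
                assert v is None
            else:
                assert v == pytest.approx((h_t - h_s) / h_t, abs=1e-9)

    def test_affine_invariance_dosage_vs_copies(self):
        rng = np.random.default_rng(10)
        a, b = rng.integers(0, 3, 30).astype(float), rng.integers(0, 3, 25).astype(float)
        _, _, v_dosage = vst_from_values(a, b)
        _, _, v_del = vst_from_values(2 - a, 2 - b)      # deletion copy numbers
        _, _, v_dup = vst_from_values(2 + a, 2 + b)      # duplication copy numbers
        assert v_dosage == pytest.approx(v_del, abs=1e-12)
        assert v_dosage == pytest.approx(v_dup, abs=1e-12)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a = rng.integers(0, 3, 20).astype(float)
            b = rng.integers(0, 3, 20).astype(float)
            try:
                _, _, v1 = vst_from_values(a, b)
                _, _, v2 = vst_from_values(b, a)
            except ValueError:
                continue
            if v1 is not None:
                assert v1 == pytest.approx(v2, abs=1e-12) and v1 <= 1.0

    def test_matrix_interface_matches_scalar(self):
        pops = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
        matrix = make_matrix({"v": [0, 1, 2, 0, 0, 0]}, pops)
        res = vst(matrix, "v", ("A", "B"))
        long = pairwise_vst(matrix)
        assert res.vst == pytest.approx(long.loc[0, "vst"])


class TestTopQuintile:
    def test_values_one_to_ten(self):
        table = pd.DataFrame({"pop_a": "A", "pop_b": "B",
                              "vst": np.arange(1.0, 11.0),
                              "v_total": 1.0, "v_within": 0.0,
                              "variant": [f"v{i}" for i in range(10)]})
        top = top_quintile(table)
        assert sorted(top["vst"]) == [9.0, 10.0]  # 80th percentile = 8.2

    def test_all_equal_degenerate_quantile_includes_all(self):
        table = pd.DataFrame({"pop_a": "A", "pop_b": "B", "vst": [0.3] * 6,
                              "v_total": 1.0, "v_within": 0.7,
                              "variant": [f"v{i}" for i in range(6)]})
        assert len(top_quintile(table)) == 6

    def test_too_few_values_warns_and_skips(self):
        table = pd.DataFrame({"pop_a": "A", "pop_b": "B", "vst": [0.1] * 4,
                              "v_total": 1.0, "v_within": 0.9,
                              "variant": [f"v{i}" for i in range(4)]})
        with pytest.warns(UserWarning, match="< 5 defined"):
            top = top_quintile(table)
        assert top.empty


class TestContingencyChiSquared:
    def test_independent_table_is_zero(self):
        chi2, df, p = contingency_chi_squared([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0) and df == 1

    def test_frequency_class_table_reproduces_printed_statistic(self):
        table = [[1967, 479, 288], [1899, 345, 223], [1835, 289, 230], [2006, 531, 382]]
        chi2, df, p = contingency_chi_squared(table)
        assert abs(chi2 - 83.6) <= 0.1 and df == 6
        assert p == pytest.approx(6.25e-16, rel=0.01)

    def test_location_type_table_reproduces_printed_statistic(self):
        chi2, df, _ = contingency_chi_squared([[211, 1111, 1849], [89, 134, 266]])
        assert round(chi2, 1) == 77.3 and df == 2

    def test_matches_from_scratch_oracle_on_random_tables(self):
        rng = np.random.default_rng(14)
        for _ in range(30):
            r, c = rng.integers(2, 7, 2)
            t = rng.integers(1, 50, (r, c)).astype(float)
            chi2, df, _ = contingency_chi_squared(t)
            total = t.sum()
            expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
            oracle = ((t - expected) ** 2 / expected).sum()
            assert chi2 == pytest.approx(oracle, abs=1e-9)
            assert df == (r - 1) * (c - 1)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            contingency_chi_squared([[0, 0], [5, 5]])


def test_frequency_class_table_uses_per_population_af():
    pops = {f"a{i}": "A" for i in range(50)} | {f"b{i}": "B" for i in range(50)}
    rows = {
        "common_in_A": [1.0] * 25 + [0.0] * 75,          # AF 0.25 in A, absent in B
        "rare_in_A": [1.0] + [0.0] * 99,                 # AF 0.01 in A -> low class
    }
    matrix = make_matrix(rows, pops)
    tab = frequency_class_by_population(matrix)
    assert tab.loc["A", "common"] == 1 and tab.loc["A", "low"] == 1
    assert tab.loc["B"].sum() == 0
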