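"""Burden regression, FDR control, gene-set tests and the overlap test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cpgburden import (
    BurdenResult,
    CarrierMatrix,
    GeneSetDefinition,
    adjust_fdr,
    class_enrichment,
    eligible_genes,
    fit_burden,
    geneset_summary,
    overlap_fisher,
    run_burden,
    single_cancer_run,
    summarize_significance,
)


def _matrix_from_counts(n_case, case_carriers, n_control, control_carriers, gene="G1"):
    samples = [f"ca{i}" for i in range(n_case)] + [f"co{i}" for i in range(n_control)]
    row = [i < case_carriers for i in range(n_case)] + [i < control_carriers for i in range(n_control)]
    cm = CarrierMatrix(pd.DataFrame([row], index=[gene], columns=samples))
    status = pd.Series([1] * n_case + [0] * n_control, index=samples)
    return cm, status


class TestEligibility:
    def test_pan_cancer_needs_three_total_carriers(self):
        cm, _ = _matrix_from_counts(100, 2, 100, 1)
        assert eligible_genes(cm, "pan_cancer") == {"G1"}
        cm2, _ = _matrix_from_counts(100, 2, 100, 0)
        assert eligible_genes(cm2, "pan_cancer") == set()

    def test_breast_threshold_is_strictly_more_than_four(self):
        cm, _ = _matrix_from_counts(100, 4, 100, 0)
        assert eligible_genes(cm, "Breast-AdenoCA") == set()
        cm5, _ = _matrix_from_counts(100, 5, 100, 0)
        assert eligible_genes(cm5, "Breast-AdenoCA") == {"G1"}

    @pytest.mark.parametrize("cancer,minimum", [("CNS-Medullo", 2), ("Liver-HCC", 2), ("Kidney-RCC", 3), ("Skin-Melanoma", 3)])
    def test_per_cancer_minima(self, cancer, minimum):
        at = _matrix_from_counts(100, minimum, 100, 0)[0]
        above = _matrix_from_counts(100, minimum + 1, 100, 0)[0]
        assert eligible_genes(at, cancer) == set()
        assert eligible_genes(above, cancer) == {"G1"}

    def test_unknown_cancer_type_raises(self):
        cm, _ = _matrix_from_counts(10, 5, 10, 0)
        with pytest.raises(KeyError):
            eligible_genes(cm, "Imaginary-Cancer")


class TestFitBurden:
    def test_no_covariate_fit_equals_crude_odds_ratio(self):
        """10/100 case vs 5/100 control carriers: OR = (10*95)/(90*5)."""
        cm, status = _matrix_from_counts(100, 10, 100, 5)
        r = fit_burden("G1", cm, status)
        assert r.n_case_carriers == 10 and r.n_control_carriers == 5
        assert abs(np.exp(r.coef) - (10 * 95) / (90 * 5)) < 1e-3
        assert abs(r.log2_or - 1.0780) < 1e-4

    def test_equal_frequencies_give_null_coefficient(self):
        cm, status = _matrix_from_counts(200, 20, 200, 20)
        r = fit_burden("G1", cm, status)
        assert abs(r.coef) < 1e-6
        assert r.p_value > 0.99

    def test_zero_control_carriers_flagged_and_penalized(self):
        cm, status = _matrix_from_counts(200, 15, 200, 0)
        r = fit_burden("G1", cm, status)
        assert r.separation_flag and r.penalized
        assert np.isfinite(r.coef) and r.coef > 0

    def test_zero_variance_pcs_reduce_to_crude_estimate(self):
        from cpgburden.popstruct import PCResult

        cm, status = _matrix_from_counts(100, 10, 100, 5)
        pcs = PCResult(
            scores=pd.DataFrame({"PC1": 0.0}, index=cm.samples) + pd.DataFrame({"PC1": 0.0}, index=cm.samples),
            variance_explained=np.array([0.0]),
            k=1,
        )
        r = fit_burden("G1", cm, status, pcs)
        assert abs(np.exp(r.coef) - (10 * 95) / (90 * 5)) < 1e-2


class TestFDR:
    def test_hand_computed_step_up(self):
        results = [BurdenResult(f"g{i}", 1, 1, True, p_value=p) for i, p in enumerate([0.01, 0.02, 0.03, 0.04])]
        adjust_fdr(results)
        assert np.allclose([r.q_value for r in results], 0.04)

    def test_single_p_value_unchanged(self):
        (r,) = adjust_fdr([BurdenResult("g", 1, 1, True, p_value=0.07)])
        assert r.q_value == pytest.approx(0.07)

    def test_ineligible_results_left_out_of_family(self):
        results = [
            BurdenResult("a", 1, 1, True, p_value=0.01),
            BurdenResult("b", 0, 0, False),
        ]
        adjust_fdr(results)
        assert np.isnan(results[1].q_value)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_matches_reference_step_up(self, pvals):
        """Property: BH q-values equal the textbook step-up computed by hand."""
        results = [BurdenResult(f"g{i}", 1, 1, True, p_value=p) for i, p in enumerate(pvals)]
        adjust_fdr(results)
        m = len(pvals)
        order = np.argsort(pvals)
        ref = np.empty(m)
        prev = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            rank = m - rank_from_top
            prev = min(prev, pvals[idx] * m / rank)
            ref[idx] = prev
        assert np.allclose([r.q_value for r in results], ref, atol=1e-12)

    def test_summarize_significance_share(self):
        results = [BurdenResult(f"g{i}", 1, 1, True, p_value=0.01, significant=i < 38) for i in range(49)]
        s = summarize_significance(results)
        assert s["n_significant"] == 38 and s["pct_significant"] == 77.6


class TestGenesetSummary:
    def _results(self, log2_ors):
        return [BurdenResult(f"g{i}", 1, 1, True, coef=v * np.log(2), p_value=0.5) for i, v in enumerate(log2_ors)]

    def test_median_of_members(self):
        res = self._results([1, 2, 3, -1, -2])
        out = geneset_summary(res, [GeneSetDefinition("S", ["g0", "g1", "g2"])])
        assert out.loc["S", "median_log2_or"] == 2

    def test_exchangeable_set_gives_p_near_one(self, rng):
        vals = rng.normal(size=40)
        res = self._results(vals)
        out = geneset_summary(res, [GeneSetDefinition("S", [f"g{i}" for i in range(0, 40, 2)])])
        assert out.loc["S", "p_value"] > 0.3

    def test_rank_sum_matches_exhaustive_permutation(self):
        """Oracle: 3-vs-3 rank-sum p equals full enumeration over splits."""
        vals = [0.1, 0.9, 1.7, 0.4, 2.5, -0.3]
        res = self._results(vals)
        out = geneset_summary(res, [GeneSetDefinition("S", ["g0", "g1", "g2"])], reference="complement")
        member, other = np.array(vals[:3]), np.array(vals[3:])
        obs = stats.mannwhitneyu(member, other, alternative="two-sided").statistic
        n, m = 3, 3
        stats_all = []
        for combo in itertools.combinations(range(6), n):
            a = np.array([vals[i] for i in combo])
            b = np.array([vals[i] for i in range(6) if i not in combo])
            stats_all.append(stats.mannwhitneyu(a, b, alternative="two-sided").statistic)
        stats_all = np.array(stats_all)
        mid = n * m / 2
        p_exact = np.mean(np.abs(stats_all - mid) >= abs(obs - mid) - 1e-12)
        assert out.loc["S", "p_value"] == pytest.approx(p_exact, abs=1e-9)

    def test_set_without_eligible_genes_untested(self):
        res = self._results([1.0])
        out = geneset_summary(res, [GeneSetDefinition("S", ["absent"])])
        assert out.loc["S", "n_tested"] == 0 and np.isnan(out.loc["S", "p_value"])


class TestClassEnrichment:
    def test_single_gene_set_reduces_to_gene_fit(self):
        cm, status = _matrix_from_counts(150, 12, 150, 4)
        gene_fit = fit_burden("G1", cm, status)
        set_fit = class_enrichment(GeneSetDefinition("solo", ["G1"]), cm, status)
        assert set_fit.coef == pytest.approx(gene_fit.coef, abs=1e-10)
        assert set_fit.p_value == pytest.approx(gene_fit.p_value, abs=1e-10)

    def test_disjoint_null_genes_pool_to_null(self, rng):
        samples = [f"s{i}" for i in range(600)]
        status = pd.Series([1] * 300 + [0] * 300, index=samples)
        data = pd.DataFrame(rng.random((2, 600)) < 0.04, index=["A", "B"], columns=samples)
        cm = CarrierMatrix(data)
        r = class_enrichment(GeneSetDefinition("null", ["A", "B"]), cm, status)
        assert abs(r.coef) < 1.0
        assert r.p_value > 0.01


class TestSingleCancer:
    def _samples(self):
        rows = []
        for i in range(120):
            rows.append((f"ca{i}", "case", "Liver-HCC" if i < 80 else "Other", "EAS" if i % 10 else "EUR"))
        for i in range(200):
            rows.append((f"co{i}", "control", "none", "EAS" if i % 2 else "EUR"))
        return pd.DataFrame(rows, columns=["sample_id", "cohort", "cancer_type", "population"]).set_index("sample_id")

    def test_restricts_to_majority_population(self, rng):
        samples = self._samples()
        data = pd.DataFrame(rng.random((3, len(samples))) < 0.2, index=["G1", "G2", "G3"], columns=samples.index)
        cm = CarrierMatrix(data)
        results, meta = single_cancer_run(cm, samples, "Liver-HCC", "EAS", min_cases=50)
        expected_cases = ((samples["cohort"] == "case") & (samples["cancer_type"] == "Liver-HCC") & (samples["population"] == "EAS")).sum()
        assert meta["n_cases"] == expected_cases
        assert meta["n_controls"] == ((samples["cohort"] == "control") & (samples["population"] == "EAS")).sum()

    def test_refuses_underpowered_subset(self, rng):
        samples = self._samples()
        data = pd.DataFrame(rng.random((1, len(samples))) < 0.2, index=["G1"], columns=samples.index)
        with pytest.raises(ValueError, match="refusing"):
            single_cancer_run(CarrierMatrix(data), samples, "Other", "EAS", min_cases=50)


class TestOverlapFisher:
    def test_independence_table(self):
        a = {"g1", "g2"}
        b = {"g1", "g3"}
        universe = {"g1", "g2", "g3", "g4"}
        sample_or, cond_or, p = overlap_fisher(a, b, universe)
        assert sample_or == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_pan_vs_single_cancer_worked_example(self):
        """41 of 109 pan-cancer hits among 246 single-cancer hits in 1,224 genes."""
        universe = {f"g{i}" for i in range(1224)}
        pan = {f"g{i}" for i in range(109)}
        single = {f"g{i}" for i in range(68, 68 + 246)}  # 41-gene overlap
        sample_or, cond_or, p = overlap_fisher(pan, single, universe)
        assert sample_or == pytest.approx(2.676, abs=5e-4)
        assert cond_or == pytest.approx(2.67, abs=0.02)
        assert p == pytest.approx(8.15e-6, rel=0.05)

    def test_exact_p_matches_hypergeometric_enumeration(self, rng):
        """Oracle: two-sided p equals direct enumeration of table probabilities."""
        for _ in range(20):
            a, b, c, d = rng.integers(0, 7, size=4)
            n = a + b + c + d
            if n == 0:
                continue
            universe = {f"g{i}" for i in range(n)}
            ids = list(universe)
            set_a = set(ids[: a + b])
            set_b = set(ids[:a]) | set(ids[a + b : a + b + c])
            _, _, p = overlap_fisher(set_a, set_b, universe)
            row, col = a + b, a + c
            probs = []
            obs_prob = stats.hypergeom.pmf(a, n, row, col)
            for k in range(max(0, row + col - n), min(row, col) + 1):
                probs.append(stats.hypergeom.pmf(k, n, row, col))
            p_enum = sum(q for q in probs if q <= obs_prob * (1 + 1e-9))
            assert p == pytest.approx(p_enum, rel=1e-6)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            overlap_fisher(set(), set(), set())


def test_run_burden_recovers_planted_gene(small_cohort):
    """End-to-end on a small cohort: the planted gene is the top hit."""
    _, data = small_cohort
    status = (data.samples["cohort"] == "case").astype(int)
    results = run_burden(data.carriers, status)
    tested = [r for r in results if r.eligible]
    top = min(tested, key=lambda r: r.p_value)
    assert top.gene_id == "HIT"
    assert top.significant
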