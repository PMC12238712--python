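import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from odontofa import ScreenConfig, generate, holm_correct, inject_pathology, run_screen, to_trait_table
from odontofa.qc import (
    InsufficientDataError,
    antisymmetry_test,
    directional_asymmetry_test,
    error_vs_asymmetry_screen,
    grubbs_scan,
    replicate_bias_test,
    size_dependence_test,
)


class TestReplicateBias:
    def test_identical_replicates_show_no_bias(self):
        v = np.array([5.0, 5.2, 4.9, 5.1])
        res = replicate_bias_test(v, v)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_constant_shift_is_exact_bias(self):
        res = replicate_bias_test(np.array([1.0, 2, 3, 4]), np.array([2.0, 3, 4, 5]))
        assert res.flag == "exact_bias"
        assert res.p == 0.0

    def test_matches_textbook_formula(self):
        # independent closed-form computation: t = mean(d) / (sd(d)/sqrt(n))
        first = np.array([5.0, 5.2, 4.9])
        second = np.array([5.1, 5.1, 5.0])
        d = second - first
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        p_expected = 2 * stats.t.sf(abs(t_expected), 2)
        res = replicate_bias_test(first, second)
        assert res.statistic == pytest.approx(t_expected)
        assert res.statistic == pytest.approx(0.5)
        assert res.p == pytest.approx(p_expected)
        assert res.df == 2

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            replicate_bias_test(np.array([1.0, 2]), np.array([1.0, 2]))


class TestErrorScreen:
    def test_error_dominates(self):
        assert error_vs_asymmetry_screen([0.30, 0.30], [0.10, 0.10]).exclude

    def test_asymmetry_dominates(self):
        assert not error_vs_asymmetry_screen([0.05], [0.20]).exclude

    def test_equality_retains(self):
        # strict inequality: equal means do not exclude
        assert not error_vs_asymmetry_screen([0.1, 0.3], [0.2, 0.2]).exclude

    def test_empty_input(self):
        with pytest.raises(InsufficientDataError):
            error_vs_asymmetry_screen([], [0.1])


class TestGrubbs:
    def test_tight_cluster_clean(self):
        res = grubbs_scan(np.array([0.1, -0.1, 0.0, 0.05, -0.05]))
        assert res.outlier_indices == []

    def test_gross_outlier_flagged_with_verified_critical_value(self):
        d = np.array([0.1, -0.1, 0.0, 0.05, 5.0])
        res = grubbs_scan(d, alpha=0.05)
        assert res.outlier_indices[0] == 4
        # independent computation of G and its critical value
        g_expected = np.max(np.abs(d - d.mean())) / d.std(ddof=1)
        n = 5
        t2 = stats.t.ppf(1 - 0.05 / (2 * n), n - 2) ** 2
        crit_expected = (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))
        assert res.g_values[0] == pytest.approx(g_expected)
        assert res.critical_values[0] == pytest.approx(crit_expected)

    def test_constant_vector_degenerate(self):
        res = grubbs_scan(np.full(6, 0.2))
        assert res.outlier_indices == [] and res.degenerate

    def test_idempotent_on_cleaned_vector(self, rng):
        d = np.concatenate([rng.normal(0, 0.1, 40), [3.0]])
        first = grubbs_scan(d)
        cleaned = np.delete(d, first.outlier_indices)
        assert grubbs_scan(cleaned).outlier_indices == []


class TestDirectionalAsymmetry:
    def test_symmetric_vector_null(self):
        res = directional_asymmetry_test(np.array([-0.2, -0.1, 0.0, 0.1, 0.2]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_shifted_vector_detected_and_matches_closed_form(self):
        d = np.array([0.2, 0.25, 0.3, 0.22])
        res = directional_asymmetry_test(d)
        t_expected = d.mean() / (d.std(ddof=1) / 2.0)
        assert res.statistic == pytest.approx(t_expected)
        assert res.p < 0.05

    def test_zero_mean_huge_spread(self, rng):
        d = np.array([-5.0, 5.0, -4.0, 4.0, 0.0])
        assert directional_asymmetry_test(d).p > 0.9

    def test_constant_degenerate(self):
        assert directional_asymmetry_test(np.full(5, 0.1)).flag == "degenerate"


class TestAntisymmetry:
    def test_two_modes_platykurtic(self, rng):
        d = np.concatenate([rng.normal(-1, 0.1, 25), rng.normal(1, 0.1, 25)])
        res = antisymmetry_test(d)
        assert res.flagged
        # verify against an independent moment computation
        k_expected, _ = stats.kurtosistest(d)
        assert res.kurtosis_statistic == pytest.approx(k_expected)
        assert res.excess_kurtosis == pytest.approx(stats.kurtosis(d))
        assert res.excess_kurtosis < 0

    def test_normal_data_rarely_flagged(self):
        flags = 0
        for seed in range(100):
            d = np.random.default_rng(seed).normal(size=500)
            flags += antisymmetry_test(d).flagged
        assert flags <= 10  # ~alpha/2-level false positives, 90%+ clean

    def test_constant_degenerate(self):
        assert antisymmetry_test(np.full(10, 0.3)).flag == "degenerate"

    def test_minimum_n(self):
        with pytest.raises(InsufficientDataError):
            antisymmetry_test(np.arange(7.0))


class TestSizeDependence:
    def test_monotone_relationship(self):
        size = np.linspace(3, 7, 30)
        res = size_dependence_test(size * 0.01, size)
        assert res["pooled"].rho == pytest.approx(1.0)

    def test_independent_inputs_null(self, rng):
        size = np.linspace(3, 7, 200)
        abs_d = rng.permutation(size) * 0.01
        res = size_dependence_test(abs_d, size)
        assert abs(res["pooled"].rho) < 0.15
        assert res["pooled"].p > 0.05

    def test_small_group_skipped(self, rng):
        abs_d = rng.random(24)
        size = rng.random(24) + 3
        groups = np.array(["F"] * 20 + ["M"] * 4)
        res = size_dependence_test(abs_d, size, groups)
        assert res["M"].flag == "insufficient_n"
        assert res["F"].rho is not None


class TestHolm:
    def test_single_p_identity(self):
        adj, _ = holm_correct(np.array([0.03]))
        assert adj[0] == pytest.approx(0.03)

    def test_stepdown_worked_example(self):
        adj, rej = holm_correct(np.array([0.01, 0.04, 0.03]))
        assert adj == pytest.approx([0.03, 0.06, 0.06])
        assert list(rej) == [True, False, False]

    def test_all_ones(self):
        adj, rej = holm_correct(np.ones(5))
        assert np.all(adj == 1.0) and not rej.any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_correct(np.array([0.5, 1.2]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=12))
    def test_dominates_raw_and_order_invariant(self, ps):
        p = np.array(ps)
        adj, _ = holm_correct(p)
        assert np.all(adj >= p - 1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        adj_perm, _ = holm_correct(p[perm])
        assert adj_perm == pytest.approx(adj[perm])


class TestRunScreen:
    def test_injected_error_traits_are_the_exclusions(self, small_config):
        cfg = inject_pathology(small_config, "measurement_error", ["t03", "t07"], magnitude=3.0)
        cohort = generate(cfg)
        result = run_screen(to_trait_table(cohort.measurements), cohort.measurements)
        excluded = {r.trait_id for r in result.reports if not r.retained}
        assert excluded == {"t03", "t07"}

    def test_reports_ordered_and_summary_counts(self, small_cohort):
        result = run_screen(to_trait_table(small_cohort.measurements), small_cohort.measurements)
        assert [r.trait_id for r in result.reports] == sorted(r.trait_id for r in result.reports)
        assert "screened 10 traits" in result.summary()

    def test_null_cohort_keeps_all_traits(self, small_cohort):
        result = run_screen(to_trait_table(small_cohort.measurements), small_cohort.measurements)
        assert len(result.retained_traits) == 10

    def test_da_injection_reported_not_exclusionary_by_default(self, small_config):
        cfg = inject_pathology(small_config, "DA", ["t01"], magnitude=0.2)
        cohort = generate(cfg)
        traits = to_trait_table(cohort.measurements)
        result = run_screen(traits, cohort.measurements)
        rep = {r.trait_id: r for r in result.reports}
        assert rep["t01"].holm_adjusted_p["da"] < 0.05
        assert rep["t01"].retained
        strict = run_screen(traits, cohort.measurements, ScreenConfig(distributional_exclusions=True))
        assert "directional_asymmetry" in {r for rr in strict.reports if rr.trait_id == "t01" for r in rr.reasons}

    def test_antisymmetry_injection_flags_only_that_trait(self, small_config):
        flagged_target = 0
        false_flags = 0
        from dataclasses import replace

        for seed in range(10):
            cfg = replace(
                inject_pathology(small_config, "antisymmetry", ["t05"], magnitude=0.35),
                seed=100 + seed,
            )
            cohort = generate(cfg)
            result = run_screen(to_trait_table(cohort.measurements), cohort.measurements)
            for r in result.reports:
                holm_p = r.holm_adjusted_p.get("antisymmetry", 1.0)
                hit = r.antisymmetry is not None and r.antisymmetry.excess_kurtosis < 0 and holm_p < 0.05
                if r.trait_id == "t05":
                    flagged_target += hit
                else:
                    false_flags += hit
        assert flagged_target >= 9
        assert false_flags <= 2
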