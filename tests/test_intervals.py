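"""Unit tests for the closed-form interval constructors."""

import math

import pytest
from scipy import stats

from predint import (
    CorrelationStudy,
    DStudy,
    Interval,
    MeanStudy,
    ReplicationPlan,
    correlation_pi,
    correlation_pi_rtoz,
    correlation_pi_simple,
    d_ci_noncentral,
    d_pi,
    d_unbiased,
    fisher_ci,
    mean_ci,
    mean_pi,
    zou_combine,
)


class TestMeanIntervals:
    def test_ci_matches_published_report(self):
        ci = mean_ci(MeanStudy(98.59, 14.76, 50), 0.95)
        assert ci.lower == pytest.approx(94.40, abs=5e-3)
        assert ci.upper == pytest.approx(102.78, abs=5e-3)

    def test_ci_hand_computed_small_sample(self):
        # 5 +/- 2.262157 * 2/sqrt(10), critical value from a t table
        ci = mean_ci(MeanStudy(5, 2, 10), 0.95)
        assert ci.lower == pytest.approx(3.569286, abs=1e-5)
        assert ci.upper == pytest.approx(6.430714, abs=1e-5)

    def test_ci_half_width_approaches_normal_limit(self):
        n = 1_000_000
        ci = mean_ci(MeanStudy(0, 1, n), 0.95)
        assert ci.width / 2 == pytest.approx(1.959964 / math.sqrt(n), rel=1e-4)

    def test_pi_worked_example(self):
        pi = mean_pi(MeanStudy(98.59, 14.76, 50), ReplicationPlan(n_rep=100))
        assert pi.lower == pytest.approx(93.45, abs=5e-3)
        assert pi.upper == pytest.approx(103.73, abs=5e-3)
        assert pi.width / 2 == pytest.approx(5.14, abs=5e-3)

    def test_pi_approaches_ci_as_replication_grows(self):
        study = MeanStudy(10, 3, 40)
        ci = mean_ci(study)
        pi = mean_pi(study, ReplicationPlan(n_rep=10_000_000))
        assert pi.lower == pytest.approx(ci.lower, abs=1e-3)
        assert pi.upper == pytest.approx(ci.upper, abs=1e-3)

    def test_equal_n_reduces_to_sqrt_two_over_n_form(self):
        # At N1 = N2 = N the PI half-width is t_{N-1} * SD * sqrt(2/N)
        pi = mean_pi(MeanStudy(0, 15, 25), ReplicationPlan(n_rep=25))
        expected = stats.t.ppf(0.975, 24) * 15 * math.sqrt(2 / 25)
        assert pi.width / 2 == pytest.approx(expected, abs=1e-12)


class TestFisherCI:
    @pytest.mark.parametrize(
        "n, lower, upper",
        [(100, 0.1649195, 0.5112702), (200, 0.2220412, 0.4661072)],
    )
    def test_seven_digit_bounds(self, n, lower, upper):
        ci = fisher_ci(CorrelationStudy(0.35, n), 0.95)
        assert ci.lower == pytest.approx(lower, abs=1e-6)
        assert ci.upper == pytest.approx(upper, abs=1e-6)

    def test_symmetric_about_zero_for_null_r(self):
        ci = fisher_ci(CorrelationStudy(0.0, 30), 0.95)
        assert ci.lower == pytest.approx(-ci.upper, abs=1e-15)

    def test_bounds_inside_unit_interval_for_extreme_r(self):
        ci = fisher_ci(CorrelationStudy(0.999, 5), 0.99)
        assert -1 < ci.lower < ci.upper < 1


class TestZouCombine:
    def test_correlation_worked_example(self):
        pi = zou_combine(
            0.35,
            Interval(0.1649195, 0.5112702, 0.95),
            Interval(0.2220412, 0.4661072, 0.95),
        )
        assert pi.lower == pytest.approx(0.1315151, abs=1e-6)
        assert pi.upper == pytest.approx(0.5558678, abs=1e-6)

    def test_d_worked_example(self):
        ci = Interval(0.2460344, 1.050815, 0.95)
        pi = zou_combine(0.65, ci, ci)
        assert pi.lower == pytest.approx(0.08093008, abs=1e-6)
        assert pi.upper == pytest.approx(1.21907, abs=1e-5)

    def test_symmetric_components_scale_by_sqrt_two(self):
        h = 0.3
        ci = Interval(1.0 - h, 1.0 + h, 0.9)
        pi = zou_combine(1.0, ci, ci)
        assert pi.width / 2 == pytest.approx(h * math.sqrt(2), abs=1e-12)

    def test_rejects_point_outside_component(self):
        with pytest.raises(ValueError, match="outside"):
            zou_combine(2.0, Interval(0, 1, 0.95), Interval(0, 1, 0.95))

    def test_rejects_mismatched_levels(self):
        with pytest.raises(ValueError, match="level"):
            zou_combine(0.5, Interval(0, 1, 0.95), Interval(0, 1, 0.90))


class TestCorrelationPI:
    def test_worked_example_two_decimals(self):
        pi = correlation_pi(
            CorrelationStudy(0.35, 100), ReplicationPlan(n_rep=200)
        )
        assert round(pi.lower, 2) == 0.13
        assert round(pi.upper, 2) == 0.56

    def test_small_original_large_replication(self):
        pi = correlation_pi(
            CorrelationStudy(0.30, 50), ReplicationPlan(n_rep=1000)
        )
        assert round(pi.lower, 2) == 0.02
        assert round(pi.upper, 2) == 0.54

    def test_equal_n_components_give_symmetric_arm_pairing(self):
        study = CorrelationStudy(0.4, 80)
        ci = fisher_ci(study)
        pi = correlation_pi(study, ReplicationPlan(n_rep=80))
        assert pi.lower == pytest.approx(
            0.4 - math.hypot(0.4 - ci.lower, ci.upper - 0.4), abs=1e-12
        )
        assert pi.upper == pytest.approx(
            0.4 + math.hypot(0.4 - ci.lower, ci.upper - 0.4), abs=1e-12
        )

    def test_simple_asymptotic_is_symmetric(self):
        pi = correlation_pi_simple(
            CorrelationStudy(0.0, 101), ReplicationPlan(n_rep=101)
        )
        assert pi.upper == pytest.approx(0.2771808, abs=1e-6)
        assert pi.lower == pytest.approx(-0.2771808, abs=1e-6)

    def test_simple_asymptotic_loses_asymmetry_at_large_r(self):
        study = CorrelationStudy(0.9, 50)
        plan = ReplicationPlan(n_rep=50)
        simple = correlation_pi_simple(study, plan)
        zou = correlation_pi(study, plan)
        # the symmetric interval under-reaches on the heavy (lower) side
        assert simple.lower > zou.lower
        assert simple.upper - 0.9 == pytest.approx(0.9 - simple.lower, abs=1e-12)

    def test_rtoz_close_to_zou_at_moderate_r(self):
        study = CorrelationStudy(0.35, 100)
        plan = ReplicationPlan(n_rep=200)
        a = correlation_pi_rtoz(study, plan)
        b = correlation_pi(study, plan)
        assert abs(a.lower - b.lower) < 0.02
        assert abs(a.upper - b.upper) < 0.02
        assert (a.lower, a.upper) != (b.lower, b.upper)

    def test_rtoz_converges_to_fisher_ci(self):
        study = CorrelationStudy(0.35, 100)
        big = correlation_pi_rtoz(study, ReplicationPlan(n_rep=5_000_000))
        ci = fisher_ci(study)
        assert big.lower == pytest.approx(ci.lower, abs=1e-3)
        assert big.upper == pytest.approx(ci.upper, abs=1e-3)


class TestDIntervals:
    def test_noncentral_ci_worked_example(self):
        ci = d_ci_noncentral(DStudy(0.65, 50, 50), 0.95)
        assert ci.lower == pytest.approx(0.2460344, abs=1e-6)
        assert ci.upper == pytest.approx(1.050815, abs=1e-6)

    def test_null_d_gives_symmetric_ci(self):
        ci = d_ci_noncentral(DStudy(0.0, 30, 30), 0.95)
        assert ci.lower == pytest.approx(-ci.upper, abs=1e-7)

    def test_noncentral_ci_against_grid_inversion(self):
        # independent oracle: brute-force grid search over the ncp axis
        import numpy as np

        study = DStudy(0.65, 100, 100)
        ci = d_ci_noncentral(study, 0.95)
        scale = math.sqrt(1 / 100 + 1 / 100)
        t_obs = 0.65 / scale
        grid = np.linspace(t_obs - 8, t_obs + 8, 2_000_001)
        cdf = stats.nct.cdf(t_obs, 198, grid)
        ncp_u = grid[int(np.argmin(np.abs(cdf - 0.025)))]
        ncp_l = grid[int(np.argmin(np.abs(cdf - 0.975)))]
        assert ci.upper == pytest.approx(ncp_u * scale, abs=1e-5)
        assert ci.lower == pytest.approx(ncp_l * scale, abs=1e-5)

    @pytest.mark.parametrize(
        "rep, lower, upper",
        [((50, 50), 0.08, 1.22), ((100, 100), 0.16, 1.14)],
    )
    def test_pi_worked_examples(self, rep, lower, upper):
        pi = d_pi(
            DStudy(0.65, 50, 50),
            ReplicationPlan(n1_rep=rep[0], n2_rep=rep[1]),
        )
        assert round(pi.lower, 2) == lower
        assert round(pi.upper, 2) == upper

    def test_pi_collapses_to_ci_for_huge_replication(self):
        study = DStudy(0.65, 50, 50)
        ci = d_ci_noncentral(study)
        pi = d_pi(study, ReplicationPlan(n1_rep=500_000, n2_rep=500_000))
        assert pi.lower == pytest.approx(ci.lower, abs=2e-3)
        assert pi.upper == pytest.approx(ci.upper, abs=2e-3)

    def test_hedges_correction(self):
        assert d_unbiased(0.0, 10) == 0.0
        assert d_unbiased(1.0, 98) == pytest.approx(1 - 3 / 391, abs=1e-12)
        assert d_unbiased(0.5, 10_000_000) == pytest.approx(0.5, rel=1e-6)
        assert abs(d_unbiased(-0.8, 8)) < 0.8


class TestValidation:
    @pytest.mark.parametrize("level", [0.0, 1.0, -0.1, 1.5])
    def test_bad_levels_rejected(self, level):
        with pytest.raises(ValueError):
            mean_ci(MeanStudy(0, 1, 10), level)

    def test_degenerate_studies_rejected(self):
        with pytest.raises(ValueError):
            MeanStudy(0, 0.0, 10)  # zero SD
        with pytest.raises(ValueError):
            MeanStudy(0, 1, 1)
        with pytest.raises(ValueError):
            CorrelationStudy(1.0, 50)  # |r| = 1
        with pytest.raises(ValueError):
            CorrelationStudy(0.5, 3)  # Fisher SE undefined
        with pytest.raises(ValueError):
            DStudy(0.5, 2, 2)  # df too small
        with pytest.raises(ValueError):
            d_unbiased(0.5, 0)

    def test_replication_plan_shape_mismatch(self):
        with pytest.raises(ValueError):
            mean_pi(MeanStudy(0, 1, 10), ReplicationPlan(n1_rep=5, n2_rep=5))
        with pytest.raises(ValueError):
            d_pi(DStudy(0.5, 10, 10), ReplicationPlan(n_rep=20))

    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            Interval(1.0, 0.0, 0.95)
        with pytest.raises(ValueError):
            Interval(0.0, 1.0, 1.0)
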