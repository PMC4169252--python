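"""Robust null fitting, interval construction and efficiency classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from kindeg import (
    Call,
    NullModel,
    RatioPair,
    classify,
    classify_table,
    correct_ratios,
    fit_null,
    interval,
    robust_location_scale,
)

PAPER_NULL = NullModel(mu_a=-0.003, sd_a=0.1451, mu_b=0.009, sd_b=0.1871)


class TestRobustLocationScale:
    def test_constant_input_uses_degenerate_fallback(self):
        with pytest.warns(RuntimeWarning, match="MAD is zero"):
            loc, scale = robust_location_scale([0.5, 0.5, 0.5, 0.5])
        assert loc == 0.5
        assert scale == 0.0

    def test_symmetric_triple(self):
        loc, _ = robust_location_scale([-1.0, 0.0, 1.0])
        assert loc == pytest.approx(0.0, abs=1e-12)

    def test_monte_carlo_recovery(self):
        """10^5 normal(0.2, 0.3) draws recover both parameters within +-0.01."""
        rng = np.random.default_rng(42)
        loc, scale = robust_location_scale(rng.normal(0.2, 0.3, 10**5))
        assert loc == pytest.approx(0.2, abs=0.01)
        assert scale == pytest.approx(0.3, abs=0.01)

    def test_agrees_with_mean_sd_without_outliers(self):
        """Huber estimates track mean/sd within 2% relative on clean normal data."""
        rng = np.random.default_rng(7)
        x = rng.normal(1.0, 0.5, 10**4)
        loc, scale = robust_location_scale(x)
        assert abs(loc - x.mean()) / abs(x.mean()) < 0.02
        assert abs(scale - x.std(ddof=1)) / x.std(ddof=1) < 0.02

    def test_resists_outliers(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0.0, 0.15, 500), np.full(25, 8.0)])
        loc, scale = robust_location_scale(x)
        assert abs(loc) < 0.05
        assert scale < 0.25  # plain sd would be ~1.8

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            robust_location_scale([1.0, 2.0])


class TestFitNull:
    def test_recovers_study_null_at_n541(self):
        """Pairs drawn from the fitted-null normals are recovered at study size."""
        rng = np.random.default_rng(2026)
        pairs = np.column_stack(
            [rng.normal(-0.003, 0.1451, 541), rng.normal(0.009, 0.1871, 541)]
        )
        null = fit_null([RatioPair(a, b) for a, b in pairs])
        # Monte-Carlo tolerance ~ 3 * sd / sqrt(541) for the location
        assert null.mu_a == pytest.approx(-0.003, abs=0.02)
        assert null.sd_a == pytest.approx(0.1451, abs=0.02)
        assert null.mu_b == pytest.approx(0.009, abs=0.025)
        assert null.sd_b == pytest.approx(0.1871, abs=0.025)
        assert null.n_fit == 541

    def test_identical_axes_identical_models(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0.1, 0.2, 100)
        null = fit_null([RatioPair(v, v) for v in vals])
        assert null.mu_a == null.mu_b
        assert null.sd_a == null.sd_b

    def test_arithmetic_progression_location_is_middle(self):
        null = fit_null([RatioPair(v, v) for v in (0.1, 0.2, 0.3)])
        assert null.mu_a == pytest.approx(0.2, abs=1e-9)


class TestCorrectRatios:
    def test_shift_removal(self):
        rng = np.random.default_rng(11)
        raw = [RatioPair(v + 0.1, w + 0.1) for v, w in rng.normal(0, 0.15, (200, 2))]
        null = fit_null(raw)
        corrected = correct_ratios(raw, null)
        refit = fit_null(corrected)
        assert refit.mu_a == pytest.approx(0.0, abs=0.01)
        assert refit.mu_b == pytest.approx(0.0, abs=0.01)

    def test_zero_mean_null_is_identity(self):
        null = NullModel(0.0, 0.1, 0.0, 0.1)
        pairs = [RatioPair(0.3, -0.2)]
        assert correct_ratios(pairs, null) == pairs

    def test_single_pair_subtraction(self):
        (out,) = correct_ratios([RatioPair(0.097, -0.009)], PAPER_NULL)
        assert out.axis_a == pytest.approx(0.100, abs=1e-12)
        assert out.axis_b == pytest.approx(-0.018, abs=1e-12)

    def test_none_passes_through(self):
        assert correct_ratios([None], PAPER_NULL) == [None]


class TestInterval:
    def test_98_interval_of_study_null(self):
        """Two-sided central 98% interval: mu +- 2.3263 sd, to 4 decimals."""
        lo, hi = interval(PAPER_NULL, "a")
        assert lo == pytest.approx(-0.3406, abs=5e-5)
        assert hi == pytest.approx(0.3346, abs=5e-5)

    def test_width_monotone_in_coverage(self):
        widths = []
        for cov in (0.5, 0.9, 0.98, 0.999, 0.999999):
            null = NullModel(0.0, 1.0, 0.0, 1.0, coverage=cov)
            lo, hi = interval(null, "a")
            widths.append(hi - lo)
        assert all(w1 < w2 for w1, w2 in zip(widths, widths[1:]))

    def test_halfwidth_linear_in_scale(self):
        n1 = NullModel(0.0, 0.2, 0.0, 0.2)
        n2 = NullModel(0.0, 0.1, 0.0, 0.1)
        assert interval(n1, "a")[1] == pytest.approx(2 * interval(n2, "a")[1])


class TestClassify:
    def test_center_is_efficient(self):
        assert classify(RatioPair(0.0, 0.0), PAPER_NULL).call is Call.EFFICIENT

    def test_large_ratios_are_bystander(self):
        """(1.585, 1.0) = a still-accumulating neo-N-terminus, far outside the null."""
        call = classify(RatioPair(1.585, 1.0), PAPER_NULL)
        assert call.call is Call.BYSTANDER
        assert not call.inside_a and not call.inside_b

    def test_boundary_is_inclusive(self):
        _, hi = interval(PAPER_NULL, "a")
        call = classify(RatioPair(float(hi), 0.0), PAPER_NULL)
        assert call.call is Call.EFFICIENT

    def test_one_axis_outside_is_bystander(self):
        call = classify(RatioPair(0.0, 1.0), PAPER_NULL)
        assert call.call is Call.BYSTANDER
        assert call.inside_a and not call.inside_b

    def test_missing_ratio_is_unclassifiable(self):
        assert classify(None, PAPER_NULL).call is Call.UNCLASSIFIABLE

    def test_ellipse_region_center_and_far(self):
        assert classify(RatioPair(0.0, 0.0), PAPER_NULL, region="ellipse").call is Call.EFFICIENT
        assert classify(RatioPair(2.0, 2.0), PAPER_NULL, region="ellipse").call is Call.BYSTANDER

    @given(st.floats(-1.5, 1.5), st.floats(-1.5, 1.5))
    def test_enlarging_coverage_never_flips_efficient_to_bystander(self, a, b):
        small = NullModel(0.0, 0.15, 0.0, 0.19, coverage=0.90)
        large = NullModel(0.0, 0.15, 0.0, 0.19, coverage=0.99)
        if classify(RatioPair(a, b), small).call is Call.EFFICIENT:
            assert classify(RatioPair(a, b), large).call is Call.EFFICIENT


class TestClassifyTable:
    def test_noiseless_planted_classes(self):
        """9 events at the null center and 28 far outside give exactly (9, 28, 0)."""
        events = [(None, RatioPair(-0.003, 0.009))] * 9
        events += [(None, RatioPair(1.3, 0.6))] * 28
        _, summary = classify_table(events, PAPER_NULL)
        assert (summary.n_efficient, summary.n_bystander, summary.n_unclassifiable) == (9, 28, 0)

    def test_empty_events(self):
        _, summary = classify_table([], PAPER_NULL)
        assert (summary.n_efficient, summary.n_bystander, summary.n_unclassifiable) == (0, 0, 0)

    def test_missing_ratio_counted_unclassifiable(self):
        _, summary = classify_table([(None, None)], PAPER_NULL)
        assert summary.n_unclassifiable == 1

    def test_summary_consistent_with_calls(self):
        rng = np.random.default_rng(9)
        events = [(None, RatioPair(a, b)) for a, b in rng.normal(0, 0.5, (50, 2))]
        calls, summary = classify_table(events, PAPER_NULL)
        assert summary.n_efficient == sum(c.call is Call.EFFICIENT for c in calls)
        assert summary.total == 50


class TestCalibration:
    def test_per_axis_and_joint_coverage(self):
        """Draws from the null land inside the interval at the nominal rate.

        10^6 draws per axis: per-axis containment 98% and joint containment
        coverage^2 = 96.04%, both within 3 binomial standard errors.
        """
        rng = np.random.default_rng(123)
        n = 10**6
        a = rng.normal(PAPER_NULL.mu_a, PAPER_NULL.sd_a, n)
        b = rng.normal(PAPER_NULL.mu_b, PAPER_NULL.sd_b, n)
        lo_a, hi_a = interval(PAPER_NULL, "a")
        lo_b, hi_b = interval(PAPER_NULL, "b")
        in_a = (a >= lo_a) & (a <= hi_a)
        in_b = (b >= lo_b) & (b <= hi_b)
        tol = 3 * np.sqrt(0.98 * 0.02 / n)
        assert abs(in_a.mean() - 0.98) < tol
        assert abs(in_b.mean() - 0.98) < tol
        tol_joint = 3 * np.sqrt(0.9604 * (1 - 0.9604) / n)
        assert abs((in_a & in_b).mean() - 0.9604) < tol_joint

    def test_shift_equivariance_of_calls(self):
        """Adding a constant to one raw axis changes no call after fit + correct."""
        rng = np.random.default_rng(77)
        ann = [RatioPair(a, b) for a, b in rng.normal(0, 0.15, (300, 2))]
        neo = [RatioPair(a, b) for a, b in rng.normal(0.8, 0.15, (30, 2))]

        def run(shift):
            ann_s = [RatioPair(p.axis_a + shift, p.axis_b) for p in ann]
            neo_s = [RatioPair(p.axis_a + shift, p.axis_b) for p in neo]
            null = fit_null(ann_s)
            corrected = correct_ratios(neo_s, null)
            calls, _ = classify_table([(None, r) for r in corrected], fit_null(correct_ratios(ann_s, null)))
            return [c.call for c in calls]

        assert run(0.0) == run(2.5)
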