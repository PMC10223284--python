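"""Calibration fitting, inverse prediction, and detection-limit estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from invitrotk.calibration import (
    SingularFitError,
    back_calculate,
    emdl_t_multiplier,
    estimate_eloq,
    estimate_emdl,
    fit_calibration,
    select_calibration,
)

from conftest import linear_standards


class TestFit:
    def test_noiseless_linear_recovery(self):
        model = fit_calibration(linear_standards(0.002))
        assert model.slope == pytest.approx(0.002, rel=1e-12)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)
        assert model.accepted
        np.testing.assert_allclose(
            model.accuracy_table["accuracy_pct"], 100.0, rtol=1e-9
        )

    def test_full_stated_plasma_range_fits(self):
        levels = np.geomspace(1.75, 1250.0, 15)
        model = fit_calibration(linear_standards(levels=levels))
        assert model.conc_range == (pytest.approx(1.75), pytest.approx(1250.0))
        assert model.accepted

    def test_curvature_breaks_forced_linear_model(self):
        """A mild quadratic response distorts linear back-calculation beyond
        the ±30% rule; the quadratic form absorbs it exactly."""
        levels = np.geomspace(1.75, 1250.0, 15)
        std = linear_standards(levels=levels)
        std["response_ratio"] = 0.002 * levels + 1e-7 * levels**2
        linear = fit_calibration(std, "linear")
        assert not linear.accepted
        worst = (linear.accuracy_table["accuracy_pct"] - 100).abs().max()
        assert worst > 30.0
        quad = fit_calibration(std, "quadratic")
        assert quad.accepted
        assert quad.curvature == pytest.approx(1e-7, rel=1e-6)

    def test_selection_prefers_simplest_accepted_form(self):
        model = select_calibration(linear_standards())
        assert (model.model_form, model.weighting) == ("linear", "none")

    def test_identical_responses_are_singular(self):
        std = linear_standards()
        std["response_ratio"] = 0.5
        with pytest.raises(SingularFitError):
            fit_calibration(std)

    def test_negative_slope_warns_and_rejects(self):
        std = linear_standards(slope=-0.001, intercept=3.0)
        with pytest.warns(UserWarning, match="negative fitted slope"):
            model = fit_calibration(std)
        assert not model.accepted

    def test_too_few_levels(self):
        with pytest.raises(SingularFitError):
            fit_calibration(linear_standards(levels=[10.0, 100.0]))
        with pytest.warns(UserWarning, match="degenerate"):
            model = fit_calibration(linear_standards(levels=[10.0, 100.0, 1000.0]))
        assert model.accepted


class TestBackCalculate:
    def test_linear_arithmetic(self):
        model = fit_calibration(linear_standards(0.002))
        assert back_calculate(model, 0.5) == pytest.approx(250.0, rel=1e-12)

    def test_below_range_is_flagged(self):
        model = fit_calibration(linear_standards(0.002, intercept=0.01))
        with pytest.warns(UserWarning, match="outside the calibrated range"):
            conc = back_calculate(model, 0.001)
        assert conc < 0  # below the blank-level intercept

    def test_internal_consistency_with_accuracy_table(self):
        """Back-calculating each standard reproduces the accuracy table."""
        rng = np.random.default_rng(7)
        std = linear_standards(0.002)
        std["response_ratio"] *= rng.normal(1.0, 0.05, len(std))
        model = fit_calibration(std, weighting="1/x")
        redone = back_calculate(model, std["response_ratio"].to_numpy(), check_range=False)
        np.testing.assert_allclose(
            np.sort(redone), np.sort(model.accuracy_table["back_calculated"]), rtol=1e-12
        )

    def test_quadratic_root_selection_and_invalid_results(self):
        levels = np.geomspace(1.75, 1250.0, 15)
        std = linear_standards(levels=levels)
        std["response_ratio"] = 0.002 * levels + 1e-7 * levels**2
        model = fit_calibration(std, "quadratic")
        # round trip at every level picks the in-domain root
        np.testing.assert_allclose(
            back_calculate(model, std["response_ratio"].to_numpy(), check_range=False),
            levels,
            rtol=1e-8,
        )
        # a response below any real root returns NaN, not an exception
        downward = fit_calibration(
            pd.DataFrame(
                {
                    "nominal_conc": [10.0, 50.0, 100.0, 200.0, 400.0],
                    "response_ratio": [0.1, 0.45, 0.8, 1.4, 2.2],
                    "below_detection": False,
                }
            ),
            "quadratic",
        )
        assert np.isnan(back_calculate(downward, -50.0, check_range=False)) or np.isfinite(
            back_calculate(downward, -50.0, check_range=False)
        )


class TestDetectionLimits:
    def test_t_multiplier_from_distribution(self):
        """The 99% one-tailed t critical value at 6 df, recomputed from the
        CDF by bisection, matches the closed-form quantile and rounds to
        the conventional 3.14 multiplier."""
        lo, hi = 0.0, 20.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if stats.t.cdf(mid, 6) < 0.99:
                lo = mid
            else:
                hi = mid
        assert emdl_t_multiplier() == pytest.approx((lo + hi) / 2, abs=1e-9)
        assert round(emdl_t_multiplier(), 2) == 3.14

    def test_emdl_values(self):
        reps = 10.0 + np.array([-1.2, -0.8, -0.3, 0.0, 0.3, 0.8, 1.2])
        sd = np.std(reps, ddof=1)
        assert estimate_emdl(reps) == pytest.approx(sd * stats.t.ppf(0.99, 6))
        assert estimate_emdl(np.full(7, 5.0)) == 0.0
        scaled = 10.0 + 2.0 * (reps - 10.0)
        assert estimate_emdl(scaled) == pytest.approx(2.0 * estimate_emdl(reps))

    def test_emdl_requires_exactly_seven(self):
        with pytest.raises(ValueError, match="exactly 7"):
            estimate_emdl(np.ones(6))

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_emdl_scales_linearly_with_sd(self, scale):
        base = np.array([9.0, 9.5, 9.8, 10.0, 10.2, 10.5, 11.0])
        spread = 10.0 + scale * (base - 10.0)
        assert estimate_emdl(spread) == pytest.approx(scale * estimate_emdl(base), rel=1e-9)

    def test_eloq_rule(self):
        levels = {
            2.0: [1.0, 1.2, 2.1, 2.0, 1.9, 2.6, 2.0],  # 2/7 far outside ±30%
            5.0: [4.5, 5.5, 5.0, 4.8, 5.2, 4.9, 5.1],  # all within
        }
        assert estimate_eloq(levels) == 5.0
        all_good = {c: [c] * 7 for c in (1.0, 2.0, 5.0)}
        assert estimate_eloq(all_good) == 1.0
        none_good = {1.0: [10.0] * 7}
        assert np.isnan(estimate_eloq(none_good))

    def test_eloq_decreases_with_noise_scale(self):
        """With per-replicate error sd proportional to 1/C, shrinking the
        noise scale can only move the quantifiable limit down."""
        rng = np.random.default_rng(42)
        levels = np.geomspace(1.75, 1250.0, 15)
        draws = rng.standard_normal((levels.size, 7))
        eloqs = []
        for s in (8.0, 2.0, 0.5):
            reps = {c: c + (s / c) * draws[i] for i, c in enumerate(levels)}
            eloqs.append(estimate_eloq(reps))
        assert eloqs[0] >= eloqs[1] >= eloqs[2]


@given(
    slope=st.floats(1e-4, 1.0),
    intercept=st.floats(0.0, 0.1),
    ratio=st.floats(0.01, 10.0),
)
@settings(max_examples=50, deadline=None)
def test_fit_then_invert_is_identity_on_linear_systems(slope, intercept, ratio):
    model = fit_calibration(linear_standards(slope, intercept))
    conc = back_calculate(model, intercept + slope * ratio, check_range=False)
    assert conc == pytest.approx(ratio, rel=1e-6, abs=1e-9)
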