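"""Two-state DSC pipeline: baseline, enthalpies, fit, regression, Gibbs-Helmholtz."""

import numpy as np
import pytest

from sptdsc.constants import R, T_CELSIUS_OFFSET
from sptdsc.dsc import (
    BaselineError,
    Thermogram,
    calorimetric_enthalpy,
    cooperative_unit,
    cp_regression,
    fit_two_state,
    gibbs_helmholtz,
    scan_area_difference,
    subtract_baseline,
    two_state_excess_cp,
)
from sptdsc.synthetic import SyntheticSpec, generate


def exact_curve(t_d=63.4, dh=448.0, **kw):
    curve, _ = generate(SyntheticSpec(t_d=t_d, dh_vh=dh, noise_sd=0.0, **kw))
    return curve


class TestBaseline:
    def test_recovers_known_linear_baseline(self):
        curve = exact_curve(baseline_intercept=4.0, baseline_slope=0.02)
        excess, (b0, b1) = subtract_baseline(curve, (20.0, 40.0))
        assert b1 == pytest.approx(0.02, rel=0.05)
        assert b0 == pytest.approx(4.0, rel=0.05)

    def test_zero_baseline_leaves_curve_unchanged(self):
        curve = exact_curve()
        excess, _ = subtract_baseline(curve, (20.0, 40.0))
        # the fitted line absorbs only the ~1e-3 kJ/K/mol pre-transition wing
        assert np.allclose(excess.cp, curve.cp, atol=5e-3)

    def test_pure_baseline_curve_gives_zero_excess(self):
        t = np.arange(20.0, 90.0, 0.5)
        flat = Thermogram(temperature=t, cp=2.0 + 0.01 * t)
        excess, _ = subtract_baseline(flat, (20.0, 40.0))
        assert np.allclose(excess.cp, 0.0, atol=1e-10)

    def test_window_outside_data_rejected(self):
        curve = exact_curve()
        with pytest.raises(BaselineError, match="outside"):
            subtract_baseline(curve, (0.0, 10.0))

    def test_window_with_too_few_points_rejected(self):
        curve = exact_curve()
        with pytest.raises(BaselineError, match=">= 5"):
            subtract_baseline(curve, (20.0, 20.3))


class TestCalorimetricEnthalpy:
    def test_two_state_curve_integrates_to_its_enthalpy(self):
        curve = exact_curve(t_d=63.4, dh=448.0)
        assert calorimetric_enthalpy(curve) == pytest.approx(448.0, rel=0.01)

    def test_zero_curve_and_linearity(self):
        t = np.arange(20.0, 90.0, 0.5)
        assert calorimetric_enthalpy(Thermogram(t, np.zeros_like(t))) == 0.0
        curve = exact_curve()
        doubled = Thermogram(curve.temperature, 2.0 * curve.cp)
        assert calorimetric_enthalpy(doubled) == pytest.approx(
            2.0 * calorimetric_enthalpy(curve), rel=1e-12
        )

    def test_truncated_tail_warns(self):
        curve = exact_curve(t_d=63.4, dh=448.0)
        half = Thermogram(curve.temperature[:450], curve.cp[:450])
        with pytest.warns(UserWarning, match="decay"):
            calorimetric_enthalpy(half)


class TestTwoStateFit:
    def test_noiseless_recovery_to_four_significant_figures(self):
        curve = exact_curve(t_d=63.4, dh=448.0)
        params, diag = fit_two_state(curve)
        assert params.t_d == pytest.approx(63.4 + T_CELSIUS_OFFSET, rel=5e-4)
        assert params.dh_vh == pytest.approx(448.0, rel=5e-4)
        assert diag["residual_norm"] < 1e-6

    def test_peak_height_matches_closed_form(self):
        t_d = 336.55
        cp = two_state_excess_cp(np.array([t_d]), t_d, 448.0)
        expected = 448000.0**2 / (4 * R * t_d**2) / 1000.0  # ~53.3 kJ/K/mol
        assert cp[0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(53.3, abs=0.1)

    def test_noisy_recovery_within_stated_errors(self):
        curve, truth = generate(
            SyntheticSpec(t_d=63.4, dh_vh=448.0, noise_sd=1.0, seed=11)
        )
        params, _ = fit_two_state(curve)
        assert abs(params.t_d - (63.4 + T_CELSIUS_OFFSET)) < 0.2
        assert params.dh_vh == pytest.approx(448.0, rel=0.05)

    def test_kirchhoff_variant_steps_to_dcp(self):
        T = np.array([280.0, 400.0])
        cp = two_state_excess_cp(T, 336.55, 448.0, kirchhoff_dcp=6.4)
        assert cp[0] == pytest.approx(0.0, abs=1e-6)  # folded side
        assert cp[1] == pytest.approx(6.4, abs=0.05)  # unfolded plateau


class TestCooperativeUnit:
    def test_ratio_and_two_state_band(self):
        assert cooperative_unit(448.0, 448.0) == 1.0
        assert cooperative_unit(320.0, 340.0) == pytest.approx(0.94, abs=0.005)

    def test_nonpositive_vant_hoff_rejected(self):
        with pytest.raises(ValueError):
            cooperative_unit(400.0, 0.0)

    def test_end_to_end_synthetic_cu_is_unity(self):
        curve = exact_curve(baseline_intercept=3.0, baseline_slope=0.015)
        excess, _ = subtract_baseline(curve, (20.0, 40.0))
        params, _ = fit_two_state(excess)
        cu = cooperative_unit(calorimetric_enthalpy(excess), params.dh_vh)
        assert cu == pytest.approx(1.0, abs=0.02)


class TestCpRegression:
    def test_two_point_line_and_collinear_r(self):
        slope = cp_regression([(300.0, 100.0), (310.0, 164.0), (305.0, 132.0)]).slope
        assert slope == pytest.approx(6.4, rel=1e-12)
        r = cp_regression([(300.0, 10.0), (310.0, 20.0), (320.0, 30.0)]).r
        assert r == pytest.approx(1.0)

    def test_invariant_to_ordering_and_abscissa_shift(self):
        pts = [(300.0, 100.0), (320.0, 230.0), (310.0, 170.0), (305.0, 131.0)]
        a = cp_regression(pts)
        b = cp_regression(list(reversed(pts)))
        shifted = cp_regression([(t - T_CELSIUS_OFFSET, h) for t, h in pts])
        assert a.slope == pytest.approx(b.slope)
        assert a.slope == pytest.approx(shifted.slope)

    def test_degenerate_abscissa_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            cp_regression([(300.0, 1.0), (300.0, 2.0), (300.0, 3.0)])


class TestGibbsHelmholtz:
    @pytest.mark.parametrize(
        "td_c, dh, expected",
        [(68.4, 446.0, 38), (53.9, 427.0, 29)],  # trehalose / TMU rows
    )
    def test_published_stability_values(self, td_c, dh, expected):
        dg = gibbs_helmholtz(td_c + T_CELSIUS_OFFSET, dh, 6.4, 298.15)
        assert round(dg) == expected

    def test_zero_at_midpoint_and_dcp_free_reduction(self):
        assert gibbs_helmholtz(340.0, 400.0, 6.4, 340.0) == 0.0
        assert gibbs_helmholtz(340.0, 400.0, 0.0, 300.0) == pytest.approx(
            400.0 * (1 - 300.0 / 340.0)
        )

    def test_positive_below_midpoint(self):
        for T in (280.0, 298.15, 320.0):
            assert gibbs_helmholtz(335.0, 420.0, 6.4, T) > 0.0


def test_scan_area_difference_reversibility_plumbing():
    first = exact_curve()
    second = Thermogram(first.temperature, 0.9 * first.cp)
    assert scan_area_difference(first, second) == pytest.approx(0.1, rel=1e-9)
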