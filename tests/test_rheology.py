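"""Casson constitutive law, fitting, and group-summary behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemoflow.rheology import (
    CassonParams,
    RegularizationConfig,
    RheologyError,
    ViscosityCurve,
    apparent_viscosity,
    casson_from_two_viscosities,
    casson_shear_stress,
    fit_casson,
    group_viscosity_summary,
    interpolate_viscosity,
    percent_difference,
    percent_difference_truncated,
    read_viscosity_csv,
    write_viscosity_csv,
)

REG = RegularizationConfig()


class TestCassonShearStress:
    @pytest.mark.parametrize("tau_y,k,gdot,expected", [
        (0.0, 0.0035, 100.0, 0.35),                 # Newtonian limit tau = k*gdot
        (0.02, 0.0035, 0.0, 0.02),                  # yield stress at rest
        # direct expansion (sqrt(ty) + sqrt(k g))^2 = ty + k g + 2 sqrt(ty k g)
        (0.01, 0.003, 100.0, 0.01 + 0.3 + 2.0 * np.sqrt(0.01 * 0.3)),
    ])
    def test_known_values(self, tau_y, k, gdot, expected):
        assert casson_shear_stress(CassonParams(tau_y, k), gdot) == pytest.approx(
            expected, rel=1e-12)

    def test_negative_shear_rate_rejected(self):
        with pytest.raises(RheologyError):
            casson_shear_stress(CassonParams(0.01, 0.003), -1.0)

    @given(tau_y=st.floats(0.0, 0.1), k=st.floats(1e-4, 0.05))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_shear_rate(self, tau_y, k):
        g = np.linspace(0.0, 1000.0, 200)
        tau = casson_shear_stress(CassonParams(tau_y, k), g)
        assert np.all(np.diff(tau) >= -1e-12)


class TestApparentViscosity:
    def test_newtonian_limit_is_constant_k(self):
        mu = apparent_viscosity(CassonParams(0.0, 0.0035),
                                np.array([0.01, 1.0, 100.0, 1000.0]), REG)
        assert np.allclose(mu, 0.0035, rtol=1e-14)

    def test_equals_stress_over_rate(self):
        p = CassonParams(0.01, 0.003)
        got = apparent_viscosity(p, 100.0, REG)
        assert got == pytest.approx(casson_shear_stress(p, 100.0) / 100.0, rel=1e-12)

    def test_clamped_below_floor(self):
        p = CassonParams(0.05, 0.004)
        assert apparent_viscosity(p, 0.0, REG) == pytest.approx(
            apparent_viscosity(p, REG.gamma_min, REG))

    def test_capped_at_mu_max(self):
        reg = RegularizationConfig(gamma_min=1e-6, mu_max=10.0)
        assert apparent_viscosity(CassonParams(0.05, 0.004), 1e-6, reg) == 10.0

    @given(tau_y=st.floats(0.0, 0.1), k=st.floats(1e-4, 0.05))
    @settings(deadline=None, max_examples=50)
    def test_shear_thinning(self, tau_y, k):
        g = np.logspace(-3, 3, 100)
        mu = apparent_viscosity(CassonParams(tau_y, k), g, REG)
        assert np.all(np.diff(mu) <= 1e-15)


class TestFitCasson:
    def test_newtonian_curve(self):
        curve = ViscosityCurve("p", "before", [1.0, 10.0, 100.0, 1000.0],
                               [3.5] * 4)
        fit = fit_casson(curve)
        assert fit.params.tau_y == pytest.approx(0.0, abs=1e-18)
        assert fit.params.k == pytest.approx(0.0035, rel=1e-12)

    def test_noiseless_round_trip_six_significant_figures(self):
        true = CassonParams(0.02, 0.004)
        g = np.logspace(0, 3, 20)
        mu_cp = np.asarray(apparent_viscosity(true, g, REG)) * 1e3
        fit = fit_casson(ViscosityCurve("p", "before", g, mu_cp))
        assert fit.params.tau_y == pytest.approx(true.tau_y, rel=1e-6)
        assert fit.params.k == pytest.approx(true.k, rel=1e-6)
        assert fit.residual_norm < 1e-10

    def test_noisy_recovery_within_five_percent(self):
        true = CassonParams(0.02, 0.004)
        g = np.logspace(0, 3, 20)
        mu_cp = np.asarray(apparent_viscosity(true, g, REG)) * 1e3
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(25):
            noisy = mu_cp * np.exp(0.02 * rng.standard_normal(len(g)))
            fit = fit_casson(ViscosityCurve("p", "before", g, noisy))
            worst = max(worst,
                        abs(fit.params.tau_y - true.tau_y) / true.tau_y,
                        abs(fit.params.k - true.k) / true.k)
        assert worst < 0.05

    def test_requires_three_distinct_points(self):
        with pytest.raises(RheologyError):
            fit_casson(ViscosityCurve("p", "before", [1.0, 2.0], [30.0, 25.0]))

    def test_two_anchor_inversion_round_trip(self):
        p = casson_from_two_viscosities(33.64, 1.0, 5.02, 300.0)
        mu1 = apparent_viscosity(p, 1.0, REG) * 1e3
        mu2 = apparent_viscosity(p, 300.0, REG) * 1e3
        assert mu1 == pytest.approx(33.64, rel=1e-12)
        assert mu2 == pytest.approx(5.02, rel=1e-12)


class TestGroupSummary:
    def _curve(self, pid, cond, vals, g=(1.0, 10.0, 100.0, 1000.0)):
        return ViscosityCurve(pid, cond, np.asarray(g), np.asarray(vals))

    def test_single_curve_exact_point(self):
        c = self._curve("a", "before", [30.0, 10.0, 6.0, 4.0])
        df = group_viscosity_summary([c], [10.0])
        row = df.iloc[0]
        assert row.mean_cP == pytest.approx(10.0)
        assert row.sd_cP == 0.0 and row.n == 1

    def test_identical_curves_zero_sd(self):
        c1 = self._curve("a", "before", [30.0, 10.0, 6.0, 4.0])
        c2 = self._curve("b", "before", [30.0, 10.0, 6.0, 4.0])
        df = group_viscosity_summary([c1, c2], [5.0, 100.0])
        assert np.allclose(df.sd_cP, 0.0)

    def test_log_linear_interpolation(self):
        c = self._curve("a", "before", [32.0, 8.0, 2.0, 0.5])
        # exact power law mu = 32 * g**-0.60206; log-linear interp is exact
        expect = 32.0 * 31.623 ** (np.log10(8.0 / 32.0) / np.log10(10.0))
        got = interpolate_viscosity(c, 31.623)
        assert got == pytest.approx(expect, rel=1e-3)

    def test_extrapolation_rejected(self):
        c = self._curve("a", "before", [30.0, 10.0, 6.0, 4.0],
                        g=(1.0, 10.0, 100.0, 500.0))
        with pytest.raises(RheologyError):
            group_viscosity_summary([c], [1000.0])


class TestPercentDifference:
    @pytest.mark.parametrize("before,after,two_dp,truncated", [
        (33.64, 28.40, 18.45, 18),
        (5.02, 4.51, 11.31, 11),
        (0.92, 0.84, 9.52, 9),
        (0.09, 0.08, 12.50, 12),
        (0.52, 0.48, 8.33, 8),
    ])
    def test_study_style_renderings(self, before, after, two_dp, truncated):
        assert round(percent_difference(before, after), 2) == two_dp
        assert percent_difference_truncated(before, after) == truncated

    def test_identity_is_zero(self):
        assert percent_difference(3.7, 3.7) == 0.0

    @given(a=st.floats(0.1, 100.0), b=st.floats(0.1, 100.0))
    @settings(deadline=None, max_examples=50)
    def test_sign_matches_direction(self, a, b):
        assert np.sign(percent_difference(a, b)) == np.sign(a - b)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(RheologyError):
            percent_difference(1.0, 0.0)


def test_viscosity_csv_round_trip(tmp_path):
    g = np.logspace(0, 3, 5)
    curves = [ViscosityCurve("P01", "before", g, 30.0 / g ** 0.3),
              ViscosityCurve("P01", "after", g, 25.0 / g ** 0.3)]
    path = tmp_path / "visc.csv"
    write_viscosity_csv(curves, path)
    back = read_viscosity_csv(path)
    assert len(back) == 2
    by_cond = {c.condition: c for c in back}
    for c in curves:
        np.testing.assert_allclose(by_cond[c.condition].viscosities_cp,
                                   c.viscosities_cp)


def test_curve_invariants_enforced():
    with pytest.raises(RheologyError):
        ViscosityCurve("p", "before", [1.0, 1.0, 10.0], [3, 3, 3])
    with pytest.raises(RheologyError):
        ViscosityCurve("p", "before", [1.0, 10.0], [3.0, -1.0])
    with pytest.raises(RheologyError):
        ViscosityCurve("p", "middle", [1.0, 10.0], [3.0, 2.0])
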