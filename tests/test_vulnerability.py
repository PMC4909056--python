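"""Sigmoid vulnerability curves: model, analytic inverse, least-squares fit."""

import numpy as np
import pytest

from beechtrial.simulate import PLCSimSpec, simulate_plc_series
from beechtrial.vulnerability import (
    PLCSeries,
    VulnerabilityCurve,
    empirical_conductivities,
    fit_vulnerability_curve,
    plc_from_conductance,
    pressure_at_plc,
    sigmoid_plc,
)


class TestSigmoid:
    def test_half_loss_at_p50(self):
        assert sigmoid_plc(-3.0, -3.0, 40.0) == pytest.approx(50.0)

    def test_asymptotes(self):
        assert sigmoid_plc(50.0, -3.0, 40.0) == pytest.approx(0.0, abs=1e-9)
        assert sigmoid_plc(-50.0, -3.0, 40.0) == pytest.approx(100.0, abs=1e-9)

    def test_value_near_p88(self):
        assert sigmoid_plc(-4.2453, -3.0, 40.0) == pytest.approx(88.0, abs=1e-2)

    def test_monotone_decreasing_in_pressure(self):
        p = np.linspace(-6, 0, 200)
        v = sigmoid_plc(p, -3.0, 40.0)
        assert np.all(np.diff(v) < 0)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            sigmoid_plc(-3.0, -3.0, 0.0)


class TestAnalyticInverse:
    def test_target_50_returns_p50(self):
        assert pressure_at_plc(-3.0, 40.0, 50.0) == pytest.approx(-3.0)

    def test_p88_and_p12_values(self):
        assert pressure_at_plc(-3.0, 40.0, 88.0) == pytest.approx(-4.2453, abs=1e-4)
        assert pressure_at_plc(-3.0, 40.0, 12.0) == pytest.approx(-1.7547, abs=1e-4)

    def test_logistic_symmetry_about_p50(self):
        p12 = pressure_at_plc(-3.0, 40.0, 12.0)
        p88 = pressure_at_plc(-3.0, 40.0, 88.0)
        assert abs(-3.0 - p12) == pytest.approx(abs(p88 - (-3.0)), abs=1e-12)

    @pytest.mark.parametrize("p50,s", [(-2.0, 20.0), (-3.0, 40.0), (-4.5, 75.0)])
    def test_roundtrip_against_sigmoid(self, p50, s):
        for t in np.linspace(0.5, 99.5, 41):
            p = pressure_at_plc(p50, s, t)
            assert sigmoid_plc(p, p50, s) == pytest.approx(t, abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            pressure_at_plc(-3.0, 40.0, 0.0)
        with pytest.raises(ValueError):
            pressure_at_plc(-3.0, 40.0, 100.0)


class TestPlcFromConductance:
    @pytest.mark.parametrize("k,expected", [(1.0, 0.0), (0.0, 100.0), (0.25, 75.0)])
    def test_arithmetic(self, k, expected):
        assert plc_from_conductance(k, 1.0) == pytest.approx(expected)

    def test_overshoot_clips_to_zero(self):
        assert plc_from_conductance(1.01, 1.0) == 0.0

    def test_zero_kmax_rejected(self):
        with pytest.raises(ValueError):
            plc_from_conductance(0.5, 0.0)


class TestFit:
    def test_noiseless_curve_recovered_exactly(self):
        series = simulate_plc_series(PLCSimSpec(noise_sd=0.0), seed=0)
        fit = fit_vulnerability_curve(series)
        assert fit.converged and fit.qc_pass
        assert fit.p50 == pytest.approx(-3.0, abs=1e-6)
        assert fit.slope == pytest.approx(40.0, abs=1e-4)
        assert fit.p12 > fit.p50 > fit.p88

    def test_noisy_recovery_median_error(self):
        spec = PLCSimSpec(true_p50=-3.0, true_slope=40.0, noise_sd=3.0)
        errs = []
        for seed in range(100):
            fit = fit_vulnerability_curve(simulate_plc_series(spec, seed))
            errs.append(abs(fit.p50 - (-3.0)))
        assert np.median(errs) < 0.1

    def test_constant_series_flagged_not_raised(self):
        series = PLCSeries("flat", np.array([-1.0, -2.0, -3.0, -4.0]), np.full(4, 40.0))
        fit = fit_vulnerability_curve(series)
        assert not fit.converged and not fit.qc_pass
        assert np.isnan(fit.p50)

    def test_qc_requires_90_percent_loss(self):
        # truncate the grid so the curve never reaches 90 % loss
        spec = PLCSimSpec(
            noise_sd=0.0, pressure_grid=tuple(np.arange(-1.0, -3.3, -0.25).round(4))
        )
        fit = fit_vulnerability_curve(simulate_plc_series(spec, 0))
        assert fit.converged and not fit.qc_pass
        assert fit.max_plc_reached < 90.0

    def test_matches_brute_force_grid_search(self):
        """Coarse-lattice exhaustive search agrees with the optimizer."""
        series = simulate_plc_series(PLCSimSpec(noise_sd=0.0), seed=0)
        p50s = np.linspace(-4.0, -2.0, 81)
        slopes = np.linspace(20.0, 60.0, 81)
        rss = np.array(
            [
                [
                    np.sum((sigmoid_plc(series.pressures_mpa, p, s) - series.plc) ** 2)
                    for s in slopes
                ]
                for p in p50s
            ]
        )
        i, j = np.unravel_index(rss.argmin(), rss.shape)
        fit = fit_vulnerability_curve(series)
        assert fit.p50 == pytest.approx(p50s[i], abs=np.diff(p50s)[0])
        assert fit.slope == pytest.approx(slopes[j], abs=np.diff(slopes)[0])
        assert fit.rss <= rss[i, j] + 1e-9

    def test_predict_requires_fit(self):
        vc = VulnerabilityCurve()
        with pytest.raises(RuntimeError):
            vc.predict([-3.0])

    def test_ordering_holds_for_all_qc_pass_fits(self):
        spec = PLCSimSpec(noise_sd=3.0)
        for seed in range(50):
            fit = fit_vulnerability_curve(simulate_plc_series(spec, seed))
            if fit.qc_pass:
                assert fit.p12 > fit.p50 > fit.p88


class TestEmpiricalConductivity:
    def test_normalization_arithmetic(self):
        m = empirical_conductivities(1.0e-6, 2.0e-5)
        assert m.ks_emp == pytest.approx(0.05)
        assert m.kl_emp is None

    def test_zero_flow_gives_zero(self):
        m = empirical_conductivities(0.0, 1e-5, 0.3)
        assert m.ks_emp == 0.0 and m.kl_emp == 0.0

    def test_inverse_proportional_to_area(self):
        a = empirical_conductivities(1.0, 2.0e-5).ks_emp
        b = empirical_conductivities(1.0, 1.0e-5).ks_emp
        assert b == pytest.approx(2 * a)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            empirical_conductivities(1.0, 0.0)
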