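"""KWW kinetics: prediction, recovery parameter, and parameter fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import glassage as ga
import glassage.kinetics as kin
from glassage.errors import ParameterError, ValidationError
from glassage.units import days_to_seconds, hours_to_seconds

TIMES_H = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0, 32.0])
TIMES_S = hours_to_seconds(TIMES_H)

# literature kinetics of amorphous indapamide (Ta = 65/75/85 °C)
PARAMS_65 = dict(tau=days_to_seconds(189.0), beta=0.277, dHr_inf=16.88)
PARAMS_75 = dict(tau=days_to_seconds(6.0), beta=0.306, dHr_inf=12.45)
PARAMS_85 = dict(tau=hours_to_seconds(28.0), beta=0.327, dHr_inf=7.92)


class TestPrediction:
    def test_limits_and_tau_crossing(self):
        assert kin.kww_predict(0.0, 100.0, 0.5, 10.0) == 0.0
        # at t = tau the exponent is 1 for any beta
        for beta in (0.25, 0.5, 1.0):
            assert kin.kww_predict(100.0, 100.0, beta, 10.0) == pytest.approx(
                10.0 * (1 - np.exp(-1))
            )
        assert kin.kww_predict(1e18, 100.0, 0.5, 10.0) == pytest.approx(10.0)

    def test_domain_violations_rejected(self):
        with pytest.raises(ParameterError):
            kin.kww_predict(1.0, -1.0, 0.5, 10.0)
        with pytest.raises(ParameterError):
            kin.kww_predict(1.0, 10.0, 1.5, 10.0)
        with pytest.raises(ParameterError):
            kin.recovery(-1.0, 10.0, 0.5)

    @settings(derandomize=True, max_examples=40)
    @given(
        t=hst.floats(0.0, 1e9),
        tau=hst.floats(1.0, 1e9),
        beta=hst.floats(0.05, 1.0),
        inf=hst.floats(0.1, 100.0),
    )
    def test_prediction_and_recovery_are_exact_complements(self, t, tau, beta, inf):
        total = kin.kww_predict(t, tau, beta, inf) + inf * kin.recovery(t, tau, beta)
        assert total == pytest.approx(inf, rel=1e-12)


class TestRecovery:
    def test_published_values_at_32_hours(self):
        t = hours_to_seconds(32.0)
        assert round(float(kin.recovery(t, PARAMS_65["tau"], PARAMS_65["beta"])), 2) == 0.78
        assert round(float(kin.recovery(t, PARAMS_75["tau"], PARAMS_75["beta"])), 2) == 0.53

    def test_strictly_decreasing_and_beta_independent_at_tau(self):
        t = np.geomspace(1.0, 1e7, 50)
        phi = kin.recovery(t, 1e4, 0.4)
        assert np.all(np.diff(phi) < 0)
        for beta in (0.2, 0.5, 0.9):
            assert kin.recovery(1e4, 1e4, beta) == pytest.approx(np.exp(-1))

    def test_recovery_from_series(self):
        series = ga.simulate_kww_series(358.15, TIMES_S, **PARAMS_85)
        pts = kin.recovery_from_series(series, PARAMS_85["dHr_inf"])
        expected = 1.0 - series.dHr / PARAMS_85["dHr_inf"]
        np.testing.assert_allclose([p.phi for p in pts], expected, rtol=1e-12)

    def test_experimental_phi_at_85C(self):
        # dHr = 4.93 against the 7.92 equilibrium value
        assert round(1.0 - 4.93 / 7.92, 2) == 0.38


class TestFitKWW:
    @pytest.mark.parametrize("params", [PARAMS_65, PARAMS_75, PARAMS_85])
    def test_noiseless_literature_parameters_recovered(self, params):
        series = ga.simulate_kww_series(358.15, TIMES_S, **params)
        fit = kin.fit_kww(series)
        assert fit.tau == pytest.approx(params["tau"], rel=1e-6)
        assert fit.beta == pytest.approx(params["beta"], rel=1e-6)
        assert fit.dHr_inf == pytest.approx(params["dHr_inf"], rel=1e-6)

    @pytest.mark.parametrize("tau_h", [10.0, 100.0, 1000.0])
    @pytest.mark.parametrize("beta", [0.25, 0.5, 0.75])
    def test_noiseless_grid_recovery(self, tau_h, beta):
        tau = hours_to_seconds(tau_h)
        series = ga.simulate_kww_series(358.15, TIMES_S, tau, beta, 10.0)
        fit = kin.fit_kww(series)
        assert fit.tau == pytest.approx(tau, rel=1e-6)
        assert fit.beta == pytest.approx(beta, rel=1e-6)
        assert fit.dHr_inf == pytest.approx(10.0, rel=1e-6)

    def test_fixed_equilibrium_value_is_honoured(self):
        series = ga.simulate_kww_series(358.15, TIMES_S, **PARAMS_85)
        fit = kin.fit_kww(series, dHr_inf_fixed=8.5)
        assert fit.dHr_inf == 8.5
        assert fit.fixed_flags["dHr_inf"]

    def test_too_few_points_rejected(self):
        series = ga.simulate_kww_series(358.15, TIMES_S[:3], **PARAMS_85)
        with pytest.raises(ValidationError):
            kin.fit_kww(series)

    def test_noisy_monte_carlo_median_tau_within_25_percent(self):
        """Repeated fits of noisy 85 °C-like series: the median fitted tau
        stays within 25 % of the generating value (sd = 0.3 J/g)."""
        taus = []
        for rep in range(200):
            series = ga.simulate_kww_series(
                358.15, TIMES_S, noise_sd=0.3, seed=1000 + rep, **PARAMS_85
            )
            try:
                taus.append(kin.fit_kww(series).tau)
            except Exception:
                continue
        assert len(taus) > 180
        med = np.median(taus)
        assert abs(med - PARAMS_85["tau"]) / PARAMS_85["tau"] < 0.25


class TestFictiveVsTime:
    def test_linearised_mapping(self):
        series = ga.simulate_kww_series(358.15, TIMES_S, **PARAMS_85)
        pts = kin.fictive_vs_time(series, Tg=375.35, dcp=0.47)
        # dHr = 2.35 with dCp = 0.47 lowers Tf by 5 K
        assert 375.35 - 2.35 / 0.47 == pytest.approx(370.35)
        for (t, tf), h in zip(pts, series.dHr):
            assert tf == pytest.approx(375.35 - h / 0.47)
        # full relaxation maps exactly onto the ageing temperature
        s2 = ga.build_series(
            [
                ga.AgeingRecord(358.15, 1e9, 0.47 * (375.35 - 358.15)),
                ga.AgeingRecord(358.15, 0.0, 0.0),
                ga.AgeingRecord(358.15, 1.0, 0.1),
            ]
        )
        tf_map = dict(kin.fictive_vs_time(s2, 375.35, 0.47))
        assert tf_map[0.0] == pytest.approx(375.35)
        assert tf_map[1e9] == pytest.approx(358.15)
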