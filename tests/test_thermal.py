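"""Baselines, glass-transition detection, enthalpy and fictive temperature."""

import numpy as np
import pytest
from scipy.special import expit

import glassage as ga
import glassage.thermal as th
from glassage.dsc_io import SPECIFIC_HEAT, DSCCurve
from glassage.errors import AnchorError, ValidationError, WindowError
from tests.conftest import LIQUID_WINDOW, SOLID_WINDOW, TA_85C


def _cp_curve(T, cp, rate=10.0):
    time = (T - T[0]) * 6.0  # 10 K/min
    return DSCCurve("syn", SPECIFIC_HEAT, time, T, cp, nominal_rate=rate)


GRID = np.linspace(290.0, 440.0, 1501)


class TestBaselines:
    def test_exact_linear_input_recovered(self):
        curve = _cp_curve(GRID, 0.001 * GRID + 1.0)
        bl = th.fit_cp_baselines(curve, SOLID_WINDOW, LIQUID_WINDOW)
        assert bl.solid == pytest.approx((0.001, 1.0), abs=1e-12)
        assert bl.solid_rms == pytest.approx(0.0, abs=1e-12)

    def test_constant_step_gives_flat_delta_cp(self):
        cp = np.where(GRID < 370, 1.2, 1.65)
        bl = th.fit_cp_baselines(_cp_curve(GRID, cp), SOLID_WINDOW, LIQUID_WINDOW)
        T = np.linspace(330, 410, 9)
        np.testing.assert_allclose(bl.delta_cp(T), 0.45, atol=1e-12)

    def test_noisy_slope_within_three_standard_errors(self):
        rng = np.random.default_rng(7)
        T = np.linspace(300, 330, 200)
        sigma = 0.005
        cp = 0.001 * T + 1.0 + rng.normal(0, sigma, T.size)
        curve = _cp_curve(np.concatenate([T, np.linspace(400, 430, 30)]),
                          np.concatenate([cp, 0.001 * np.linspace(400, 430, 30) + 1.5]))
        bl = th.fit_cp_baselines(curve, (300, 330), (400, 430))
        se = sigma / np.sqrt(np.sum((T - T.mean()) ** 2))
        assert abs(bl.solid[0] - 0.001) < 3 * se

    def test_overlapping_or_sparse_windows_rejected(self):
        curve = _cp_curve(GRID, np.ones_like(GRID))
        with pytest.raises(WindowError):
            th.fit_cp_baselines(curve, (300, 405), (400, 430))
        with pytest.raises(WindowError):
            th.fit_cp_baselines(curve, (250.0, 252.0), (400, 430))

    def test_delta_cp_of_parallel_lines(self):
        bl = th.CpBaseline((0.0, 1.2), (0.0, 1.63), SOLID_WINDOW, LIQUID_WINDOW)
        assert th.delta_cp(bl, 350.0) == pytest.approx(0.43)
        bl2 = th.CpBaseline((0.002, 1.2), (0.002, 1.67), SOLID_WINDOW, LIQUID_WINDOW)
        assert th.delta_cp(bl2, 300.0) == pytest.approx(0.47)
        assert th.delta_cp(bl2, 430.0) == pytest.approx(0.47)


class TestGlassTransition:
    def _sigmoid_curve(self, center=375.35, dcp=0.47, base=1.2, offset=0.0):
        cp = base + offset + dcp * expit((GRID - center) / 2.0)
        return _cp_curve(GRID, cp), th.CpBaseline(
            (0.0, base + offset), (0.0, base + offset + dcp), SOLID_WINDOW, LIQUID_WINDOW
        )

    def test_symmetric_step_midpoint(self):
        curve, bl = self._sigmoid_curve()
        tg = th.detect_glass_transition(curve, bl)
        assert tg.T_mid == pytest.approx(375.35, abs=0.01)
        assert tg.delta_cp_at_Tg == pytest.approx(0.47, abs=1e-9)
        assert tg.T_onset < tg.T_mid < tg.T_end

    def test_invariant_under_constant_cp_shift(self):
        t0 = th.detect_glass_transition(*self._sigmoid_curve(offset=0.0))
        t1 = th.detect_glass_transition(*self._sigmoid_curve(offset=0.35))
        assert t1.T_mid == pytest.approx(t0.T_mid, abs=1e-9)

    def test_tnm_midpoint_matches_trajectory_oracle(self, unaged_sim, unaged_analysis):
        """The detector's half-step crossing must match the temperature at
        which the simulated dTf/dT crosses 1/2 on the heating scan."""
        heat, baseline, tg = unaged_analysis
        idx = len(unaged_sim.segment_slices) - 1
        T = unaged_sim.segment_curve(idx).temperature
        dtf = np.gradient(unaged_sim.segment_tf(idx), T)
        above = np.nonzero((dtf[:-1] < 0.5) & (dtf[1:] >= 0.5))[0]
        cross = [
            T[i] + (0.5 - dtf[i]) / (dtf[i + 1] - dtf[i]) * (T[i + 1] - T[i])
            for i in above
        ]
        oracle = min(cross, key=lambda c: abs(c - tg.T_mid))
        assert tg.T_mid == pytest.approx(oracle, abs=0.5)


class TestEnthalpy:
    def test_constant_cp_integral(self):
        T = np.linspace(300, 310, 101)
        H = th.integrate_enthalpy(_cp_curve(T, np.full_like(T, 2.0)), 300.0, 0.0)
        assert H.interp(310.0) == pytest.approx(20.0, rel=1e-12)

    def test_linear_cp_matches_closed_form(self):
        a, T1, T2 = 0.004, 310.0, 390.0
        T = np.linspace(T1, T2, 10_000)
        H = th.integrate_enthalpy(_cp_curve(T, a * T), T1, 0.0)
        assert H.interp(T2) == pytest.approx(a * (T2**2 - T1**2) / 2, rel=1e-9)

    def test_non_decreasing_for_positive_cp(self, unaged_analysis):
        heat, _, _ = unaged_analysis
        H = th.integrate_enthalpy(heat, 320.0, 0.0)
        assert np.all(np.diff(H.H) >= 0)

    def test_matches_fine_riemann_oracle(self):
        rng = np.random.default_rng(3)
        T = np.linspace(300, 400, 200_001)
        cp = 1.2 + 0.3 * expit((T - 350) / 3.0) + 0.002 * (T - 300)
        H = th.integrate_enthalpy(_cp_curve(T, cp), 300.0, 0.0)
        mid = 0.5 * (cp[1:] + cp[:-1])  # midpoint Riemann sum on the fine grid
        oracle = np.sum(mid * np.diff(T))
        assert H.H[-1] == pytest.approx(oracle, rel=1e-6)

    def test_reference_outside_range_rejected(self):
        T = np.linspace(300, 310, 11)
        with pytest.raises(AnchorError):
            th.integrate_enthalpy(_cp_curve(T, np.ones_like(T)), 500.0, 0.0)


class TestFictiveTemperature:
    def test_constructed_line_intersection(self):
        T = np.linspace(300, 360, 61)
        H = th.EnthalpyCurve(T, 0.5 * (T - 300.0), (300.0, 0.0))
        res = th.fictive_temperature(H, (1.0, -300.0 - 37.0), (300, 360))
        assert res.Tf == pytest.approx(374.0, abs=1e-9)

    def test_parallel_lines_rejected(self):
        T = np.linspace(300, 360, 61)
        H = th.EnthalpyCurve(T, 0.5 * (T - 300.0), (300.0, 0.0))
        with pytest.raises(ValidationError):
            th.fictive_temperature(H, (0.5, 5.0), (300, 360))

    def test_equal_area_of_symmetric_step_is_midpoint(self):
        cp = 1.2 + 0.47 * expit((GRID - 375.35) / 2.0)
        bl = th.CpBaseline((0.0, 1.2), (0.0, 1.67), SOLID_WINDOW, LIQUID_WINDOW)
        res = th.fictive_temperature_equal_area(_cp_curve(GRID, cp), bl)
        assert res.Tf == pytest.approx(375.35, abs=0.02)

    def test_overshoot_area_lowers_equal_area_tf_monotonically(self):
        grid = np.linspace(300, 440, 2801)
        tfs = []
        for area in (0.0, 1.0, 2.0, 4.0):
            unaged, aged = ga.phenomenological_pair(375.35, 0.47, area, 3.0, grid)
            bl = th.fit_cp_baselines(unaged, SOLID_WINDOW, LIQUID_WINDOW)
            tfs.append(th.fictive_temperature_equal_area(aged, bl).Tf)
        assert all(a > b for a, b in zip(tfs, tfs[1:]))

    def test_unaged_tf_matches_limiting_fictive_temperature(
        self, unaged_sim, unaged_analysis
    ):
        """For the unaged glass the analysed Tf equals the fictive
        temperature at which the simulated cooling froze the structure."""
        heat, baseline, _ = unaged_analysis
        tf_true = unaged_sim.segment_tf(1)[-1]  # end of cooling below Ta
        ea = th.fictive_temperature_equal_area(heat, baseline)
        ti = th.fictive_temperature_intersection(heat, baseline)
        assert ea.Tf == pytest.approx(tf_true, abs=0.5)
        assert ti.Tf == pytest.approx(tf_true, abs=0.5)

    def test_methods_agree_on_aged_curves(self, aged_sims, unaged_analysis):
        _, baseline, _ = unaged_analysis
        for out in aged_sims.values():
            heat = out.final_heating_curve
            ea = th.fictive_temperature_equal_area(heat, baseline)
            ti = th.fictive_temperature_intersection(heat, baseline)
            assert abs(ea.Tf - ti.Tf) <= 0.5

    def test_fully_relaxed_glass_reaches_ageing_temperature(
        self, equilibrated_sim, unaged_analysis
    ):
        _, baseline, _ = unaged_analysis
        heat = equilibrated_sim.final_heating_curve
        res = th.fictive_temperature_equal_area(heat, baseline)
        assert res.Tf == pytest.approx(TA_85C, abs=1.0)

    def test_tf_decreases_with_ageing_time_toward_ta(
        self, unaged_sim, aged_sims, unaged_analysis
    ):
        _, baseline, _ = unaged_analysis
        tfs = [
            th.fictive_temperature_equal_area(
                sim.final_heating_curve, baseline
            ).Tf
            for sim in [unaged_sim] + [aged_sims[h] for h in sorted(aged_sims)]
        ]
        assert all(a > b for a, b in zip(tfs, tfs[1:]))
        assert all(tf >= TA_85C for tf in tfs)
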