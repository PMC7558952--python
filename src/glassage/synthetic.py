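"""Synthetic data generation: TNM glass simulator and fixture builders.

Three generators stand in for the calorimeter:

* :func:`simulate_tnm` — a Tool–Narayanaswamy–Moynihan (TNM) structural
  relaxation simulator.  The fictive temperature T_f evolves under an
  arbitrary thermal program with a relaxation time that depends on both
  temperature and structure,

      ln τ(T, T_f) = ln A + x·Δh*/(R·T) + (1−x)·Δh*/(R·T_f) ,

  and a stretched-exponential (KWW) memory kernel with exponent β.
  The apparent specific heat on a ramp is
  Cp(T) = Cp_solid(T) + ΔCp(T)·dT_f/dT, which reproduces the full
  phenomenology of a real glass former: rate-dependent Tg and limiting
  T_f, and ageing overshoots that grow and shift with hold time.

* :func:`phenomenological_pair` — an aged/unaged Cp pair whose
  overshoot area is known in closed form, giving bit-exact ground
  truth for the enthalpy-relaxation integral.

* :func:`simulate_kww_series` — ΔH_r(t) series drawn from the KWW law
  with optional Gaussian noise, seed-deterministic.

The default parameter set emulates an indapamide-like pharmaceutical
glass: Tg ≈ 102–107 °C depending on scan rate, ΔCp = 0.47 J·g⁻¹·K⁻¹,
and a fragility index in the moderately fragile band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .ageing import AgeingRecord, RelaxationSeries, build_series
from .dsc_io import (
    SPECIFIC_HEAT,
    DSCCurve,
    ThermalProgram,
    ThermalSegment,
    isothermal,
    ramp,
)
from .errors import GeometryError, ParameterError, ResolutionError
from .kinetics import kww_predict
from .thermal import CpBaseline
from .units import GAS_CONSTANT, SECONDS_PER_MINUTE, days_to_seconds, hours_to_seconds

#: reference temperature at which the default τ(T, T) is pinned to 100 s
T_REF = 375.35  # K (102.2 °C)

#: published isothermal-ageing kinetics of amorphous indapamide, keyed by
#: ageing temperature in °C: KWW relaxation time, stretching exponent and
#: equilibrium enthalpy relaxation
INDAPAMIDE_AGEING_KINETICS = {
    65.0: {"tau_s": days_to_seconds(189.0), "beta": 0.277, "dHr_inf": 16.88},
    75.0: {"tau_s": days_to_seconds(6.0), "beta": 0.306, "dHr_inf": 12.45},
    85.0: {"tau_s": hours_to_seconds(28.0), "beta": 0.327, "dHr_inf": 7.92},
}


def default_cp_baseline() -> CpBaseline:
    """Parallel solid/liquid Cp lines with a constant step of 0.47 J·g⁻¹·K⁻¹."""
    return CpBaseline(
        solid=(0.0025, 0.30),
        liquid=(0.0025, 0.77),
        solid_window=(300.0, 330.0),
        liquid_window=(400.0, 430.0),
    )


@dataclass(frozen=True)
class TNMParameters:
    """Constants of the TNM structural-relaxation model."""

    lnA: float  # ln(pre-exponential / s)
    dh_star: float  # J·mol⁻¹, apparent activation enthalpy
    x: float  # nonlinearity, (0, 1]
    beta: float  # nonexponentiality, (0, 1]
    cp_baseline: CpBaseline = field(default_factory=default_cp_baseline)
    Tf_init: Optional[float] = None  # K; defaults to the program start T

    def __post_init__(self):
        if not (0 < self.x <= 1):
            raise ParameterError(f"x must lie in (0, 1], got {self.x}")
        if not (0 < self.beta <= 1):
            raise ParameterError(f"beta must lie in (0, 1], got {self.beta}")
        if self.dh_star <= 0:
            raise ParameterError("dh_star must be positive")

    def tau(self, T, Tf):
        """Relaxation time τ(T, T_f) in seconds."""
        return np.exp(
            self.lnA
            + self.x * self.dh_star / (GAS_CONSTANT * np.asarray(T))
            + (1.0 - self.x) * self.dh_star / (GAS_CONSTANT * np.asarray(Tf))
        )


def default_tnm_parameters(
    dh_star: float = 500e3,
    x: float = 0.5,
    beta: float = 0.5,
    tau_ref: float = 100.0,
    T_ref: float = T_REF,
) -> TNMParameters:
    """Indapamide-like defaults: ln A pinned so τ(T_ref, T_ref) = tau_ref."""
    lnA = math.log(tau_ref) - dh_star / (GAS_CONSTANT * T_ref)
    return TNMParameters(lnA=lnA, dh_star=dh_star, x=x, beta=beta)


@dataclass
class SimulationOutput:
    """A simulated multi-segment thermogram with its T_f trajectory."""

    curve: DSCCurve  # specific-heat signal over the whole program
    tf_trajectory: np.ndarray  # K, aligned with curve samples
    params: TNMParameters
    program: ThermalProgram
    segment_slices: List[Tuple[ThermalSegment, slice]]
    seed: Optional[int] = None

    def segment_curve(self, index: int) -> DSCCurve:
        """Extract one program segment as a stand-alone curve."""
        seg, sl = self.segment_slices[index]
        return DSCCurve(
            sample_id=f"{self.curve.sample_id}/seg{index}",
            signal_kind=SPECIFIC_HEAT,
            time=self.curve.time[sl].copy(),
            temperature=self.curve.temperature[sl].copy(),
            value=self.curve.value[sl].copy(),
            nominal_rate=abs(seg.rate),
            metadata=dict(self.curve.metadata),
        )

    def segment_tf(self, index: int) -> np.ndarray:
        return self.tf_trajectory[self.segment_slices[index][1]]

    @property
    def final_heating_curve(self) -> DSCCurve:
        """The last heating ramp of the program (the measurement scan)."""
        for i in range(len(self.segment_slices) - 1, -1, -1):
            seg, _ = self.segment_slices[i]
            if seg.kind == "ramp" and seg.rate > 0:
                return self.segment_curve(i)
        raise ValueError("program contains no heating ramp")


def _segment_steps(
    seg: ThermalSegment, max_step_K: float, iso_steps: int, iso_min_dt: float
):
    """Per-step (dt_s, T_target) arrays for one segment."""
    dur_s = seg.duration * SECONDS_PER_MINUTE
    if seg.kind == "ramp":
        n = max(2, math.ceil(abs(seg.T_end - seg.T_start) / max_step_K))
        T = np.linspace(seg.T_start, seg.T_end, n + 1)[1:]
        dt = np.full(n, dur_s / n)
        return dt, T
    # isothermal: geometric time grid so long holds stay cheap while the
    # early fast relaxation is still resolved
    if dur_s <= iso_min_dt:
        return np.array([dur_s]), np.array([seg.T_start])
    t = np.geomspace(iso_min_dt, dur_s, iso_steps)
    dt = np.diff(np.concatenate([[0.0], t]))
    return dt, np.full(dt.size, seg.T_start)


def simulate_tnm(
    program: ThermalProgram,
    params: TNMParameters,
    *,
    max_step_K: float = 0.5,
    iso_steps: int = 200,
    iso_min_dt: float = 1.0,
    seed: Optional[int] = None,
    sample_id: str = "tnm",
    metadata: Optional[dict] = None,
) -> SimulationOutput:
    """Integrate the TNM recursion over a thermal program.

    Discretisation: the fictive temperature after step n is

        T_f(n) = T₀ + Σ_j ΔT_j · [1 − exp(−(Z_n − Z_{j−1})^β)] ,

    where Z is the cumulative reduced time Σ Δt_k/τ_k and τ_k is
    evaluated at the step's temperature and the previous T_f
    (Boltzmann superposition of the responses to each temperature
    step, with one common reduced-time clock).  Ramps are subdivided
    so |ΔT| ≤ ``max_step_K`` per step (at most 0.5 K); holds use a
    geometric time grid.  When every past contribution has fully
    relaxed the history is compacted (T₀ reset to the current
    temperature), which keeps the reduced-time differences well
    inside double precision on programs with high-temperature
    excursions.

    The simulation itself is deterministic; ``seed`` is recorded for
    provenance of any downstream noise.
    """
    if max_step_K > 0.5:
        raise ResolutionError("max_step_K must be at most 0.5 K on ramps")

    per_seg = [
        _segment_steps(seg, max_step_K, iso_steps, iso_min_dt)
        for seg in program.segments
    ]
    n_total = sum(dt.size for dt, _ in per_seg) + 1

    time = np.empty(n_total)
    temp = np.empty(n_total)
    tf = np.empty(n_total)

    T0 = program.segments[0].T_start
    base = params.Tf_init if params.Tf_init is not None else T0
    time[0], temp[0], tf[0] = 0.0, T0, base

    # history of temperature steps and the reduced time at which each began
    dT_h = np.empty(n_total)
    Zp_h = np.empty(n_total)
    m = 0
    if base != T0:
        # initial structural departure decays like one extra step from base
        dT_h[0], Zp_h[0] = T0 - base, 0.0
        m = 1

    Z = 0.0
    # a contribution with (Z - Zp)^beta above this is fully relaxed
    relaxed = max(30.0 ** (1.0 / params.beta), 100.0)
    R = GAS_CONSTANT
    xdh = params.x * params.dh_star
    ydh = (1.0 - params.x) * params.dh_star

    i = 1
    t_clock = 0.0
    T_prev = T0
    Tf_prev = base
    seg_slices: List[Tuple[ThermalSegment, slice]] = []
    for seg, (dts, Ts) in zip(program.segments, per_seg):
        start = i - 1  # include the boundary sample in both neighbours' view
        for dt, T in zip(dts, Ts):
            tau = math.exp(params.lnA + xdh / (R * T) + ydh / (R * Tf_prev))
            Zp = Z
            Z += dt / tau
            dT = T - T_prev
            if dT != 0.0:
                dT_h[m], Zp_h[m] = dT, Zp
                m += 1
            if m:
                u = Z - Zp_h[:m]
                Tf_now = base + float(np.sum(dT_h[:m] * (1.0 - np.exp(-(u**params.beta)))))
                if u[-1] > relaxed:  # whole history equilibrated; compact it
                    base = Tf_now
                    m = 0
                    Z = 0.0
            else:
                Tf_now = base
            t_clock += dt
            time[i], temp[i], tf[i] = t_clock, T, Tf_now
            T_prev, Tf_prev = T, Tf_now
            i += 1
        seg_slices.append((seg, slice(start, i)))

    # apparent Cp: solid baseline plus the structural contribution on ramps
    bl = params.cp_baseline
    cp = bl.solid_at(temp)
    for seg, sl in seg_slices:
        if seg.kind == "ramp":
            dtf_dT = np.gradient(tf[sl], temp[sl])
            cp[sl] = bl.solid_at(temp[sl]) + bl.delta_cp(temp[sl]) * dtf_dT

    curve = DSCCurve(
        sample_id=sample_id,
        signal_kind=SPECIFIC_HEAT,
        time=time,
        temperature=temp,
        value=cp,
        nominal_rate=abs(program.segments[0].rate),
        metadata=dict(metadata or {}),
    )
    return SimulationOutput(
        curve=curve,
        tf_trajectory=tf,
        params=params,
        program=program,
        segment_slices=seg_slices,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# protocol builders mirroring the study's thermal programs


def ageing_protocol(
    Ta: float,
    t_a: float,
    *,
    rate: float = 10.0,
    heating_rate: Optional[float] = None,
    T_high: float = 463.15,
    T_low: float = 298.15,
    hold_low_min: float = 5.0,
) -> ThermalProgram:
    """Cool to Ta, hold t_a seconds, cool to T_low, hold, reheat to T_high."""
    segs = [ramp(T_high, Ta, rate)]
    if t_a > 0:
        segs.append(isothermal(Ta, t_a / SECONDS_PER_MINUTE))
    segs.append(ramp(Ta, T_low, rate))
    if hold_low_min > 0:
        segs.append(isothermal(T_low, hold_low_min))
    segs.append(ramp(T_low, T_high, heating_rate or rate))
    return ThermalProgram(segs)


def cooling_rate_protocol(
    q_cool: float, *, T_high: float = 463.15, T_low: float = 298.15
) -> ThermalProgram:
    """A single cooling ramp for limiting-fictive-temperature sweeps."""
    return ThermalProgram([ramp(T_high, T_low, q_cool)])


def heating_rate_protocol(
    q_heat: float,
    *,
    q_cool: Optional[float] = None,
    T_high: float = 463.15,
    T_low: float = 298.15,
    hold_low_min: float = 5.0,
) -> ThermalProgram:
    """Cooling followed by a variable-rate heating scan.

    By default the cooling rate matches the heating rate
    (``q_cool = q_heat``), the condition under which the heating-scan
    Tg obeys d ln q / d(1/Tg) = −Δh*/R; pass an explicit ``q_cool``
    for a fixed-cooling protocol (whose apparent activation energy is
    systematically inflated, because slow scans age the glass in situ).
    """
    segs = [ramp(T_high, T_low, q_cool if q_cool is not None else q_heat)]
    if hold_low_min > 0:
        segs.append(isothermal(T_low, hold_low_min))
    segs.append(ramp(T_low, T_high, q_heat))
    return ThermalProgram(segs)


# ---------------------------------------------------------------------------
# phenomenological fixtures with closed-form ground truth


def phenomenological_pair(
    Tg: float,
    dcp: float,
    overshoot_area: float,
    peak_width: float,
    grid: np.ndarray,
    *,
    baseline: Optional[CpBaseline] = None,
    step_width: float = 2.0,
    peak_offset: Optional[float] = None,
    rate: float = 10.0,
) -> Tuple[DSCCurve, DSCCurve]:
    """An aged/unaged Cp pair whose area difference is known exactly.

    The unaged curve is a smooth sigmoid Cp step of height ``dcp``
    centred at Tg between linear baselines; the aged curve adds a
    Gaussian endotherm of exact area ``overshoot_area`` centred just
    above Tg (offset 2 peak widths by default).  The peak must sit at
    least 6 standard deviations inside the grid so its tails are not
    truncated.  Sample the grid a few points per ``peak_width`` to
    keep the trapezoid recovery inside 0.5 %.
    """
    if overshoot_area < 0:
        raise ParameterError("overshoot_area must be non-negative")
    grid = np.asarray(grid, dtype=float)
    bl = baseline or default_cp_baseline()
    center = Tg + (2.0 * peak_width if peak_offset is None else peak_offset)
    if overshoot_area > 0 and (
        center - 6 * peak_width < grid[0] or center + 6 * peak_width > grid[-1]
    ):
        raise GeometryError("overshoot peak truncated by the temperature grid")

    step = dcp * expit((grid - Tg) / step_width)
    unaged_cp = bl.solid_at(grid) + step
    aged_cp = unaged_cp + overshoot_area * norm.pdf(grid, loc=center, scale=peak_width)

    q_s = rate / SECONDS_PER_MINUTE
    time = (grid - grid[0]) / q_s

    def _curve(sample_id, cp):
        return DSCCurve(
            sample_id=sample_id,
            signal_kind=SPECIFIC_HEAT,
            time=time.copy(),
            temperature=grid.copy(),
            value=cp,
            nominal_rate=rate,
        )

    return _curve("unaged", unaged_cp), _curve("aged", aged_cp)


def simulate_kww_series(
    Ta: float,
    times: Sequence[float],
    tau: float,
    beta: float,
    dHr_inf: float,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> RelaxationSeries:
    """Draw a ΔH_r(t) series from the KWW law with Gaussian noise.

    ``times`` are ageing times in seconds.  Noisy draws are clipped at
    the −0.3 J·g⁻¹ physical-plausibility floor used for measured
    records.  Deterministic for a fixed seed.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    times = np.asarray(times, dtype=float)
    clean = kww_predict(times, tau, beta, dHr_inf)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = np.maximum(clean + rng.normal(0.0, noise_sd, times.size), -0.3)
        sd = noise_sd
    else:
        values = clean
        sd = None
    records = [
        AgeingRecord(Ta=Ta, t_a=float(t), dHr=float(v), sd=sd)
        for t, v in zip(times, values)
    ]
    return build_series(records)
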