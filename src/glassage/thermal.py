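"""Cp baselines, glass transition, total enthalpy and fictive temperature.

The glass transition of an amorphous solid appears in DSC as a step in
apparent specific heat between two nearly linear reference lines: the
solid (glassy) Cp below the transition and the liquid (supercooled
melt) Cp above it.  This module fits those reference lines, locates the
transition, integrates Cp into a total-enthalpy curve H(T), and
determines the fictive temperature T_f — the temperature at which the
glass's frozen structure would be the equilibrium liquid structure —
by two routes:

* the enthalpy-intersection construction: extrapolate the liquid
  enthalpy line below the transition and intersect it with the glass
  enthalpy line;
* the Moynihan equal-area construction on the Cp curve, used as an
  independent cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .dsc_io import SPECIFIC_HEAT, DSCCurve
from .errors import (
    AnchorError,
    TransitionNotFoundError,
    ValidationError,
    WindowError,
)

Line = Tuple[float, float]  # (slope, intercept)


def _eval_line(line: Line, T):
    return line[0] * np.asarray(T, dtype=float) + line[1]


@dataclass(frozen=True)
class CpBaseline:
    """Linear solid and liquid specific-heat reference lines.

    Each line is (slope J·g⁻¹·K⁻², intercept J·g⁻¹·K⁻¹); the windows
    record the temperature ranges the lines were fitted over.  The
    liquid line must lie above the solid line throughout the gap
    between the windows so that ΔCp(T) > 0 there.
    """

    solid: Line
    liquid: Line
    solid_window: Tuple[float, float]
    liquid_window: Tuple[float, float]
    solid_rms: float = 0.0
    liquid_rms: float = 0.0

    def __post_init__(self):
        lo, hi = self.solid_window[1], self.liquid_window[0]
        T = np.linspace(lo, hi, 32)
        if np.any(self.delta_cp(T) <= 0):
            raise ValidationError(
                "liquid Cp line must lie above the solid line between the windows"
            )

    def solid_at(self, T):
        return _eval_line(self.solid, T)

    def liquid_at(self, T):
        return _eval_line(self.liquid, T)

    def delta_cp(self, T):
        """ΔCp(T) = Cp_liquid(T) − Cp_solid(T)."""
        return self.liquid_at(T) - self.solid_at(T)


@dataclass(frozen=True)
class GlassTransition:
    """Tangent-construction characterisation of a Cp step."""

    T_onset: float  # K
    T_mid: float  # K, half-ΔCp midpoint
    T_end: float  # K
    delta_cp_at_Tg: float  # J·g⁻¹·K⁻¹
    mode: str  # "heating" | "cooling"

    def __post_init__(self):
        if not (self.T_onset < self.T_mid < self.T_end):
            raise ValidationError("require T_onset < T_mid < T_end")
        if self.delta_cp_at_Tg <= 0:
            raise ValidationError("delta_cp_at_Tg must be positive")


@dataclass(frozen=True)
class EnthalpyCurve:
    """Total enthalpy H(T) from integrating Cp, anchored at a reference."""

    temperature: np.ndarray  # K, strictly increasing
    H: np.ndarray  # J·g⁻¹
    reference: Tuple[float, float]  # (T_ref, H_ref)

    def interp(self, T):
        return np.interp(T, self.temperature, self.H)


@dataclass(frozen=True)
class FictiveTempResult:
    Tf: float  # K
    method: str  # "enthalpy_intersection" | "equal_area"
    diagnostics: dict


def _window_mask(T, window):
    return (T >= window[0]) & (T <= window[1])


def fit_cp_baselines(
    curve: DSCCurve,
    solid_window: Tuple[float, float],
    liquid_window: Tuple[float, float],
) -> CpBaseline:
    """Ordinary least-squares lines through Cp inside each window.

    Windows must not overlap and each must contain at least five
    samples; residual RMS per window is reported on the result.
    """
    if curve.signal_kind != SPECIFIC_HEAT:
        raise ValidationError("baseline fitting expects a specific-heat curve")
    if solid_window[1] >= liquid_window[0]:
        raise WindowError("solid window must lie entirely below the liquid window")
    T = curve.temperature
    lines, rms = [], []
    for window in (solid_window, liquid_window):
        mask = _window_mask(T, window)
        if mask.sum() < 5:
            raise WindowError(f"window {window} contains {mask.sum()} < 5 samples")
        coef = np.polyfit(T[mask], curve.value[mask], 1)
        resid = curve.value[mask] - np.polyval(coef, T[mask])
        lines.append((float(coef[0]), float(coef[1])))
        rms.append(float(np.sqrt(np.mean(resid**2))))
    return CpBaseline(
        solid=lines[0],
        liquid=lines[1],
        solid_window=tuple(solid_window),
        liquid_window=tuple(liquid_window),
        solid_rms=rms[0],
        liquid_rms=rms[1],
    )


def delta_cp(baseline: CpBaseline, T) -> float:
    """Heat-capacity step between liquid and solid reference lines at T."""
    return baseline.delta_cp(T)


def detect_glass_transition(curve: DSCCurve, baseline: CpBaseline) -> GlassTransition:
    """Locate the glass transition between the baseline windows.

    T_mid is where Cp crosses the half-step line
    Cp_solid(T) + ΔCp(T)/2 (midpoint convention).  T_onset and T_end
    are the intersections of the tangent at the steepest Cp slope with
    the solid and liquid lines.  With several half-step crossings (an
    ageing overshoot recrosses the line) the crossing nearest the
    steepest slope wins, with a warning.
    """
    if curve.signal_kind != SPECIFIC_HEAT:
        raise ValidationError("transition detection expects a specific-heat curve")
    mode = "heating" if curve.is_heating else "cooling"
    asc = curve.sorted_by_temperature()
    T, cp = asc.temperature, asc.value
    region = (T > baseline.solid_window[1]) & (T < baseline.liquid_window[0])
    if region.sum() < 5:
        raise TransitionNotFoundError("too few samples between the baseline windows")
    Tr, cpr = T[region], cp[region]

    excess = cpr - (baseline.solid_at(Tr) + 0.5 * baseline.delta_cp(Tr))
    sign_change = np.nonzero(np.diff(np.signbit(excess)))[0]
    if sign_change.size == 0:
        raise TransitionNotFoundError("Cp never crosses the half-step line")

    slope = np.gradient(cpr, Tr)
    i_steep = int(np.argmax(slope))
    crossings = []
    for i in sign_change:
        # linear interpolation of the zero crossing between samples i, i+1
        f = excess[i] / (excess[i] - excess[i + 1])
        crossings.append(Tr[i] + f * (Tr[i + 1] - Tr[i]))
    crossings = np.asarray(crossings)
    if crossings.size > 1:
        warnings.warn(
            f"{crossings.size} half-step crossings; using the one nearest "
            "the steepest slope",
            stacklevel=2,
        )
    T_mid = float(crossings[np.argmin(np.abs(crossings - Tr[i_steep]))])

    # tangent construction for onset/end
    m = slope[i_steep]
    tangent = (m, cpr[i_steep] - m * Tr[i_steep])
    onset = _intersect(tangent, baseline.solid)
    end = _intersect(tangent, baseline.liquid)
    if onset is None or end is None or not (onset < T_mid < end):
        # steep tangent pathologies (noise spikes); fall back to window edges
        onset = onset if onset is not None and onset < T_mid else float(Tr[0])
        end = end if end is not None and end > T_mid else float(Tr[-1])
    return GlassTransition(
        T_onset=float(onset),
        T_mid=T_mid,
        T_end=float(end),
        delta_cp_at_Tg=float(baseline.delta_cp(T_mid)),
        mode=mode,
    )


def _intersect(a: Line, b: Line) -> Optional[float]:
    if a[0] == b[0]:
        return None
    return (b[1] - a[1]) / (a[0] - b[0])


def integrate_enthalpy(curve: DSCCurve, T_ref: float, H_ref: float) -> EnthalpyCurve:
    """Cumulative trapezoidal integral of Cp over T, anchored at a reference.

    H(T) = H_ref + ∫_{T_ref}^{T} Cp dT on the sampled grid; the curve
    must be monotone in temperature (a single ramp).
    """
    if curve.signal_kind != SPECIFIC_HEAT:
        raise ValidationError("enthalpy integration expects a specific-heat curve")
    asc = curve.sorted_by_temperature()
    T, cp = asc.temperature, asc.value
    if np.any(np.diff(T) <= 0):
        raise ValidationError("curve temperature must be strictly monotone")
    if not (T[0] <= T_ref <= T[-1]):
        raise AnchorError(f"T_ref = {T_ref} K outside curve range [{T[0]}, {T[-1]}] K")
    H = cumulative_trapezoid(cp, T, initial=0.0)
    H = H - np.interp(T_ref, T, H) + H_ref
    return EnthalpyCurve(temperature=T, H=H, reference=(T_ref, H_ref))


def fit_enthalpy_line(curve: EnthalpyCurve, window: Tuple[float, float]) -> Line:
    """Least-squares line through H(T) inside a temperature window."""
    mask = _window_mask(curve.temperature, window)
    if mask.sum() < 2:
        raise WindowError(f"enthalpy window {window} contains < 2 samples")
    coef = np.polyfit(curve.temperature[mask], curve.H[mask], 1)
    return (float(coef[0]), float(coef[1]))


def fictive_temperature(
    H_glass: EnthalpyCurve,
    liquid_line: Line,
    glass_window: Tuple[float, float],
) -> FictiveTempResult:
    """T_f from the intersection of glass and liquid enthalpy lines.

    The glass line is the least-squares line through H(T) inside
    ``glass_window`` (well below the transition); the liquid line is
    the enthalpy of the equilibrium liquid extrapolated linearly to
    low temperature.  Their intersection is the fictive temperature.
    """
    glass_line = fit_enthalpy_line(H_glass, glass_window)
    slope_gap = abs(glass_line[0] - liquid_line[0])
    if slope_gap <= 1e-9 * max(abs(glass_line[0]), abs(liquid_line[0]), 1.0):
        raise ValidationError("glass and liquid enthalpy lines are parallel")
    Tf = _intersect(glass_line, liquid_line)
    mask = _window_mask(H_glass.temperature, glass_window)
    resid = H_glass.H[mask] - _eval_line(glass_line, H_glass.temperature[mask])
    return FictiveTempResult(
        Tf=float(Tf),
        method="enthalpy_intersection",
        diagnostics={
            "glass_line": glass_line,
            "liquid_line": tuple(liquid_line),
            "glass_rms": float(np.sqrt(np.mean(resid**2))),
        },
    )


def fictive_temperature_intersection(
    curve: DSCCurve,
    baseline: CpBaseline,
    *,
    glass_window: Optional[Tuple[float, float]] = None,
    liquid_window: Optional[Tuple[float, float]] = None,
) -> FictiveTempResult:
    """T_f where the glass enthalpy meets the extended liquid enthalpy.

    The solid and liquid enthalpy references are the integrals of the
    fitted Cp baseline lines, each anchored to the measured total
    enthalpy by its mean offset inside the corresponding window (glass
    branch below the transition, liquid branch above).  T_f solves

        H_solid_ref(Tf) = H_liquid_ref(Tf) ,

    i.e. the extended liquid enthalpy intersects the enthalpy of the
    glassy state.  Because the references integrate the same baseline
    lines used by the equal-area balance, the two constructions are
    analytically equivalent; fitting straight lines to H(T) instead
    would inject an O((dCp/dT)·ΔT²) extrapolation bias, since the
    enthalpy of a phase with linearly varying Cp is quadratic in T.
    """
    glass_window = glass_window or baseline.solid_window
    liquid_window = liquid_window or baseline.liquid_window
    H = integrate_enthalpy(curve, float(glass_window[0]), 0.0)
    T = H.temperature

    # antiderivatives of the baseline lines from T0 = glass_window[0]
    T0 = float(glass_window[0])

    def _antideriv(line: Line, Tq):
        return line[0] * (Tq**2 - T0**2) / 2.0 + line[1] * (Tq - T0)

    offsets = []
    for window, line in ((glass_window, baseline.solid), (liquid_window, baseline.liquid)):
        mask = _window_mask(T, window)
        if mask.sum() < 2:
            raise WindowError(f"window {window} contains < 2 enthalpy samples")
        offsets.append(float(np.mean(H.H[mask] - _antideriv(line, T[mask]))))
    c_glass, c_liquid = offsets

    # (L - S)(Tf) = c_glass - c_liquid, with L - S the ΔCp antiderivative
    a = baseline.liquid[0] - baseline.solid[0]
    b = baseline.liquid[1] - baseline.solid[1]
    target = c_glass - c_liquid

    def gap(Tf):
        return a * (Tf**2 - T0**2) / 2.0 + b * (Tf - T0) - target

    lo, hi = T0, float(liquid_window[1])
    if gap(lo) * gap(hi) > 0:
        raise TransitionNotFoundError("enthalpy references do not intersect in range")
    Tf = brentq(gap, lo, hi, xtol=1e-10)
    return FictiveTempResult(
        Tf=float(Tf),
        method="enthalpy_intersection",
        diagnostics={
            "glass_offset": c_glass,
            "liquid_offset": c_liquid,
            "glass_window": tuple(glass_window),
            "liquid_window": tuple(liquid_window),
        },
    )


def fictive_temperature_equal_area(
    curve: DSCCurve,
    baseline: CpBaseline,
    *,
    T_low: Optional[float] = None,
    T_high: Optional[float] = None,
) -> FictiveTempResult:
    """T_f by the Moynihan equal-area construction on the Cp curve.

    Solves  ∫_{Tf}^{T*} ΔCp dT = ∫_{T'}^{T*} (Cp − Cp_solid) dT,
    with T' below and T* above the transition (defaulting to the inner
    baseline-window edges).  Exact for data that follow the reference
    lines outside the transition.
    """
    if curve.signal_kind != SPECIFIC_HEAT:
        raise ValidationError("equal-area method expects a specific-heat curve")
    asc = curve.sorted_by_temperature()
    T, cp = asc.temperature, asc.value
    T_low = baseline.solid_window[1] if T_low is None else T_low
    T_high = baseline.liquid_window[0] if T_high is None else T_high
    if not (T[0] <= T_low < T_high <= T[-1]):
        raise ValidationError("curve must span [T_low, T_high]")

    mask = (T >= T_low) & (T <= T_high)
    Tm, cpm = T[mask], cp[mask]
    rhs = np.trapezoid(cpm - baseline.solid_at(Tm), Tm)

    # ∫_{Tf}^{T_high} ΔCp dT with linear ΔCp has a closed-form antiderivative
    a = baseline.liquid[0] - baseline.solid[0]
    b = baseline.liquid[1] - baseline.solid[1]

    def lhs_minus_rhs(Tf):
        return a * (T_high**2 - Tf**2) / 2.0 + b * (T_high - Tf) - rhs

    lo, hi = T_low, T_high
    if lhs_minus_rhs(lo) * lhs_minus_rhs(hi) > 0:
        raise TransitionNotFoundError("equal-area balance has no root in range")
    Tf = brentq(lhs_minus_rhs, lo, hi, xtol=1e-10)
    return FictiveTempResult(
        Tf=float(Tf),
        method="equal_area",
        diagnostics={"excess_area": float(rhs), "T_low": T_low, "T_high": T_high},
    )
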