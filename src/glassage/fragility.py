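"""Kinetic fragility from the scan-rate dependence of Tg / Tf.

Scanning a glass former at different rates shifts the glass transition:
faster scans freeze (or unfreeze) the structure at higher temperature.
The shift follows an Arrhenius-like law, so a regression of ln q on
1/T_char gives the apparent activation energy of structural
relaxation,

    Ea = −R · d ln q / d(1/T_char) ,

with T_char the heating-scan Tg or the cooling-scan limiting fictive
temperature Tf.  Scaling Ea by the thermal energy at Tg gives Angell's
fragility index

    m = Ea / (2.303 · R · Tg) ,

which ranks glass formers from "strong" (low m, near-Arrhenius) to
"fragile" (high m).  Amorphous drugs typically fall at m ≈ 60–120.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ConditioningError, ParameterError, ValidationError
from .units import GAS_CONSTANT

STRONG_LIMIT = 40.0  # m below this: "strong"
FRAGILE_LIMIT = 100.0  # m at or above this: "fragile"


@dataclass(frozen=True)
class RateSweepPoint:
    """One scan of a rate sweep: unsigned rate and its characteristic T."""

    rate: float  # K·min⁻¹, magnitude
    T_char: float  # K: Tg (heating) or limiting Tf (cooling)
    mode: str  # "heating" | "cooling"

    def __post_init__(self):
        if self.rate <= 0:
            raise ValidationError("rate magnitude must be positive")
        if self.T_char <= 0:
            raise ValidationError("T_char must be positive")
        if self.mode not in ("heating", "cooling"):
            raise ValidationError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class FragilityResult:
    Ea: float  # J·mol⁻¹
    m: float
    Tg_ref: float  # K
    slope: float  # K (of ln q vs 1/T)
    intercept: float
    r_squared: float
    label: str
    mode: str


def fit_activation_energy(
    points: Sequence[RateSweepPoint],
) -> Tuple[float, float, float, float]:
    """Regress ln(q) on 1/T_char; returns (Ea, slope, intercept, r²).

    All points must share one scan mode and have distinct rates; the
    spread of 1/T must be resolvable or the regression is declared
    degenerate.
    """
    if len(points) < 3:
        raise ValidationError("activation-energy fit needs at least 3 points")
    modes = {p.mode for p in points}
    if len(modes) != 1:
        raise ValidationError(f"mixed scan modes in one sweep: {sorted(modes)}")
    rates = np.array([p.rate for p in points])
    if np.unique(rates).size != rates.size:
        raise ValidationError("rates must be distinct")
    inv_T = 1.0 / np.array([p.T_char for p in points])
    if np.ptp(inv_T) < 1e-12 * np.mean(inv_T):
        raise ConditioningError("1/T spread too small to regress on")
    fit = stats.linregress(inv_T, np.log(rates))
    Ea = -GAS_CONSTANT * fit.slope
    return float(Ea), float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def fragility_m(Ea: float, Tg_ref: float) -> float:
    """Angell fragility index m = Ea / (2.303·R·Tg_ref)."""
    if Tg_ref <= 0:
        raise ParameterError("Tg_ref must be positive")
    return Ea / (2.303 * GAS_CONSTANT * Tg_ref)


def classify_fragility(m: float) -> str:
    """Classify m on the Angell scale: strong / moderately fragile / fragile."""
    if m <= 0:
        raise ParameterError("m must be positive")
    if m < STRONG_LIMIT:
        return "strong"
    if m < FRAGILE_LIMIT:
        return "moderately_fragile"
    return "fragile"


def analyze_sweep(
    points: Sequence[RateSweepPoint],
    Tg_ref: float | None = None,
    *,
    reference_rate: float = 10.0,
) -> FragilityResult:
    """Full fragility analysis of one rate sweep.

    ``Tg_ref`` defaults to the characteristic temperature of the sweep
    point closest (in log rate) to the 10 K·min⁻¹ reference protocol.
    """
    Ea, slope, intercept, r2 = fit_activation_energy(points)
    if Tg_ref is None:
        Tg_ref = min(
            points, key=lambda p: abs(np.log(p.rate / reference_rate))
        ).T_char
    m = fragility_m(Ea, Tg_ref)
    return FragilityResult(
        Ea=Ea,
        m=m,
        Tg_ref=Tg_ref,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        label=classify_fragility(m),
        mode=points[0].mode,
    )
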