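"""Enthalpy-relaxation quantification from aged/unaged thermogram pairs.

A glass stored at T_a < T_g slowly relaxes toward the equilibrium
supercooled liquid, losing enthalpy; on reheating that enthalpy is
recovered as an endothermic overshoot at the glass transition.  The
recovered enthalpy ΔH_r is the area between the aged and unaged scans,

    ΔH_r = (1/q)·∫_{T1}^{T2} (Φ_aged − Φ_unaged) dT
         = ∫_{T1}^{T2} (Cp_aged − Cp_unaged) dT ,

with T1 < T_g < T2.  The maximum recoverable enthalpy at T_a — the
equilibrium enthalpy relaxation — is

    ΔH_r^inf = ∫_{Ta}^{Tg} ΔCp dT ≈ ΔCp·(Tg − Ta).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dsc_io import DSCCurve, to_specific_heat
from .errors import ParameterError, RateMismatchError, ValidationError
from .thermal import CpBaseline
from .units import SECONDS_PER_HOUR, ZERO_CELSIUS

#: measurement standard deviation assigned to replicate-averaged points
#: when none is supplied (J·g⁻¹)
DEFAULT_SD = 0.3


@dataclass(frozen=True)
class AgeingRecord:
    """One enthalpy-relaxation measurement at (Ta, t_a)."""

    Ta: float  # K
    t_a: float  # s
    dHr: float  # J·g⁻¹
    sd: Optional[float] = None  # J·g⁻¹

    def __post_init__(self):
        if self.t_a < 0:
            raise ValidationError("ageing time must be non-negative")
        if self.dHr < -0.3:  # allow noise scatter around zero only
            raise ValidationError(f"dHr = {self.dHr} J/g is unphysically negative")
        if self.sd is not None and self.sd < 0:
            raise ValidationError("sd must be non-negative")


@dataclass
class RelaxationSeries:
    """ΔH_r versus ageing time at a single ageing temperature."""

    Ta: float  # K
    records: List[AgeingRecord] = field(default_factory=list)
    dHr_inf_fixed: Optional[float] = None  # J·g⁻¹

    def __post_init__(self):
        for r in self.records:
            if r.Ta != self.Ta:
                raise ValidationError("all records must share the series Ta")
        times = [r.t_a for r in self.records]
        if len(set(times)) != len(times):
            raise ValidationError("ageing times must be unique")
        self.records = sorted(self.records, key=lambda r: r.t_a)

    @property
    def times(self) -> np.ndarray:
        return np.array([r.t_a for r in self.records])

    @property
    def dHr(self) -> np.ndarray:
        return np.array([r.dHr for r in self.records])

    @property
    def sd(self) -> np.ndarray:
        return np.array([DEFAULT_SD if r.sd is None else r.sd for r in self.records])

    def __len__(self):
        return len(self.records)


def build_series(
    records: Sequence[AgeingRecord],
    dHr_inf_fixed: Optional[float] = None,
) -> RelaxationSeries:
    """Validate and sort records into a series (≥ 3 records, one Ta)."""
    if len(records) < 3:
        raise ValidationError("a relaxation series needs at least 3 records")
    Ta = records[0].Ta
    return RelaxationSeries(Ta=Ta, records=list(records), dHr_inf_fixed=dHr_inf_fixed)


def enthalpy_relaxation(
    aged: DSCCurve,
    unaged: DSCCurve,
    T1: float,
    T2: float,
) -> float:
    """ΔH_r from the area between aged and unaged heating scans.

    Both curves are brought to specific heat (heat-flow inputs are
    divided by their common scan rate), linearly interpolated onto the
    union of their temperature samples inside [T1, T2], and the Cp
    difference is integrated by the trapezoid rule.  The union grid is
    exact for piecewise-linear inputs and introduces no new extrema.
    """
    if T1 >= T2:
        raise ValidationError("require T1 < T2")
    if abs(aged.nominal_rate) != abs(unaged.nominal_rate):
        raise RateMismatchError(
            f"scan rates differ: {aged.nominal_rate} vs {unaged.nominal_rate} K/min"
        )
    cps = []
    for curve in (aged, unaged):
        cp = to_specific_heat(curve).sorted_by_temperature()
        if not (cp.temperature[0] <= T1 and cp.temperature[-1] >= T2):
            raise ValidationError(
                f"curve {curve.sample_id!r} does not cover [{T1}, {T2}] K"
            )
        cps.append(cp)
    grid = np.union1d(cps[0].temperature, cps[1].temperature)
    grid = grid[(grid >= T1) & (grid <= T2)]
    grid = np.union1d(grid, [T1, T2])
    diff = np.interp(grid, cps[0].temperature, cps[0].value) - np.interp(
        grid, cps[1].temperature, cps[1].value
    )
    return float(np.trapezoid(diff, grid))


def equilibrium_relaxation(
    baseline_or_dcp: Union[CpBaseline, float],
    Tg: float,
    Ta: float,
    mode: str = "scalar",
) -> float:
    """Equilibrium enthalpy relaxation ΔH_r^inf at ageing temperature Ta.

    ``scalar`` mode evaluates ΔCp·(Tg − Ta) with ΔCp taken at Tg;
    ``integral`` mode evaluates ∫_{Ta}^{Tg} ΔCp(T) dT exactly for the
    linear reference lines.  A plain float is accepted in place of a
    baseline and treated as a temperature-independent ΔCp (the two
    modes then coincide).
    """
    if Ta > Tg:
        raise ParameterError(f"Ta = {Ta} K must not exceed Tg = {Tg} K")
    if mode not in ("scalar", "integral"):
        raise ParameterError(f"unknown mode {mode!r}")
    if isinstance(baseline_or_dcp, CpBaseline):
        if mode == "scalar":
            return float(baseline_or_dcp.delta_cp(Tg) * (Tg - Ta))
        a = baseline_or_dcp.liquid[0] - baseline_or_dcp.solid[0]
        b = baseline_or_dcp.liquid[1] - baseline_or_dcp.solid[1]
        return float(a * (Tg**2 - Ta**2) / 2.0 + b * (Tg - Ta))
    dcp = float(baseline_or_dcp)
    return dcp * (Tg - Ta)


def series_to_frame(series: RelaxationSeries) -> pd.DataFrame:
    """Tabulate a series in the boundary units (°C, hours)."""
    return pd.DataFrame(
        {
            "Ta_C": [series.Ta - ZERO_CELSIUS] * len(series),
            "t_a_h": series.times / SECONDS_PER_HOUR,
            "dHr_J_per_g": series.dHr,
            "sd_J_per_g": series.sd,
        }
    )


def write_series(series: RelaxationSeries, path) -> None:
    series_to_frame(series).to_csv(path, index=False)


def read_series(path, dHr_inf_fixed: Optional[float] = None) -> RelaxationSeries:
    """Read a series CSV (columns Ta_C, t_a_h, dHr_J_per_g[, sd_J_per_g])."""
    table = pd.read_csv(path)
    for col in ("Ta_C", "t_a_h", "dHr_J_per_g"):
        if col not in table.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    Ta_vals = table["Ta_C"].unique()
    if Ta_vals.size != 1:
        raise ValidationError(f"{path}: mixed ageing temperatures {Ta_vals}")
    sd = table["sd_J_per_g"] if "sd_J_per_g" in table.columns else [None] * len(table)
    records = [
        AgeingRecord(
            Ta=float(Ta_vals[0]) + ZERO_CELSIUS,
            t_a=float(t) * SECONDS_PER_HOUR,
            dHr=float(h),
            sd=None if s is None or pd.isna(s) else float(s),
        )
        for t, h, s in zip(table["t_a_h"], table["dHr_J_per_g"], sd)
    ]
    return build_series(records, dHr_inf_fixed=dHr_inf_fixed)
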