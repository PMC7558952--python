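"""Thermogram I/O, unit normalisation and protocol segmentation.

A thermogram is a sampled record of one DSC experiment: time, sample
temperature and a per-gram signal (heat flow or apparent specific heat).
This module reads plain-text exports into :class:`DSCCurve` objects in
canonical units (K, s, W·g⁻¹ or J·g⁻¹·K⁻¹), converts between the two
signal kinds, and splits a multi-step record into the steps of its
declared thermal program.

Column mapping is configured through :class:`CsvDialect` rather than
hard-coded per vendor; one bundled dialect covers a plain CSV export
with canonical column names (``time_s``, ``temperature_C`` or
``temperature_K``, and one of ``heat_flow_mW`` / ``heat_flow_W_per_g`` /
``cp_J_per_gK``).  Heat flow is endothermic-up throughout; a vendor
export with the opposite convention is flipped by ``endo_up=False`` in
its dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError, RateMismatchError, SegmentationError, ValidationError
from .units import SECONDS_PER_MINUTE, celsius_to_kelvin, per_minute_to_per_second

HEAT_FLOW = "heat_flow_per_gram"
SPECIFIC_HEAT = "specific_heat"

_RATE_TOL = 1e-6  # relative tolerance for the ramp-consistency invariant


@dataclass(frozen=True)
class ThermalSegment:
    """One step of a thermal program: a linear ramp or an isothermal hold.

    ``rate`` is signed (negative on cooling) in K·min⁻¹ and ``duration``
    is in minutes, matching how instrument methods are written; the
    simulator converts to seconds internally.
    """

    kind: str  # "ramp" | "isothermal"
    T_start: float  # K
    T_end: float  # K
    rate: float  # K·min⁻¹, signed; 0 for isothermal
    duration: float  # min

    def __post_init__(self):
        if self.kind not in ("ramp", "isothermal"):
            raise ValidationError(f"unknown segment kind {self.kind!r}")
        if self.duration <= 0:
            raise ValidationError("segment duration must be positive")
        if self.kind == "isothermal":
            if self.rate != 0 or self.T_start != self.T_end:
                raise ValidationError(
                    "isothermal segment requires rate = 0 and T_start = T_end"
                )
        else:
            if self.rate == 0:
                raise ValidationError("ramp segment requires a nonzero rate")
            implied = (self.T_end - self.T_start) / self.duration
            if abs(implied - self.rate) > _RATE_TOL * max(abs(self.rate), 1.0):
                raise ValidationError(
                    f"ramp inconsistent: (T_end - T_start)/duration = {implied:.6g} "
                    f"K/min but rate = {self.rate:.6g} K/min"
                )


def ramp(T_start: float, T_end: float, rate_K_per_min: float) -> ThermalSegment:
    """Build a ramp segment from endpoints and an unsigned rate magnitude."""
    if rate_K_per_min <= 0:
        raise ValidationError("ramp rate magnitude must be positive")
    signed = rate_K_per_min if T_end > T_start else -rate_K_per_min
    duration = (T_end - T_start) / signed
    return ThermalSegment("ramp", T_start, T_end, signed, duration)


def isothermal(T: float, duration_min: float) -> ThermalSegment:
    return ThermalSegment("isothermal", T, T, 0.0, duration_min)


@dataclass(frozen=True)
class ThermalProgram:
    """An ordered sequence of thermal segments with continuous temperature."""

    segments: tuple

    def __init__(self, segments):
        object.__setattr__(self, "segments", tuple(segments))
        if not self.segments:
            raise ValidationError("program needs at least one segment")
        for a, b in zip(self.segments, self.segments[1:]):
            if abs(a.T_end - b.T_start) > 1e-9:
                raise ValidationError(
                    f"temperature discontinuity between segments: "
                    f"{a.T_end} K -> {b.T_start} K"
                )

    @property
    def total_duration(self) -> float:
        """Total program duration in minutes."""
        return sum(s.duration for s in self.segments)

    def boundaries_s(self) -> np.ndarray:
        """Cumulative segment end times in seconds, starting at 0."""
        ends = np.cumsum([s.duration * SECONDS_PER_MINUTE for s in self.segments])
        return np.concatenate([[0.0], ends])


@dataclass
class DSCCurve:
    """One thermogram segment in canonical units.

    ``value`` is either heat flow in W·g⁻¹ (endothermic up) or apparent
    specific heat in J·g⁻¹·K⁻¹, as declared by ``signal_kind``.
    ``nominal_rate`` is the unsigned programmed scan rate in K·min⁻¹
    (0 for an isothermal record).
    """

    sample_id: str
    signal_kind: str
    time: np.ndarray  # s
    temperature: np.ndarray  # K
    value: np.ndarray
    nominal_rate: float  # K·min⁻¹, magnitude
    mass_mg: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.signal_kind not in (HEAT_FLOW, SPECIFIC_HEAT):
            raise ValidationError(f"unknown signal kind {self.signal_kind!r}")
        n = self.time.size
        if not (n >= 2 and self.temperature.size == n and self.value.size == n):
            raise ValidationError("time/temperature/value must share length >= 2")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")

    def __len__(self):
        return self.time.size

    @property
    def is_heating(self) -> bool:
        return self.temperature[-1] > self.temperature[0]

    def sorted_by_temperature(self) -> "DSCCurve":
        """Return the curve with samples in ascending temperature order.

        For a cooling scan the sample order is reversed; the time axis
        is rebased (t' = t_end − t) so it stays strictly increasing.
        """
        if self.is_heating:
            return self
        sl = slice(None, None, -1)
        return replace(
            self,
            time=(self.time[-1] - self.time)[sl].copy(),
            temperature=self.temperature[sl].copy(),
            value=self.value[sl].copy(),
        )


@dataclass(frozen=True)
class CsvDialect:
    """Column-mapping and unit declaration for a delimited thermogram file."""

    time_col: str = "time_s"
    temperature_col: str = "temperature_C"
    signal_col: str = "heat_flow_mW"
    temperature_unit: str = "C"  # "C" | "K"
    signal_unit: str = "mW"  # "mW" | "W_per_g" | "J_per_gK"
    delimiter: str = ","
    endo_up: bool = True


DEFAULT_DIALECT = CsvDialect()

#: canonical column name -> (temperature unit, signal unit) used for sniffing
_CANONICAL_SIGNALS = {
    "heat_flow_mW": "mW",
    "heat_flow_W_per_g": "W_per_g",
    "cp_J_per_gK": "J_per_gK",
}


def sniff_dialect(path) -> CsvDialect:
    """Infer a dialect from canonical column names in the header row."""
    header = pd.read_csv(path, nrows=0).columns
    cols = set(header)
    if "temperature_K" in cols:
        t_col, t_unit = "temperature_K", "K"
    elif "temperature_C" in cols:
        t_col, t_unit = "temperature_C", "C"
    else:
        raise FormatError(f"{path}: no temperature_C or temperature_K column")
    for sig_col, sig_unit in _CANONICAL_SIGNALS.items():
        if sig_col in cols:
            return CsvDialect(
                time_col="time_s",
                temperature_col=t_col,
                signal_col=sig_col,
                temperature_unit=t_unit,
                signal_unit=sig_unit,
            )
    raise FormatError(f"{path}: no recognised signal column in {sorted(cols)}")


def read_curve(
    path,
    dialect: Optional[CsvDialect] = None,
    *,
    mass_mg: Optional[float] = None,
    nominal_rate: float = 0.0,
    sample_id: Optional[str] = None,
    metadata: Optional[dict] = None,
) -> DSCCurve:
    """Read a delimited thermogram into canonical units.

    An absolute heat-flow signal (mW) requires ``mass_mg`` to normalise
    to W·g⁻¹.  Temperatures in °C are shifted to kelvin; per-gram and
    specific-heat signals pass through unchanged.
    """
    path = Path(path)
    if dialect is None:
        dialect = sniff_dialect(path)
    try:
        table = pd.read_csv(path, delimiter=dialect.delimiter)
    except Exception as exc:  # malformed delimiter/quoting
        raise FormatError(f"{path}: {exc}") from exc
    for col in (dialect.time_col, dialect.temperature_col, dialect.signal_col):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")

    time = table[dialect.time_col].to_numpy(dtype=float)
    temp = table[dialect.temperature_col].to_numpy(dtype=float)
    sig = table[dialect.signal_col].to_numpy(dtype=float)

    if dialect.temperature_unit == "C":
        temp = celsius_to_kelvin(temp)
    elif dialect.temperature_unit != "K":
        raise FormatError(f"unknown temperature unit {dialect.temperature_unit!r}")

    if dialect.signal_unit == "mW":
        if mass_mg is None:
            raise ValidationError("absolute heat flow (mW) requires mass_mg")
        sig = sig / mass_mg  # mW / mg == W / g
        kind = HEAT_FLOW
    elif dialect.signal_unit == "W_per_g":
        kind = HEAT_FLOW
    elif dialect.signal_unit == "J_per_gK":
        kind = SPECIFIC_HEAT
    else:
        raise FormatError(f"unknown signal unit {dialect.signal_unit!r}")
    if kind == HEAT_FLOW and not dialect.endo_up:
        sig = -sig

    return DSCCurve(
        sample_id=sample_id or path.stem,
        signal_kind=kind,
        time=time,
        temperature=temp,
        value=sig,
        nominal_rate=nominal_rate,
        mass_mg=mass_mg,
        metadata=dict(metadata or {}),
    )


def write_curve(curve: DSCCurve, path) -> None:
    """Write a curve in the canonical CSV dialect (K, s, per-gram signal)."""
    sig_col = "cp_J_per_gK" if curve.signal_kind == SPECIFIC_HEAT else "heat_flow_W_per_g"
    pd.DataFrame(
        {
            "time_s": curve.time,
            "temperature_K": curve.temperature,
            sig_col: curve.value,
        }
    ).to_csv(path, index=False)


def to_specific_heat(curve: DSCCurve) -> DSCCurve:
    """Convert a per-gram heat-flow ramp to apparent specific heat.

    Cp = Φ / |q| with q the programmed scan rate in K·s⁻¹.  The signal
    is endothermic-up, so an endothermic step appears as a Cp increase.
    """
    if curve.signal_kind == SPECIFIC_HEAT:
        return curve
    if curve.nominal_rate == 0:
        raise RateMismatchError("cannot convert an isothermal record to Cp")
    q = per_minute_to_per_second(abs(curve.nominal_rate))
    return replace(curve, signal_kind=SPECIFIC_HEAT, value=curve.value / q)


def to_heat_flow(curve: DSCCurve) -> DSCCurve:
    """Inverse of :func:`to_specific_heat`: Φ = Cp · |q|."""
    if curve.signal_kind == HEAT_FLOW:
        return curve
    if curve.nominal_rate == 0:
        raise RateMismatchError("cannot convert an isothermal record to heat flow")
    q = per_minute_to_per_second(abs(curve.nominal_rate))
    return replace(curve, signal_kind=HEAT_FLOW, value=curve.value * q)


def segment_curve(curve: DSCCurve, program: ThermalProgram, *, temp_tol: float = 2.0):
    """Split a thermogram into its program steps by elapsed time.

    Samples are assigned to segments by the program's cumulative time
    boundaries (curve time zero is the program start).  Each sub-curve
    is checked against its segment's temperature span within
    ``temp_tol`` kelvin (default 2 K, allowing instrument lag).
    Concatenating the outputs reproduces the input exactly.
    """
    bounds = program.boundaries_s()
    if curve.time[-1] > bounds[-1] + 1e-6:
        raise SegmentationError(
            f"curve extends to {curve.time[-1]:.1f} s but program ends "
            f"at {bounds[-1]:.1f} s"
        )
    out = []
    for k, seg in enumerate(program.segments):
        lo, hi = bounds[k], bounds[k + 1]
        if k == len(program.segments) - 1:
            mask = (curve.time >= lo) & (curve.time <= hi + 1e-9)
        else:
            mask = (curve.time >= lo) & (curve.time < hi)
        if mask.sum() < 2:
            continue
        sub = replace(
            curve,
            time=curve.time[mask].copy(),
            temperature=curve.temperature[mask].copy(),
            value=curve.value[mask].copy(),
            nominal_rate=abs(seg.rate),
        )
        t_lo = min(seg.T_start, seg.T_end) - temp_tol
        t_hi = max(seg.T_start, seg.T_end) + temp_tol
        if sub.temperature.min() < t_lo or sub.temperature.max() > t_hi:
            raise SegmentationError(
                f"segment {k}: samples span "
                f"[{sub.temperature.min():.2f}, {sub.temperature.max():.2f}] K, "
                f"outside program span [{t_lo:.2f}, {t_hi:.2f}] K"
            )
        out.append((seg, sub))
    if not out:
        raise SegmentationError("no segment captured at least two samples")
    return out
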