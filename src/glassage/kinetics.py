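"""KWW stretched-exponential kinetics of isothermal physical ageing.

Enthalpy relaxation during isothermal ageing follows the
Kohlrausch-Williams-Watts law

    ΔH_r(t) = ΔH_r^inf · [1 − exp(−(t/τ)^β)] ,     0 < β ≤ 1,

whose complement, the recovery parameter

    φ(t) = exp(−(t/τ)^β) = 1 − ΔH_r/ΔH_r^inf ,

measures the fraction of the departure from equilibrium still
remaining.  β < 1 broadens the underlying relaxation-time
distribution; τ is the characteristic relaxation time.

Fits are weighted nonlinear least squares through lmfit with a
log-parametrised τ and ΔH_r^inf (τ spans hours to years across
ageing temperatures) and β bounded in (0, 1], with a log-spaced τ
multi-start for robustness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import lmfit
import numpy as np

from .ageing import RelaxationSeries
from .errors import FitConvergenceError, ParameterError, ValidationError

_BETA_MIN = 1e-3


def _check_kww_params(tau: float, beta: float) -> None:
    if tau <= 0:
        raise ParameterError(f"tau must be positive, got {tau}")
    if not (0 < beta <= 1):
        raise ParameterError(f"beta must lie in (0, 1], got {beta}")


def kww_predict(t, tau: float, beta: float, dHr_inf: float):
    """ΔH_r(t) = ΔH_r^inf · [1 − exp(−(t/τ)^β)]."""
    _check_kww_params(tau, beta)
    if dHr_inf <= 0:
        raise ParameterError(f"dHr_inf must be positive, got {dHr_inf}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("ageing time must be non-negative")
    return dHr_inf * (1.0 - np.exp(-((t / tau) ** beta)))


def recovery(t, tau: float, beta: float):
    """Recovery parameter φ(t) = exp(−(t/τ)^β)."""
    _check_kww_params(tau, beta)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("ageing time must be non-negative")
    return np.exp(-((t / tau) ** beta))


@dataclass(frozen=True)
class RecoveryPoint:
    t_a: float  # s
    phi: float

    def __post_init__(self):
        if not (0.0 <= self.phi <= 1.0):
            raise ValidationError(f"phi = {self.phi} outside [0, 1]")


def recovery_from_series(
    series: RelaxationSeries, dHr_inf: float
) -> List[RecoveryPoint]:
    """Experimental φ_i = 1 − ΔH_r,i / ΔH_r^inf, clipped into [0, 1].

    Clipping only engages when noise pushes a measured ΔH_r slightly
    past ΔH_r^inf or below zero; a warning is emitted then.
    """
    if dHr_inf <= 0:
        raise ParameterError("dHr_inf must be positive")
    phi = 1.0 - series.dHr / dHr_inf
    if np.any(phi < 0) or np.any(phi > 1):
        import warnings

        warnings.warn("phi outside [0, 1]; clipping (dHr exceeds dHr_inf?)", stacklevel=2)
        phi = np.clip(phi, 0.0, 1.0)
    return [RecoveryPoint(t, float(p)) for t, p in zip(series.times, phi)]


@dataclass(frozen=True)
class KWWFit:
    """Result of fitting the KWW law to a relaxation series."""

    tau: float  # s
    beta: float
    dHr_inf: float  # J·g⁻¹
    fixed_flags: dict  # parameter name -> was held fixed
    covariance: Optional[np.ndarray]  # free parameters, fit order
    stderr: dict  # parameter name -> standard error (NaN if fixed/unavailable)
    rss: float  # (J·g⁻¹)²
    n_points: int

    def __post_init__(self):
        _check_kww_params(self.tau, self.beta)
        if self.dHr_inf <= 0:
            raise ParameterError("dHr_inf must be positive")

    def predict(self, t):
        return kww_predict(t, self.tau, self.beta, self.dHr_inf)


def _initial_guesses(times: np.ndarray, dhr: np.ndarray) -> Tuple[float, float]:
    """(dHr_inf0, tau0): 1.2×max amplitude; τ at the half-amplitude
    crossing, log-interpolated between bracketing samples."""
    dhr_inf0 = 1.2 * float(np.max(dhr))
    half = 0.5 * dhr_inf0
    pos = times > 0
    t_pos, h_pos = times[pos], dhr[pos]
    above = np.nonzero(h_pos >= half)[0]
    if above.size == 0 or above[0] == 0:
        tau0 = float(t_pos[-1] if above.size == 0 else t_pos[0])
    else:
        i = above[0]
        lt = np.log(t_pos[i - 1 : i + 1])
        f = (half - h_pos[i - 1]) / (h_pos[i] - h_pos[i - 1])
        tau0 = float(np.exp(lt[0] + f * (lt[1] - lt[0])))
    return dhr_inf0, tau0


def fit_kww(
    series: RelaxationSeries,
    *,
    dHr_inf_fixed: Optional[float] = None,
    beta0: float = 0.5,
    n_starts: int = 5,
) -> KWWFit:
    """Weighted nonlinear least-squares fit of the KWW law.

    Minimises Σ w_i (ΔH_r,i − model)² with w_i = 1/sd_i²; requires at
    least 4 points with all three parameters free, or 3 with ΔH_r^inf
    fixed (from the equilibrium value or the series itself).  A
    5-point log-spaced τ multi-start guards against the shallow
    τ–ΔH_r^inf valley when all times are far below τ.
    """
    if dHr_inf_fixed is None:
        dHr_inf_fixed = series.dHr_inf_fixed
    times, dhr, sd = series.times, series.dHr, series.sd
    n_free = 2 if dHr_inf_fixed is not None else 3
    if len(series) < n_free + 1:
        raise ValidationError(
            f"need at least {n_free + 1} points for {n_free} free parameters"
        )
    if np.all(dhr <= 0):
        raise ValidationError("no positive dHr values; nothing to fit")
    weights = 1.0 / sd

    dhr_inf0, tau0 = _initial_guesses(times, dhr)
    if dHr_inf_fixed is not None:
        dhr_inf0 = dHr_inf_fixed

    def residual(params):
        tau = np.exp(params["ln_tau"].value)
        inf = np.exp(params["ln_dHr_inf"].value)
        model = inf * (1.0 - np.exp(-((times / tau) ** params["beta"].value)))
        return (dhr - model) * weights

    # physical plausibility bounds: the equilibrium amplitude cannot sit
    # orders of magnitude beyond the largest observed recovery, and tau far
    # outside the observed time window is unidentifiable anyway.  Without
    # them, noisy short-time series can run down the open tau-amplitude
    # ridge (dHr_inf -> inf with the model degenerating to a power law).
    max_dhr = float(np.max(dhr))
    inf_bounds = (np.log(0.5 * max_dhr), np.log(50.0 * max_dhr))
    tau_bounds = (
        np.log(np.min(times[times > 0]) * 1e-6),
        np.log(np.max(times) * 1e6),
    )

    best = None
    for tau_start in tau0 * np.logspace(-2, 2, n_starts):
        params = lmfit.Parameters()
        params.add(
            "ln_tau",
            value=float(np.clip(np.log(tau_start), *tau_bounds)),
            min=tau_bounds[0],
            max=tau_bounds[1],
        )
        params.add("beta", value=beta0, min=_BETA_MIN, max=1.0)
        params.add(
            "ln_dHr_inf",
            value=float(np.clip(np.log(dhr_inf0), *inf_bounds))
            if dHr_inf_fixed is None
            else np.log(dhr_inf0),
            min=inf_bounds[0] if dHr_inf_fixed is None else -np.inf,
            max=inf_bounds[1] if dHr_inf_fixed is None else np.inf,
            vary=dHr_inf_fixed is None,
        )
        try:
            result = lmfit.minimize(
                residual,
                params,
                method="least_squares",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
        except Exception:
            continue
        if result.success and (best is None or result.chisqr < best.chisqr):
            best = result
    if best is None:
        raise FitConvergenceError(
            f"KWW fit failed after {n_starts}-point multi-start "
            f"(Ta = {series.Ta:.2f} K, n = {len(series)})"
        )

    tau = float(np.exp(best.params["ln_tau"].value))
    beta = float(best.params["beta"].value)
    dhr_inf = float(np.exp(best.params["ln_dHr_inf"].value))

    # back-transform standard errors from the log/bounded internal scale
    stderr = {"tau": np.nan, "beta": np.nan, "dHr_inf": np.nan}
    if best.errorbars:
        se = {p: best.params[p].stderr for p in best.params}
        if se.get("ln_tau") is not None:
            stderr["tau"] = tau * se["ln_tau"]
        if se.get("beta") is not None:
            stderr["beta"] = se["beta"]
        if dHr_inf_fixed is None and se.get("ln_dHr_inf") is not None:
            stderr["dHr_inf"] = dhr_inf * se["ln_dHr_inf"]
    covar = getattr(best, "covar", None)

    return KWWFit(
        tau=tau,
        beta=beta,
        dHr_inf=dhr_inf,
        fixed_flags={
            "tau": False,
            "beta": False,
            "dHr_inf": dHr_inf_fixed is not None,
        },
        covariance=None if covar is None else np.asarray(covar),
        stderr=stderr,
        rss=float(np.sum((dhr - kww_predict(times, tau, beta, dhr_inf)) ** 2)),
        n_points=len(series),
    )


def fictive_vs_time(
    series: RelaxationSeries, Tg: float, dcp: float
) -> List[Tuple[float, float]]:
    """Linearised fictive temperature along an ageing series.

    T_f(t) = T_g − ΔH_r(t)/ΔCp: equal to T_g for the unaged glass and
    reaching T_a when ΔH_r attains the equilibrium value ΔCp·(Tg − Ta).
    """
    if dcp <= 0:
        raise ParameterError("dcp must be positive")
    return [(float(t), float(Tg - h / dcp)) for t, h in zip(series.times, series.dHr)]
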