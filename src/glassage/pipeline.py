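"""Config-driven replication of the full ageing / fragility study design.

Two entry points mirror the two halves of the study:

* :func:`run_ageing_study` — per ageing temperature: obtain a
  ΔH_r(t_a) series (either simulated thermograms analysed through the
  area integral, or a pre-tabulated KWW series), fit the KWW law,
  derive recovery parameters and fictive temperatures, and compare
  against the equilibrium enthalpy relaxation (scalar and integral).
* :func:`run_fragility_study` — simulate heating- and cooling-rate
  sweeps, extract Tg / limiting T_f per scan, regress ln q on 1/T and
  report activation energy, fragility index m and its classification.

Both write one JSON report (plus CSV tables) and are fully
reproducible from the seed; a stage failure at one temperature is
recorded in the report without aborting the rest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from . import ageing as ag
from . import fragility as fr
from . import kinetics as kin
from . import synthetic as syn
from . import thermal as th
from .errors import ValidationError
from .units import SECONDS_PER_HOUR, ZERO_CELSIUS

log = logging.getLogger("glassage")

REPORT_SCHEMA = "glassage-report/1"


@dataclass
class StudyConfig:
    """Study design: temperatures, times, rates, windows and fit options."""

    source: str = "tnm"  # "tnm" (thermograms) | "series" (tabulated dHr)
    ageing_temperatures_C: List[float] = field(default_factory=lambda: [65.0, 75.0, 85.0])
    ageing_times_h: List[float] = field(
        default_factory=lambda: [0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0, 32.0]
    )
    heating_rates: List[float] = field(
        default_factory=lambda: [0.5, 1.0, 2.0, 5.0, 10.0, 20.0]
    )
    cooling_rates: List[float] = field(
        default_factory=lambda: [0.2, 0.5, 1.0, 2.0, 5.0, 10.0]
    )
    solid_window_K: List[float] = field(default_factory=lambda: [300.0, 330.0])
    liquid_window_K: List[float] = field(default_factory=lambda: [400.0, 430.0])
    integration_margin_K: List[float] = field(default_factory=lambda: [40.0, 25.0])
    noise_sd: float = 0.0
    seed: int = 0
    dHr_inf_mode: str = "free"  # "free" | "scalar" | "integral"
    series_params: dict = field(
        default_factory=lambda: {
            str(k): dict(v) for k, v in syn.INDAPAMIDE_AGEING_KINETICS.items()
        }
    )
    tnm: dict = field(default_factory=dict)  # overrides for default_tnm_parameters

    def __post_init__(self):
        if not self.ageing_temperatures_C:
            raise ValidationError("ageing_temperatures_C must be non-empty")
        if not self.ageing_times_h:
            raise ValidationError("ageing_times_h must be non-empty")
        if self.source not in ("tnm", "series"):
            raise ValidationError(f"unknown source {self.source!r}")
        for Ta in self.ageing_temperatures_C:
            if Ta + ZERO_CELSIUS >= self.liquid_window_K[0]:
                raise ValidationError(
                    f"ageing temperature {Ta} C is not below the liquid window"
                )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _tnm_params(config: StudyConfig) -> syn.TNMParameters:
    return syn.default_tnm_parameters(**config.tnm)


def _series_from_tnm(config: StudyConfig, Ta_K: float) -> ag.RelaxationSeries:
    """Simulate the full cool–hold–cool–reheat protocol per ageing time
    and quantify ΔH_r against the unaged (zero-hold) reference scan."""
    params = _tnm_params(config)
    unaged = syn.simulate_tnm(syn.ageing_protocol(Ta_K, 0.0), params)
    unaged_heat = unaged.final_heating_curve
    baseline = th.fit_cp_baselines(
        unaged_heat, tuple(config.solid_window_K), tuple(config.liquid_window_K)
    )
    tg = th.detect_glass_transition(unaged_heat, baseline)
    T1 = tg.T_mid - config.integration_margin_K[0]
    T2 = tg.T_mid + config.integration_margin_K[1]
    records = []
    for t_h in config.ageing_times_h:
        aged = syn.simulate_tnm(
            syn.ageing_protocol(Ta_K, t_h * SECONDS_PER_HOUR), params
        )
        dhr = ag.enthalpy_relaxation(aged.final_heating_curve, unaged_heat, T1, T2)
        records.append(ag.AgeingRecord(Ta=Ta_K, t_a=t_h * SECONDS_PER_HOUR, dHr=dhr))
    return ag.build_series(records)


def _series_from_table(config: StudyConfig, Ta_C: float, index: int) -> ag.RelaxationSeries:
    try:
        p = config.series_params[str(Ta_C)]
    except KeyError:
        raise ValidationError(f"no series parameters for Ta = {Ta_C} C") from None
    times = np.asarray(config.ageing_times_h) * SECONDS_PER_HOUR
    return syn.simulate_kww_series(
        Ta=Ta_C + ZERO_CELSIUS,
        times=times,
        tau=p["tau_s"],
        beta=p["beta"],
        dHr_inf=p["dHr_inf"],
        noise_sd=config.noise_sd,
        seed=config.seed + index,
    )


def run_ageing_study(config: StudyConfig, outdir: Optional[Path] = None) -> dict:
    """Execute the isothermal-ageing analysis for every ageing temperature."""
    params = _tnm_params(config)
    baseline = params.cp_baseline
    tg_nominal = syn.T_REF  # reference Tg for equilibrium values and Tf mapping
    dcp = float(baseline.delta_cp(tg_nominal))

    report = {
        "schema": REPORT_SCHEMA,
        "config_hash": config.hash(),
        "seed": config.seed,
        "source": config.source,
        "temperatures": [],
    }
    rows = []
    for idx, Ta_C in enumerate(config.ageing_temperatures_C):
        Ta_K = Ta_C + ZERO_CELSIUS
        entry = {"Ta_C": Ta_C}
        try:
            log.info("ageing stage: Ta = %.1f C (source=%s)", Ta_C, config.source)
            if config.source == "series":
                series = _series_from_table(config, Ta_C, idx)
            else:
                series = _series_from_tnm(config, Ta_K)

            eq_scalar = ag.equilibrium_relaxation(dcp, tg_nominal, Ta_K, "scalar")
            eq_integral = ag.equilibrium_relaxation(baseline, tg_nominal, Ta_K, "integral")
            fixed = {
                "free": None,
                "scalar": eq_scalar,
                "integral": eq_integral,
            }[config.dHr_inf_mode]
            if len(series) > 0 and np.any(series.dHr > 0.05):
                fit = kin.fit_kww(series, dHr_inf_fixed=fixed)
                phi_model = [
                    float(kin.recovery(t, fit.tau, fit.beta)) for t in series.times
                ]
                phi_exp = [p.phi for p in kin.recovery_from_series(series, fit.dHr_inf)]
                entry["kww"] = {
                    "tau_s": fit.tau,
                    "tau_h": fit.tau / SECONDS_PER_HOUR,
                    "beta": fit.beta,
                    "dHr_inf": fit.dHr_inf,
                    "rss": fit.rss,
                    "stderr": {k: _nan_none(v) for k, v in fit.stderr.items()},
                    "fixed": fit.fixed_flags,
                }
            else:
                fit = None
                phi_model = phi_exp = [None] * len(series)
                entry["kww"] = None
                entry["warning"] = "no measurable relaxation; KWW fit skipped"
                log.warning("Ta=%.1f C: all dHr ~ 0, fit skipped", Ta_C)
            tf_t = kin.fictive_vs_time(series, tg_nominal, dcp)
            entry["equilibrium"] = {"scalar": eq_scalar, "integral": eq_integral}
            entry["points"] = [
                {
                    "t_a_h": float(t / SECONDS_PER_HOUR),
                    "dHr": float(h),
                    "phi_model": phi_model[i],
                    "phi_experimental": phi_exp[i],
                    "Tf_K": tf_t[i][1],
                }
                for i, (t, h) in enumerate(zip(series.times, series.dHr))
            ]
            for p in entry["points"]:
                rows.append({"Ta_C": Ta_C, **p})
        except Exception as exc:  # record per-temperature failures, keep going
            log.exception("stage failed at Ta = %.1f C", Ta_C)
            entry["error"] = f"{type(exc).__name__}: {exc}"
        report["temperatures"].append(entry)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "ageing_report.json").write_text(json.dumps(report, indent=2))
        pd.DataFrame(rows).to_csv(outdir / "series.csv", index=False)
    return report


def run_fragility_study(config: StudyConfig, outdir: Optional[Path] = None) -> dict:
    """Rate sweeps on the TNM glass: Tg (heating) and limiting T_f (cooling)."""
    if len(config.heating_rates) < 3 or len(config.cooling_rates) < 3:
        raise ValidationError("fragility sweeps need at least 3 rates each")
    params = _tnm_params(config)
    solid_w = tuple(config.solid_window_K)
    liquid_w = tuple(config.liquid_window_K)

    heating_pts, cooling_pts, rows = [], [], []
    for q in config.heating_rates:
        log.info("fragility heating scan at %.2g K/min", q)
        out = syn.simulate_tnm(syn.heating_rate_protocol(q), params)
        heat = out.final_heating_curve
        baseline = th.fit_cp_baselines(heat, solid_w, liquid_w)
        tg = th.detect_glass_transition(heat, baseline)
        heating_pts.append(fr.RateSweepPoint(rate=q, T_char=tg.T_mid, mode="heating"))
        rows.append({"mode": "heating", "rate_K_per_min": q, "T_char_K": tg.T_mid})
    for q in config.cooling_rates:
        log.info("fragility cooling scan at %.2g K/min", q)
        out = syn.simulate_tnm(syn.cooling_rate_protocol(q), params)
        cool = out.segment_curve(0)
        baseline = th.fit_cp_baselines(cool, solid_w, liquid_w)
        tf = th.fictive_temperature_equal_area(cool, baseline)
        cooling_pts.append(fr.RateSweepPoint(rate=q, T_char=tf.Tf, mode="cooling"))
        rows.append({"mode": "cooling", "rate_K_per_min": q, "T_char_K": tf.Tf})

    heating = fr.analyze_sweep(heating_pts)
    cooling = fr.analyze_sweep(cooling_pts)
    report = {
        "schema": REPORT_SCHEMA,
        "config_hash": config.hash(),
        "seed": config.seed,
        "heating": _fragility_dict(heating),
        "cooling": _fragility_dict(cooling),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "fragility_report.json").write_text(json.dumps(report, indent=2))
        pd.DataFrame(rows).to_csv(outdir / "sweep.csv", index=False)
    return report


def _fragility_dict(res: fr.FragilityResult) -> dict:
    return {
        "Ea_kJ_per_mol": res.Ea / 1e3,
        "m": res.m,
        "Tg_ref_K": res.Tg_ref,
        "r_squared": res.r_squared,
        "label": res.label,
    }


def _nan_none(v):
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)
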