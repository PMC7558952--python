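"""Shared fixtures: TNM simulations and their standard analyses.

All thermogram fixtures are generated at test time by the package's
own TNM simulator; session scope keeps each simulation to one run.
"""

import numpy as np
import pytest

import glassage as ga
import glassage.thermal as th
from glassage.units import SECONDS_PER_HOUR

SOLID_WINDOW = (300.0, 330.0)
LIQUID_WINDOW = (400.0, 430.0)
TA_85C = 358.15  # K
AGE_HOURS = (0.5, 2.0, 8.0, 32.0)


@pytest.fixture(scope="session")
def tnm_params():
    return ga.default_tnm_parameters()


@pytest.fixture(scope="session")
def unaged_sim(tnm_params):
    """Cool–cool–hold–reheat protocol with no ageing hold, finely stepped."""
    return ga.simulate_tnm(
        ga.ageing_protocol(TA_85C, 0.0), tnm_params, max_step_K=0.25
    )


@pytest.fixture(scope="session")
def aged_sims(tnm_params):
    """Ageing holds at 85 °C for 0.5–32 h, keyed by hours."""
    return {
        h: ga.simulate_tnm(
            ga.ageing_protocol(TA_85C, h * SECONDS_PER_HOUR),
            tnm_params,
            max_step_K=0.25,
        )
        for h in AGE_HOURS
    }


@pytest.fixture(scope="session")
def equilibrated_sim(tnm_params):
    """A hold long enough (1000 h) to relax essentially to equilibrium."""
    return ga.simulate_tnm(
        ga.ageing_protocol(TA_85C, 1000.0 * SECONDS_PER_HOUR),
        tnm_params,
        max_step_K=0.25,
        iso_steps=300,
    )


@pytest.fixture(scope="session")
def unaged_analysis(unaged_sim):
    """(heating curve, fitted baseline, detected transition) of the unaged glass."""
    heat = unaged_sim.final_heating_curve
    baseline = th.fit_cp_baselines(heat, SOLID_WINDOW, LIQUID_WINDOW)
    tg = th.detect_glass_transition(heat, baseline)
    return heat, baseline, tg


@pytest.fixture(scope="session")
def fragility_report():
    from glassage.pipeline import StudyConfig, run_fragility_study

    return run_fragility_study(StudyConfig())


@pytest.fixture(scope="session")
def ageing_report_tnm():
    from glassage.pipeline import StudyConfig, run_ageing_study

    return run_ageing_study(StudyConfig(source="tnm"))


@pytest.fixture(scope="session")
def ageing_report_series():
    from glassage.pipeline import StudyConfig, run_ageing_study

    return run_ageing_study(StudyConfig(source="series", noise_sd=0.0))
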