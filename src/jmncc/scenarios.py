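"""Canonical desk-scale simulation scenarios.

These are the frozen study conditions used by the shipped experiments,
the test suite and ``scripts/acceptance.py``. They scale the full design
(N=8000 cohort, 400 cases) down proportionally to N=2000 with 100 cases
so that a 200-replicate batch runs in minutes on one CPU, keeping the
case fraction (~5%), the 1:m gender-matched incidence-density sampling,
the two-step censoring and the 2:1 cause mix. The multi-feature design
is scaled separately (see :func:`study3_scenario` and docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from .experiments import Scenario
from .simulator import SimConfig

__all__ = [
    "study1_simconfig",
    "study1_scenario",
    "study2_scenario",
    "study3_scenario",
    "STUDY3_FEATURES",
    "STUDY3_SIGNAL_FRACTION",
    "STUDY3_BETA_SIGNAL",
]

#: Study-3 multi-feature design constants (fractions/effects from the
#: high-dimensional simulation design; scale is desk-sized)
STUDY3_FEATURES = 50
STUDY3_SIGNAL_FRACTION = 0.1
STUDY3_BETA_SIGNAL = (0.5, -0.5)


def study1_simconfig(beta1: float = 0.0, beta2: float = 0.0) -> SimConfig:
    """Scaled Study-1 generator: N=2000 cohort, 100 cases, constant
    baselines, random-intercept linear trajectory.

    Scenario 1 is the global null (``beta1=beta2=0``); Scenario 2 fixes
    ``beta2=0.1`` and varies ``beta1`` (0.3 in the headline table).
    """
    return SimConfig(
        N=2000,
        n_cases_target=100,
        censor_hi=5.0,
        beta=(beta1, beta2),
    )


def study1_scenario(m: int = 1, beta1: float = 0.0, beta2: float = 0.0) -> Scenario:
    """Scaled Study-1 scenario with 1:m gender-matched NCC sampling."""
    return Scenario(sim=study1_simconfig(beta1, beta2), m=m)


def study2_scenario(m: int = 1, beta1: float = 0.0, beta2: float = 0.0) -> Scenario:
    """Scaled Study-2 scenario: random intercept + slope trajectories and
    piecewise-constant baselines rising across three intervals."""
    sim = SimConfig(
        N=2000,
        n_cases_target=100,
        censor_hi=5.0,
        random_effects="intercept_slope",
        theta_var=1.0,
        theta_slope_var=0.04,
        knots=(1.5, 3.0, np.inf),
        xi=(
            (0.008, 0.016, 0.032),
            (0.004, 0.008, 0.016),
        ),
        beta=(beta1, beta2),
    )
    return Scenario(sim=sim, m=m, nodes=9)


def study3_scenario(m: int = 1) -> Scenario:
    """Scaled Study-3 multi-feature scenario.

    Signal features carry (0.5, -0.5) effects on the two cause-specific
    hazards; the per-feature trajectory uses a modest slope so that the
    aggregate signal trend stays within what the piecewise fitted
    baseline (Q=3) can absorb — emulating the weak community-level
    trends of sparse taxa panels.
    """
    sim = SimConfig(
        N=800,
        n_cases_target=90,
        censor_hi=6.0,
        grid=0.5,
        gamma=(0.0, 0.1),
        xi=((0.0235,), (0.0168,)),
    )
    return Scenario(sim=sim, m=m, nodes=7, fit_knots=(1.5, 3.0, np.inf))
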