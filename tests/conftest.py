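import warnings

import numpy as np
import pytest

from jmncc import (
    MatchingSpec,
    ModelTemplate,
    SimConfig,
    attach_longitudinal,
    compute_inclusion_weights,
    sample_longitudinal,
    sample_ncc,
    simulate_full_cohort,
)
from jmncc.datamodel import CohortData, LongitudinalSeries, SubjectSurvival


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


def make_subject(sid, time, status, **covs):
    return SubjectSurvival(id=sid, time=time, status=status, covariates=covs)


@pytest.fixture
def toy_cohort():
    """Three subjects: one case, one selected control, one outsider."""
    survival = [
        make_subject("a", 2.0, 1, x2=1.0),
        make_subject("b", 5.0, 0, x2=1.0),
        make_subject("c", 3.0, 0, x2=0.0),
    ]
    longitudinal = {
        "a": LongitudinalSeries("a", (0.0, 1.0), (0.2, 0.7)),
        "b": LongitudinalSeries("b", (0.0, 1.0, 2.0), (-0.1, 0.4, 0.9)),
    }
    flags = {"a": 1, "b": 1, "c": 0}
    from jmncc.datamodel import NCCSelectionRecord

    selections = [
        NCCSelectionRecord(
            case_id="a", case_time=2.0, control_ids=("b",), m_drawn=1,
            riskset_size=1, matching_values={"x2": 1.0},
        )
    ]
    return CohortData(survival, longitudinal, flags, selections)


@pytest.fixture(scope="session")
def small_ncc_pipeline():
    """A small simulated cohort run through the full NCC pipeline."""
    sim = SimConfig(N=400, n_cases_target=25, censor_hi=5.0)
    cohort, truth = simulate_full_cohort(sim, seed=42)
    matching = MatchingSpec(("x2",))
    flags, selections = sample_ncc(cohort.survival, 1, matching, seed=43)
    weights = compute_inclusion_weights(selections, flags, cohort.survival, matching)
    series = sample_longitudinal(cohort, truth, sim, seed=44)
    sub_series = {sid: series[sid] for sid, r in flags.items() if r == 1}
    full = attach_longitudinal(cohort, sub_series, flags, selections)
    template = ModelTemplate(K=2, knots=(np.inf,), surv_covariates=("x2",))
    return {
        "sim": sim,
        "cohort": cohort,
        "truth": truth,
        "full": full,
        "sub": full.restrict_to_subcohort(),
        "weights": weights,
        "selections": selections,
        "series": series,
        "template": template,
    }
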