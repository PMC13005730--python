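"""Nested case-control design: risk sets, 1:m incidence-density sampling,
and inverse-probability-of-inclusion weights.

Under incidence-density sampling, every case contributes a matched set:
at the case's event time ``T_l`` the risk set consists of all subjects
still event-free (``T_j >= T_l``, ties included) sharing the case's
matching-factor values; ``m`` controls are drawn uniformly without
replacement. A subject may serve as control for several cases and may
itself later become a case.

A control's probability of ever entering the sub-cohort is
``1 - prod_{l in S_i} (1 - m_l / n_l)`` over the cases ``l`` whose risk
set contained it; its weight ``w_i`` is the inverse of that probability,
and cases carry ``w_i = 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import (
    NCCSelectionRecord,
    SubjectSurvival,
    ValidationError,
    WeightTable,
)

__all__ = ["MatchingSpec", "build_risk_set", "sample_ncc", "compute_inclusion_weights"]


@dataclass(frozen=True)
class MatchingSpec:
    """Exact-matching factors (covariate names) for control selection."""

    factor_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "factor_names", tuple(self.factor_names))

    def validate(self, survival: list[SubjectSurvival]) -> None:
        if not survival:
            return
        names = set(survival[0].covariates)
        for f in self.factor_names:
            if f not in names:
                raise ValidationError(f"matching factor {f!r} not among survival covariates")


def build_risk_set(
    survival: list[SubjectSurvival],
    case: SubjectSurvival,
    matching: MatchingSpec = MatchingSpec(),
) -> list[str]:
    """Ids of subjects at risk at the case's event time, matched exactly.

    Eligibility uses the closed boundary ``T_j >= T_case``: a subject
    censored exactly at the case's time was still event-free then and is
    included. The case itself is excluded. Returns an empty list when no
    candidate qualifies.
    """
    if case.status == 0:
        raise ValueError(f"subject {case.id} is not a case (status 0)")
    out = []
    for s in survival:
        if s.id == case.id or s.time < case.time:
            continue
        # tied subjects (event or censoring at exactly T_case) were still
        # event-free an instant before T_case and remain eligible
        if all(s.covariates[f] == case.covariates[f] for f in matching.factor_names):
            out.append(s.id)
    return out


def _riskset_mask(
    times: np.ndarray,
    match_matrix: np.ndarray,
    case_idx: int,
) -> np.ndarray:
    """Vectorized build_risk_set over a whole survival array."""
    mask = times >= times[case_idx]
    if match_matrix.size:
        mask &= np.all(match_matrix == match_matrix[case_idx], axis=1)
    mask[case_idx] = False
    return mask


def _cohort_arrays(survival: list[SubjectSurvival], matching: MatchingSpec):
    times = np.array([s.time for s in survival])
    if matching.factor_names:
        match = np.array([[s.covariates[f] for f in matching.factor_names] for s in survival])
    else:
        match = np.empty((len(survival), 0))
    return times, match


def sample_ncc(
    survival: list[SubjectSurvival],
    m: int,
    matching: MatchingSpec = MatchingSpec(),
    seed: int | np.random.SeedSequence | None = None,
    case_ids: list[str] | None = None,
) -> tuple[dict[str, int], list[NCCSelectionRecord]]:
    """Draw a 1:m incidence-density NCC sample from the full cohort.

    Every subject in ``case_ids`` (default: all subjects with status != 0,
    in order of event time with stable id tie-breaking) becomes a case
    with ``R_i = 1``; ``min(m, riskset size)`` controls are drawn uniformly
    without replacement per case. Sampling is driven by per-case child
    streams of one top-level seed, so selections are reproducible and
    insensitive to partial re-runs.

    Returns ``(subcohort_flags, selections)``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    matching.validate(survival)
    if seed is None:
        raise ValueError("a seed is required for reproducible NCC sampling")
    times, match = _cohort_arrays(survival, matching)
    ids = np.array([s.id for s in survival], dtype=object)
    idx_of = {s.id: i for i, s in enumerate(survival)}

    if case_ids is None:
        cases = [s for s in survival if s.status != 0]
        cases.sort(key=lambda s: (s.time, s.id))
        case_ids = [s.id for s in cases]

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(case_ids))

    flags = {s.id: 0 for s in survival}
    selections: list[NCCSelectionRecord] = []
    for child, cid in zip(children, case_ids):
        ci = idx_of[cid]
        case = survival[ci]
        if case.status == 0:
            raise ValueError(f"designated case {cid} has status 0")
        flags[cid] = 1
        mask = _riskset_mask(times, match, ci)
        candidates = ids[mask]
        n_l = int(candidates.size)
        if n_l == 0:
            warnings.warn(f"case {cid}: empty risk set, no controls drawn")
            selections.append(
                NCCSelectionRecord(
                    case_id=cid,
                    case_time=case.time,
                    control_ids=(),
                    m_drawn=0,
                    riskset_size=1,  # record floor; no eligible candidate
                    matching_values={f: case.covariates[f] for f in matching.factor_names},
                )
            )
            continue
        m_drawn = min(m, n_l)
        if m_drawn < m:
            warnings.warn(f"case {cid}: risk set has only {n_l} candidates; drawing {m_drawn}")
        rng = np.random.default_rng(child)
        chosen = rng.choice(candidates, size=m_drawn, replace=False)
        for sid in chosen:
            flags[sid] = 1
        selections.append(
            NCCSelectionRecord(
                case_id=cid,
                case_time=case.time,
                control_ids=tuple(sorted(chosen)),
                m_drawn=m_drawn,
                riskset_size=n_l,
                matching_values={f: case.covariates[f] for f in matching.factor_names},
            )
        )
    return flags, selections


def compute_inclusion_weights(
    selections: list[NCCSelectionRecord],
    subcohort_flags: dict[str, int],
    survival: list[SubjectSurvival],
    matching: MatchingSpec = MatchingSpec(),
) -> WeightTable:
    """Inverse-probability-of-inclusion weights for all R_i=1 subjects.

    Eligibility sets ``S_i`` are recomputed from the survival table by
    re-running the risk-set membership test for every case, so the weights
    are exact for the design actually sampled. Cases get weight 1.
    """
    matching.validate(survival)
    times, match = _cohort_arrays(survival, matching)
    idx_of = {s.id: i for i, s in enumerate(survival)}
    case_ids = {rec.case_id for rec in selections}

    log_surv_prob = {sid: 0.0 for sid, r in subcohort_flags.items() if r == 1}
    for rec in selections:
        if rec.m_drawn > rec.riskset_size:
            raise ValidationError(f"case {rec.case_id}: m_l > n_l")
        if rec.m_drawn == 0:
            continue
        frac = rec.m_drawn / rec.riskset_size
        ci = idx_of[rec.case_id]
        mask = _riskset_mask(times, match, ci)
        for sid in log_surv_prob:
            if sid in case_ids:
                continue
            if mask[idx_of[sid]]:
                if frac >= 1.0:
                    log_surv_prob[sid] = -np.inf
                else:
                    log_surv_prob[sid] += np.log1p(-frac)

    weights = WeightTable()
    for sid, r in subcohort_flags.items():
        if r != 1:
            continue
        if sid in case_ids:
            weights[sid] = 1.0
        else:
            p_incl = -np.expm1(log_surv_prob[sid])
            if p_incl <= 0:
                raise ValidationError(
                    f"subject {sid} selected as control but has inclusion probability 0"
                )
            weights[sid] = 1.0 / p_incl
    return weights
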