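"""Core data containers and delimited-table I/O.

A nested case-control (NCC) study carries three tables:

* ``survival.csv`` — one row per cohort subject: observed time ``T_i``
  (minimum of the event and censoring times), status ``delta_i`` in
  ``{0, 1, ..., K}`` (0 = censored, k = cause-k event) and the baseline
  covariates.
* ``longitudinal.csv`` — long-format biomarker samples (``id, time, value``),
  present only for subjects selected into the NCC sub-cohort (``R_i = 1``).
* ``selections.csv`` — one row per case recording which controls were drawn
  from its risk set, how many (``m_drawn``) and out of how many eligible
  candidates (``riskset_size``), plus the case's matching-factor values.

All times live on one consistent, continuous axis; ids are opaque strings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectSurvival",
    "LongitudinalSeries",
    "NCCSelectionRecord",
    "CohortData",
    "WeightTable",
    "SchemaError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "arcsine_sqrt_transform",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A type invariant is violated by the data."""


@dataclass(frozen=True)
class SubjectSurvival:
    """Observed survival record for one cohort subject."""

    id: str
    time: float
    status: int
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.time > 0):
            raise ValidationError(f"subject {self.id}: time must be > 0, got {self.time}")
        if self.status < 0:
            raise ValidationError(f"subject {self.id}: status must be >= 0, got {self.status}")
        for name, v in self.covariates.items():
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise ValidationError(f"subject {self.id}: missing covariate value for {name!r}")


@dataclass(frozen=True)
class LongitudinalSeries:
    """Repeated biomarker measurements for one subject.

    ``times`` are strictly increasing and must not exceed the subject's
    observed survival time (enforced by :class:`CohortData`).
    """

    id: str
    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValidationError(f"subject {self.id}: times/values length mismatch")
        if len(self.times) < 1:
            raise ValidationError(f"subject {self.id}: empty longitudinal series")
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"subject {self.id}: measurement times not strictly increasing")

    def validate_family(self, family: str) -> None:
        if family == "poisson":
            v = np.asarray(self.values, dtype=float)
            if np.any(v < 0) or np.any(v != np.round(v)):
                raise ValidationError(
                    f"subject {self.id}: Poisson family requires non-negative integer values"
                )


@dataclass(frozen=True)
class NCCSelectionRecord:
    """Control selection made at one case's event time.

    ``m_drawn`` is the number of controls actually selected (may be less
    than the requested ratio m when the risk set is small) and
    ``riskset_size`` the number of eligible, matched candidates.
    """

    case_id: str
    case_time: float
    control_ids: tuple[str, ...]
    m_drawn: int
    riskset_size: int
    matching_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.m_drawn != len(self.control_ids):
            raise ValidationError(
                f"case {self.case_id}: m_drawn={self.m_drawn} != #control_ids={len(self.control_ids)}"
            )
        if self.riskset_size < 1:
            raise ValidationError(f"case {self.case_id}: riskset_size must be >= 1")
        if self.m_drawn > self.riskset_size:
            raise ValidationError(
                f"case {self.case_id}: m_drawn={self.m_drawn} exceeds riskset_size={self.riskset_size}"
            )


@dataclass
class CohortData:
    """Full-cohort survival data plus NCC sub-cohort longitudinal data.

    ``subcohort_flags`` maps every subject id to its inclusion indicator
    ``R_i``; longitudinal series exist only for ``R_i = 1`` subjects.
    Subject order follows ``survival`` and is preserved by all downstream
    computations.
    """

    survival: list[SubjectSurvival]
    longitudinal: dict[str, LongitudinalSeries]
    subcohort_flags: dict[str, int]
    selections: list[NCCSelectionRecord]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n(self) -> int:
        return len(self.survival)

    @property
    def n_subcohort(self) -> int:
        return sum(1 for v in self.subcohort_flags.values() if v == 1)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        if not self.survival:
            return ()
        return tuple(self.survival[0].covariates.keys())

    def subject(self, sid: str) -> SubjectSurvival:
        return self._index[sid]

    def validate(self) -> None:
        ids = [s.id for s in self.survival]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject ids in survival table")
        self._index = {s.id: s for s in self.survival}
        names = self.covariate_names
        for s in self.survival:
            if tuple(s.covariates.keys()) != names:
                raise ValidationError(f"subject {s.id}: covariate names inconsistent")
        for sid in self.subcohort_flags:
            if sid not in self._index:
                raise ValidationError(f"subcohort flag for unknown subject {sid}")
        for sid, series in self.longitudinal.items():
            if self.subcohort_flags.get(sid, 0) != 1:
                raise ValidationError(f"longitudinal data for subject {sid} with R_i=0")
            surv = self._index.get(sid)
            if surv is None:
                raise ValidationError(f"longitudinal data for unknown subject {sid}")
            if max(series.times) > surv.time + 1e-12:
                raise ValidationError(
                    f"subject {sid}: measurement time {max(series.times)} exceeds survival time {surv.time}"
                )
        for sid, r in self.subcohort_flags.items():
            if r not in (0, 1):
                raise ValidationError(f"subject {sid}: R_i must be 0 or 1")
        for rec in self.selections:
            case = self._index.get(rec.case_id)
            if case is None:
                raise ValidationError(f"selection record for unknown case {rec.case_id}")
            if self.subcohort_flags.get(rec.case_id, 0) != 1:
                raise ValidationError(f"case {rec.case_id} not flagged into the sub-cohort")

    def restrict_to_subcohort(self) -> "CohortData":
        """Return a copy containing only R_i=1 subjects (wJM-NCC's view)."""
        keep = {sid for sid, r in self.subcohort_flags.items() if r == 1}
        return CohortData(
            survival=[s for s in self.survival if s.id in keep],
            longitudinal=dict(self.longitudinal),
            subcohort_flags={sid: 1 for sid in keep},
            selections=list(self.selections),
        )

    def equals(self, other: "CohortData") -> bool:
        if [s.id for s in self.survival] != [s.id for s in other.survival]:
            return False
        for a, b in zip(self.survival, other.survival):
            if a.id != b.id or a.status != b.status:
                return False
            if not math.isclose(a.time, b.time, rel_tol=1e-12, abs_tol=1e-12):
                return False
            if set(a.covariates) != set(b.covariates):
                return False
            if any(
                not math.isclose(a.covariates[k], b.covariates[k], rel_tol=1e-12, abs_tol=1e-12)
                for k in a.covariates
            ):
                return False
        if self.subcohort_flags != other.subcohort_flags:
            return False
        if set(self.longitudinal) != set(other.longitudinal):
            return False
        for sid, sa in self.longitudinal.items():
            sb = other.longitudinal[sid]
            if not np.allclose(sa.times, sb.times) or not np.allclose(sa.values, sb.values):
                return False
        if len(self.selections) != len(other.selections):
            return False
        for ra, rb in zip(self.selections, other.selections):
            if (
                ra.case_id != rb.case_id
                or ra.control_ids != rb.control_ids
                or ra.m_drawn != rb.m_drawn
                or ra.riskset_size != rb.riskset_size
            ):
                return False
        return True


class WeightTable(dict):
    """Inverse-probability-of-inclusion weights ``w_i`` for R_i=1 subjects.

    Cases carry ``w_i = 1``; controls carry
    ``w_i = (1 - prod_{l in S_i} (1 - m_l / n_l))^{-1} >= 1``, the inverse
    of their probability of ever being drawn as a control.
    """

    def __setitem__(self, key: str, value: float) -> None:
        if value < 1.0 - 1e-9:
            raise ValidationError(f"weight for {key} must be >= 1, got {value}")
        super().__setitem__(key, float(value))


# ---------------------------------------------------------------------------
# I/O


_SURV_REQUIRED = ("id", "time", "status")
_LONG_REQUIRED = ("id", "time", "value")
_SEL_REQUIRED = ("case_id", "case_time", "control_ids", "m_drawn", "riskset_size")


def _require_columns(df: pd.DataFrame, required: Sequence[str], table: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{table}: missing required column {col!r}")


def read_cohort(
    survival_path: str | Path,
    longitudinal_path: str | Path | None = None,
    selections_path: str | Path | None = None,
    family: str = "normal",
) -> CohortData:
    """Read the three NCC tables into a validated :class:`CohortData`.

    ``longitudinal_path`` and ``selections_path`` are optional so that a
    survival-only cohort (before NCC sampling) can round-trip.
    """
    sdf = pd.read_csv(survival_path, dtype={"id": str})
    _require_columns(sdf, _SURV_REQUIRED, "survival")
    cov_cols = [c for c in sdf.columns if c not in _SURV_REQUIRED]
    survival = [
        SubjectSurvival(
            id=row["id"],
            time=float(row["time"]),
            status=int(row["status"]),
            covariates={c: float(row[c]) for c in cov_cols},
        )
        for row in sdf.to_dict("records")
    ]

    longitudinal: dict[str, LongitudinalSeries] = {}
    if longitudinal_path is not None and Path(longitudinal_path).exists():
        ldf = pd.read_csv(longitudinal_path, dtype={"id": str})
        _require_columns(ldf, _LONG_REQUIRED, "longitudinal")
        for sid, grp in ldf.groupby("id", sort=False):
            series = LongitudinalSeries(
                id=sid,
                times=tuple(float(t) for t in grp["time"]),
                values=tuple(float(v) for v in grp["value"]),
            )
            series.validate_family(family)
            longitudinal[sid] = series

    selections: list[NCCSelectionRecord] = []
    if selections_path is not None and Path(selections_path).exists():
        xdf = pd.read_csv(selections_path, dtype={"case_id": str, "control_ids": str})
        _require_columns(xdf, _SEL_REQUIRED, "selections")
        match_cols = [c for c in xdf.columns if c not in _SEL_REQUIRED]
        for row in xdf.to_dict("records"):
            raw = row["control_ids"]
            cids = tuple(s for s in str(raw).split(";") if s) if pd.notna(raw) and str(raw) else ()
            selections.append(
                NCCSelectionRecord(
                    case_id=row["case_id"],
                    case_time=float(row["case_time"]),
                    control_ids=cids,
                    m_drawn=int(row["m_drawn"]),
                    riskset_size=int(row["riskset_size"]),
                    matching_values={c: float(row[c]) for c in match_cols},
                )
            )

    flags = {s.id: 0 for s in survival}
    for sid in longitudinal:
        flags[sid] = 1
    for rec in selections:
        flags[rec.case_id] = 1
        for cid in rec.control_ids:
            flags[cid] = 1
    return CohortData(survival, longitudinal, flags, selections)


def write_cohort(cohort: CohortData, out_dir: str | Path) -> dict[str, Path]:
    """Write ``survival.csv``, ``longitudinal.csv``, ``selections.csv``.

    Returns the three paths. Re-reading them reproduces the cohort
    (field-level equality within float round-off).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cov_names = list(cohort.covariate_names)
    sdf = pd.DataFrame(
        [
            {"id": s.id, "time": s.time, "status": s.status, **s.covariates}
            for s in cohort.survival
        ],
        columns=["id", "time", "status"] + cov_names,
    )
    surv_path = out / "survival.csv"
    sdf.to_csv(surv_path, index=False)

    lrows = []
    for s in cohort.survival:  # keep file order aligned with survival order
        series = cohort.longitudinal.get(s.id)
        if series is None:
            continue
        for t, v in zip(series.times, series.values):
            lrows.append({"id": s.id, "time": t, "value": v})
    long_path = out / "longitudinal.csv"
    pd.DataFrame(lrows, columns=["id", "time", "value"]).to_csv(long_path, index=False)

    match_names: list[str] = []
    for rec in cohort.selections:
        for k in rec.matching_values:
            if k not in match_names:
                match_names.append(k)
    xrows = [
        {
            "case_id": rec.case_id,
            "case_time": rec.case_time,
            "control_ids": ";".join(rec.control_ids),
            "m_drawn": rec.m_drawn,
            "riskset_size": rec.riskset_size,
            **rec.matching_values,
        }
        for rec in cohort.selections
    ]
    sel_path = out / "selections.csv"
    pd.DataFrame(xrows, columns=list(_SEL_REQUIRED) + match_names).to_csv(sel_path, index=False)
    return {"survival": surv_path, "longitudinal": long_path, "selections": sel_path}


def arcsine_sqrt_transform(p):
    """Variance-stabilizing arcsin(sqrt(p)) transform for proportions.

    Monotone from [0, 1] onto [0, pi/2]; standard preprocessing for
    relative-abundance biomarkers before a Gaussian longitudinal model.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("arcsine_sqrt_transform requires proportions in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out
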