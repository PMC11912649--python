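"""Core domain types, validation, and delimited-file I/O for event-history cohorts.

A cohort couples a subjects table (one row per subject: id, administrative
censoring time, covariates) with an events table (one row per event).  Time is
measured in days from each subject's entry (time 0) and events live in
``(0, follow_up_end]``; an event exactly at the censoring instant counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BINARY = "binary"
CATEGORICAL = "categorical"
CONTINUOUS = "continuous"
_KINDS = (BINARY, CATEGORICAL, CONTINUOUS)


class ValidationError(ValueError):
    """A cohort file or record violates a documented invariant."""


@dataclass(frozen=True)
class CovariateSpec:
    """Declared type of one covariate column.

    For categorical covariates ``levels`` is the ordered tuple of admissible
    values; the first level is the modelling reference.
    """

    kind: str
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown covariate kind {self.kind!r}")
        if self.kind == CATEGORICAL and len(self.levels) < 2:
            raise ValidationError("categorical covariate needs >= 2 levels")
        if self.kind != CATEGORICAL and self.levels:
            raise ValidationError(f"levels only allowed for categorical, got {self.kind}")


class CovariateSchema(Mapping[str, CovariateSpec]):
    """Ordered name -> :class:`CovariateSpec` mapping with value coercion."""

    def __init__(self, specs: Mapping[str, CovariateSpec]):
        self._specs = dict(specs)

    def __getitem__(self, name: str) -> CovariateSpec:
        return self._specs[name]

    def __iter__(self):
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def __eq__(self, other) -> bool:
        return isinstance(other, CovariateSchema) and self._specs == other._specs

    def __repr__(self) -> str:
        return f"CovariateSchema({self._specs!r})"

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._specs)

    def coerce(self, name: str, value, *, where: str = "") -> object:
        """Coerce a raw (string or numeric) value to the declared type."""
        spec = self[name]
        loc = f" ({where})" if where else ""
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        if spec.kind == CONTINUOUS:
            try:
                return float(value)
            except (TypeError, ValueError):
                raise ValidationError(f"non-numeric value {value!r} for continuous covariate {name}{loc}")
        if spec.kind == BINARY:
            try:
                iv = int(float(value))
            except (TypeError, ValueError):
                raise ValidationError(f"non-binary value {value!r} for covariate {name}{loc}")
            if iv not in (0, 1):
                raise ValidationError(f"binary covariate {name} must be 0/1, got {value!r}{loc}")
            return iv
        sval = str(value)
        if sval not in spec.levels:
            raise ValidationError(f"level {sval!r} not in schema levels {spec.levels} for {name}{loc}")
        return sval


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's covariates, follow-up window, and observed event times."""

    subject_id: str
    covariates: Mapping[str, object]
    follow_up_end: float
    event_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "event_times", tuple(float(t) for t in self.event_times))
        object.__setattr__(self, "follow_up_end", float(self.follow_up_end))
        object.__setattr__(self, "covariates", dict(self.covariates))
        if not self.subject_id:
            raise ValidationError("subject_id must be non-empty")
        if not (self.follow_up_end > 0):
            raise ValidationError(f"subject {self.subject_id}: follow_up_end must be > 0")
        prev = 0.0
        for t in self.event_times:
            if t <= 0:
                raise ValidationError(f"subject {self.subject_id}: event time {t} <= 0")
            if t <= prev and prev > 0:
                raise ValidationError(
                    f"subject {self.subject_id}: event times not strictly increasing at {t}"
                )
            if t > self.follow_up_end:
                raise ValidationError(
                    f"subject {self.subject_id}: event time {t} after follow-up end "
                    f"{self.follow_up_end}"
                )
            prev = t

    @property
    def n_events(self) -> int:
        return len(self.event_times)

    def count_by(self, horizon: float) -> int:
        """Events in ``(0, min(follow_up_end, horizon)]`` (t == horizon included)."""
        limit = min(self.follow_up_end, horizon)
        return int(sum(1 for t in self.event_times if t <= limit))


@dataclass(frozen=True)
class Cohort:
    """A validated collection of subjects sharing one covariate schema."""

    subjects: tuple[SubjectRecord, ...]
    schema: CovariateSchema

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        seen: set[str] = set()
        names = set(self.schema.names)
        for rec in self.subjects:
            if rec.subject_id in seen:
                raise ValidationError(f"duplicate subject_id {rec.subject_id!r}")
            seen.add(rec.subject_id)
            if set(rec.covariates) != names:
                raise ValidationError(
                    f"subject {rec.subject_id}: covariates {sorted(rec.covariates)} "
                    f"do not match schema {sorted(names)}"
                )
            for name in names:
                self.schema.coerce(name, rec.covariates[name], where=f"subject {rec.subject_id}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(r.subject_id for r in self.subjects)

    def counts(self, horizon: float | None = None) -> np.ndarray:
        if horizon is None:
            return np.array([r.n_events for r in self.subjects], dtype=int)
        return np.array([r.count_by(horizon) for r in self.subjects], dtype=int)

    def follow_up(self) -> np.ndarray:
        return np.array([r.follow_up_end for r in self.subjects], dtype=float)

    def covariate_frame(self) -> pd.DataFrame:
        """Covariate values as a DataFrame indexed like ``subjects``."""
        data = {name: [r.covariates[name] for r in self.subjects] for name in self.schema.names}
        return pd.DataFrame(data, index=list(self.subject_ids))

    def subset(self, keep: Sequence[bool] | Sequence[int]) -> "Cohort":
        arr = np.asarray(keep)
        if arr.dtype == bool:
            subs = tuple(r for r, k in zip(self.subjects, arr) if k)
        else:
            subs = tuple(self.subjects[i] for i in arr)
        return Cohort(subs, self.schema)

    def with_subjects(self, subjects: Iterable[SubjectRecord]) -> "Cohort":
        return Cohort(tuple(subjects), self.schema)


@dataclass(frozen=True)
class IntervalCountRecord:
    """Events reported as a count over a visit interval ``(start, end]``.

    ``exact_times`` carries recorded event dates when the reporting rule keeps
    them (counts of one or two between visits); ``None`` means only the count
    is known.
    """

    subject_id: str
    interval_start: float
    interval_end: float
    count: int
    exact_times: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.interval_start >= self.interval_end:
            raise ValidationError(
                f"subject {self.subject_id}: interval start {self.interval_start} "
                f">= end {self.interval_end}"
            )
        if self.count < 0:
            raise ValidationError(f"subject {self.subject_id}: negative count {self.count}")
        if self.exact_times is not None:
            if len(self.exact_times) != self.count:
                raise ValidationError(
                    f"subject {self.subject_id}: {len(self.exact_times)} exact times "
                    f"for count {self.count}"
                )
            for t in self.exact_times:
                if not (self.interval_start < t <= self.interval_end):
                    raise ValidationError(
                        f"subject {self.subject_id}: exact time {t} outside interval"
                    )


def validate_intervals(records: Sequence[IntervalCountRecord]) -> None:
    """Check intervals for one subject are ordered and non-overlapping."""
    for prev, cur in zip(records, records[1:]):
        if cur.subject_id != prev.subject_id:
            raise ValidationError("interval records mix subjects")
        if cur.interval_start < prev.interval_end:
            raise ValidationError(
                f"subject {cur.subject_id}: overlapping/unordered intervals at "
                f"{cur.interval_start}"
            )


# ---------------------------------------------------------------------------
# Delimited file I/O (CSV, RFC-4180 quoting, header row required)
# ---------------------------------------------------------------------------


def read_cohort(subjects_path, events_path, schema: CovariateSchema) -> Cohort:
    """Read and validate a cohort from subjects and events CSV files.

    Subjects rows with missing covariate values are dropped (count logged, no
    imputation).  Events referencing unknown subjects, events after follow-up
    end, and duplicate subject ids all raise :class:`ValidationError`.
    """
    try:
        subs = pd.read_csv(subjects_path, dtype={"subject_id": str}, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"cannot read subjects file {subjects_path}: {exc}") from exc
    required = {"subject_id", "follow_up_end", *schema.names}
    missing = required - set(subs.columns)
    if missing:
        raise ValidationError(f"subjects file missing columns: {sorted(missing)}")

    try:
        evs = pd.read_csv(events_path, dtype={"subject_id": str}, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover
        raise ValidationError(f"cannot read events file {events_path}: {exc}") from exc
    if len(evs.columns) == 0 or not {"subject_id", "event_time"} <= set(evs.columns):
        # an entirely empty file (no header) counts as zero events
        if evs.shape[0] == 0 and evs.shape[1] == 0:
            evs = pd.DataFrame(columns=["subject_id", "event_time"])
        else:
            raise ValidationError("events file missing columns: subject_id/event_time")

    events_by_id: dict[str, list[float]] = {}
    for row_no, row in enumerate(evs.itertuples(index=False), start=2):
        try:
            t = float(row.event_time)
        except (TypeError, ValueError):
            raise ValidationError(f"events row {row_no}: non-numeric event_time {row.event_time!r}")
        events_by_id.setdefault(str(row.subject_id), []).append(t)

    records: list[SubjectRecord] = []
    n_dropped = 0
    seen_ids: set[str] = set()
    for row_no, row in enumerate(subs.to_dict("records"), start=2):
        sid = str(row["subject_id"])
        if sid in seen_ids:
            raise ValidationError(f"subjects row {row_no}: duplicate subject_id {sid!r}")
        seen_ids.add(sid)
        try:
            end = float(row["follow_up_end"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"subjects row {row_no}: non-numeric follow_up_end {row['follow_up_end']!r}"
            )
        covs = {}
        dropped = False
        for name in schema.names:
            val = schema.coerce(name, row[name], where=f"subjects row {row_no}")
            if val is None:
                dropped = True
                break
            covs[name] = val
        if dropped:
            n_dropped += 1
            events_by_id.pop(sid, None)
            continue
        times = sorted(events_by_id.pop(sid, []))
        try:
            records.append(SubjectRecord(sid, covs, end, tuple(times)))
        except ValidationError as exc:
            raise ValidationError(f"subjects row {row_no}: {exc}") from exc

    if events_by_id:
        orphan = sorted(events_by_id)[0]
        raise ValidationError(f"events file references unknown subject_id {orphan!r}")
    if n_dropped:
        logger.info("read_cohort: dropped %d subject(s) with missing covariate values", n_dropped)
    return Cohort(tuple(records), schema)


def write_cohort(cohort: Cohort, subjects_path, events_path) -> None:
    """Write a cohort to subjects/events CSV files (inverse of :func:`read_cohort`)."""
    sub_rows = []
    for rec in cohort.subjects:
        row = {"subject_id": rec.subject_id, "follow_up_end": rec.follow_up_end}
        row.update({n: rec.covariates[n] for n in cohort.schema.names})
        sub_rows.append(row)
    cols = ["subject_id", "follow_up_end", *cohort.schema.names]
    pd.DataFrame(sub_rows, columns=cols).to_csv(subjects_path, index=False)

    ev_rows = [
        {"subject_id": rec.subject_id, "event_time": t}
        for rec in cohort.subjects
        for t in rec.event_times
    ]
    pd.DataFrame(ev_rows, columns=["subject_id", "event_time"]).to_csv(events_path, index=False)


def read_interval_counts(path) -> list[IntervalCountRecord]:
    """Read interval-reported counts (subject_id,interval_start,interval_end,count)."""
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    need = {"subject_id", "interval_start", "interval_end", "count"}
    if not need <= set(df.columns):
        raise ValidationError(f"interval-counts file missing columns: {sorted(need - set(df.columns))}")
    recs = [
        IntervalCountRecord(
            str(r.subject_id), float(r.interval_start), float(r.interval_end), int(r.count)
        )
        for r in df.itertuples(index=False)
    ]
    by_subject: dict[str, list[IntervalCountRecord]] = {}
    for rec in recs:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    for group in by_subject.values():
        validate_intervals(group)
    return recs


def write_interval_counts(records: Sequence[IntervalCountRecord], path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "interval_start": r.interval_start,
            "interval_end": r.interval_end,
            "count": r.count,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["subject_id", "interval_start", "interval_end", "count"]).to_csv(
        path, index=False
    )
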