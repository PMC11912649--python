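"""Data-preparation operators for recurrent-event cohorts.

Covers the standard preparation steps upstream of model fitting: merging
events closer than a resolution window, capping extreme per-subject counts at
an empirical quantile, imputing event times from interval-reported counts
under a constant-rate assumption, log-transforming continuous covariates, and
expanding a cohort into the counting-process (start, stop] layout used by the
Cox-type fits.

Convention, used everywhere: an event at time t contributes to the count over
``(0, tau]`` iff ``t <= tau``; an interval stop exactly at tau carries the
event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CONTINUOUS,
    Cohort,
    CovariateSchema,
    CovariateSpec,
    IntervalCountRecord,
    SubjectRecord,
    ValidationError,
    validate_intervals,
)

AG = "ag"
PWP_TT = "pwp-tt"
_REPRESENTATIONS = (AG, PWP_TT)


@dataclass(frozen=True)
class CountingProcessTable:
    """Counting-process rows ``(subject_id, start, stop], event, stratum, covariates``.

    For the AG representation every row has stratum 1; for PWP-TT the stratum
    of a row is 1 + the number of the subject's prior events.
    """

    data: pd.DataFrame
    representation: str
    horizon: float
    covariate_names: tuple[str, ...]
    schema: CovariateSchema
    pooled_after: int | None = None  # strata above this were pooled into it

    def __post_init__(self) -> None:
        if self.representation not in _REPRESENTATIONS:
            raise ValidationError(f"unknown representation {self.representation!r}")
        need = {"subject_id", "start", "stop", "event", "stratum", *self.covariate_names}
        missing = need - set(self.data.columns)
        if missing:
            raise ValidationError(f"counting-process table missing columns {sorted(missing)}")

    def validate(self) -> None:
        df = self.data
        if (df["start"] >= df["stop"]).any():
            raise ValidationError("counting-process row with start >= stop")
        if (df["start"] < 0).any():
            raise ValidationError("counting-process row with start < 0")
        for sid, grp in df.groupby("subject_id", sort=False):
            starts = grp["start"].to_numpy()
            stops = grp["stop"].to_numpy()
            if starts[0] != 0:
                raise ValidationError(f"subject {sid}: first start != 0")
            if not np.allclose(starts[1:], stops[:-1]):
                raise ValidationError(f"subject {sid}: rows not contiguous")
            if self.representation == AG:
                if (grp["stratum"] != 1).any():
                    raise ValidationError(f"subject {sid}: AG stratum must be 1")
            else:
                expected = 1 + np.concatenate([[0], np.cumsum(grp["event"].to_numpy()[:-1])])
                if self.pooled_after is not None:
                    expected = np.minimum(expected, self.pooled_after)
                if not np.array_equal(grp["stratum"].to_numpy(), expected):
                    raise ValidationError(f"subject {sid}: PWP-TT strata inconsistent with event order")

    def to_csv(self, path) -> None:
        cols = ["subject_id", "start", "stop", "event", "stratum", *self.covariate_names]
        self.data[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, representation: str, horizon: float, schema: CovariateSchema):
        df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
        covs = tuple(c for c in df.columns if c not in ("subject_id", "start", "stop", "event", "stratum"))
        return cls(df, representation, horizon, covs, schema)


def merge_events(record: SubjectRecord, window: float) -> SubjectRecord:
    """Drop events within ``window`` days of the last retained event.

    Greedy left-to-right scan anchored on retained events: an event is treated
    as a continuation (and dropped) if it occurs <= window days after the most
    recently retained one.  Idempotent; window 0 is the identity.
    """
    if window < 0:
        raise ValidationError(f"merge window must be >= 0, got {window}")
    if not record.event_times or window == 0:
        return record
    kept: list[float] = []
    for t in record.event_times:
        if not kept or t - kept[-1] > window:
            kept.append(t)
    return replace(record, event_times=tuple(kept))


def empirical_quantile(values: Sequence[float], quantile: float) -> float:
    """Inverse-CDF empirical quantile: smallest value with CDF >= quantile."""
    if not (0 < quantile <= 1):
        raise ValidationError(f"quantile must be in (0, 1], got {quantile}")
    arr = np.sort(np.asarray(values))
    if arr.size == 0:
        raise ValidationError("empirical quantile of empty sequence")
    idx = math.ceil(quantile * arr.size) - 1
    return arr[max(idx, 0)]


def cap_counts(cohort: Cohort, quantile: float) -> tuple[Cohort, int]:
    """Cap per-subject event counts at their empirical ``quantile``.

    The cap is the inverse-CDF quantile of the per-subject counts; subjects
    above it keep only their first ``cap`` events (earliest retained, so the
    time-to-early-event structure survives).  Returns the capped cohort and
    the cap value.
    """
    if len(cohort) == 0:
        raise ValidationError("cap_counts requires a non-empty cohort")
    counts = cohort.counts()
    cap = int(empirical_quantile(counts, quantile))
    new_subjects = [
        replace(rec, event_times=rec.event_times[:cap]) if rec.n_events > cap else rec
        for rec in cohort.subjects
    ]
    return cohort.with_subjects(new_subjects), cap


def impute_event_times(
    records: Sequence[IntervalCountRecord],
    mode: str = "equal_spacing",
    rng: np.random.Generator | None = None,
) -> tuple[float, ...]:
    """Impute event times for one subject's interval-reported counts.

    Under the constant-rate assumption an interval ``(a, b]`` with count k > 0
    yields the equally spaced times ``a + j (b - a) / (k + 1)``, j = 1..k,
    strictly inside the interval; a count of 0 yields nothing.  Records that
    carry ``exact_times`` (the reporting rule keeps exact dates for one or two
    events between visits) pass those through unchanged.  ``mode='uniform'``
    instead draws k order statistics of U(a, b) from ``rng`` (seeded caller
    responsibility).
    """
    if mode not in ("equal_spacing", "uniform"):
        raise ValidationError(f"unknown imputation mode {mode!r}")
    if mode == "uniform" and rng is None:
        raise ValidationError("uniform imputation requires a seeded rng")
    ordered = sorted(records, key=lambda r: r.interval_start)
    validate_intervals(ordered)
    times: list[float] = []
    for rec in ordered:
        if rec.count == 0:
            continue
        if rec.exact_times is not None:
            times.extend(rec.exact_times)
            continue
        a, b, k = rec.interval_start, rec.interval_end, rec.count
        if mode == "equal_spacing":
            times.extend(a + j * (b - a) / (k + 1) for j in range(1, k + 1))
        else:
            draws = np.sort(rng.uniform(a, b, size=k))  # type: ignore[union-attr]
            times.extend(float(t) for t in draws)
    return tuple(times)


def transform_covariate(
    cohort: Cohort,
    name: str,
    transform: str = "log",
    shift: float | str | None = None,
) -> Cohort:
    """Add a transformed copy of a continuous covariate (suffix ``_log``/``_lin``).

    ``transform='log'`` requires strictly positive values unless a shift is
    given: ``shift='auto'`` picks c so that min(x) + c == 1 when non-positive
    values are present (so a zero maps to log 1 = 0).  The original column is
    retained.
    """
    if transform not in ("log", "linear"):
        raise ValidationError(f"unknown transform {transform!r}")
    if name not in cohort.schema:
        raise ValidationError(f"unknown covariate {name!r}")
    if cohort.schema[name].kind != CONTINUOUS:
        raise ValidationError(f"covariate {name!r} is not continuous")
    values = np.array([float(r.covariates[name]) for r in cohort.subjects])
    suffix = "_log" if transform == "log" else "_lin"
    new_name = name + suffix
    if transform == "linear":
        new_vals = values
    else:
        c = 0.0
        if shift == "auto":
            c = 1.0 - values.min() if values.size and values.min() <= 0 else 0.0
        elif shift is not None:
            c = float(shift)
        if values.size and (values + c <= 0).any():
            raise ValidationError(
                f"log transform of non-positive values in {name!r}; pass shift='auto' or a constant"
            )
        new_vals = np.log(values + c)
    specs = dict(cohort.schema)
    specs[new_name] = CovariateSpec(CONTINUOUS)
    new_schema = CovariateSchema(specs)
    new_subjects = [
        replace(rec, covariates={**rec.covariates, new_name: float(v)})
        for rec, v in zip(cohort.subjects, new_vals)
    ]
    return Cohort(tuple(new_subjects), new_schema)


def to_counting_process(
    cohort: Cohort,
    representation: str,
    horizon: float,
    covariates: Sequence[str] | None = None,
) -> CountingProcessTable:
    """Expand a cohort into counting-process rows up to ``min(end, horizon)``.

    Each subject contributes intervals ``(0, t1], (t1, t2], ..., (tk, limit]``
    where limit = min(follow_up_end, horizon); events with t > horizon are
    dropped.  AG rows all carry stratum 1; PWP-TT strata equal the event
    order (1 + prior events).
    """
    if representation not in _REPRESENTATIONS:
        raise ValidationError(f"unknown representation {representation!r}")
    if not (horizon > 0):
        raise ValidationError(f"horizon must be > 0, got {horizon}")
    names = tuple(covariates) if covariates is not None else cohort.schema.names
    rows: list[dict] = []
    for rec in cohort.subjects:
        limit = min(rec.follow_up_end, horizon)
        times = [t for t in rec.event_times if t <= limit]
        covs = {n: rec.covariates[n] for n in names}
        start = 0.0
        for k, t in enumerate(times):
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "start": start,
                    "stop": t,
                    "event": 1,
                    "stratum": 1 if representation == AG else k + 1,
                    **covs,
                }
            )
            start = t
        if start < limit:
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "start": start,
                    "stop": limit,
                    "event": 0,
                    "stratum": 1 if representation == AG else len(times) + 1,
                    **covs,
                }
            )
    cols = ["subject_id", "start", "stop", "event", "stratum", *names]
    df = pd.DataFrame(rows, columns=cols)
    table = CountingProcessTable(df, representation, float(horizon), names, cohort.schema)
    table.validate()
    return table
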