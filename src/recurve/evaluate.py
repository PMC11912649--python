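"""Numerical and graphical performance measures for count predictions.

Numerical: RMSPE ``sqrt(mean((y - yhat)^2))``, MAPE ``mean(|y - yhat|)``
(absolute, not percentage, error), and prediction bias ``mean(yhat - y)``
with positive values meaning over-prediction.  Smaller absolute values mean a
better model.

Graphical: count-calibration curves (observed counts on x, predicted on y,
local-linear smoother with a subject-bootstrap band) and Bland–Altman
agreement data (difference vs mean, limits of agreement at 1.96 sample
standard deviations either side of the mean difference).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .count_models import CountModelFit, deviance_residuals, predict_counts
from .data_model import Cohort, ValidationError
from .preprocess import AG, PWP_TT
from .survival_models import SurvivalModelFit, predict_counts_ag, predict_counts_pwp

BA_MULTIPLIER = 1.96  # limits of agreement at 1.96 SD either side of the mean


@dataclass(frozen=True)
class PredictionSet:
    """Per-subject observed and predicted counts at one horizon for one model."""

    frame: pd.DataFrame  # subject_id, observed, predicted, <covariates>
    horizon: float
    model: str

    def __post_init__(self) -> None:
        need = {"subject_id", "observed", "predicted"}
        if not need <= set(self.frame.columns):
            raise ValidationError(f"prediction frame missing {sorted(need - set(self.frame.columns))}")
        obs = self.frame["observed"].to_numpy()
        if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
            raise ValidationError("observed counts must be non-negative integers")
        if (self.frame["predicted"].to_numpy() < 0).any():
            raise ValidationError("predicted counts must be >= 0")

    @property
    def observed(self) -> np.ndarray:
        return self.frame["observed"].to_numpy(dtype=float)

    @property
    def predicted(self) -> np.ndarray:
        return self.frame["predicted"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


def rmspe(preds: PredictionSet) -> float:
    """Root mean squared prediction error."""
    if len(preds) == 0:
        raise ValidationError("rmspe of empty prediction set")
    return float(np.sqrt(np.mean((preds.observed - preds.predicted) ** 2)))


def mape(preds: PredictionSet) -> float:
    """Mean absolute prediction error (absolute difference, not percentage)."""
    if len(preds) == 0:
        raise ValidationError("mape of empty prediction set")
    return float(np.mean(np.abs(preds.observed - preds.predicted)))


def prediction_bias(preds: PredictionSet) -> float:
    """Mean signed error ``mean(predicted - observed)``; positive = over-prediction."""
    if len(preds) == 0:
        raise ValidationError("prediction_bias of empty prediction set")
    return float(np.mean(preds.predicted - preds.observed))


def subgroup_bias(preds: PredictionSet, by: Sequence[str]) -> pd.DataFrame:
    """Prediction bias within each non-empty combination of grouping covariates.

    Grouping covariates must be categorical or binary; the n-weighted average
    of the rows equals the overall bias exactly.
    """
    for name in by:
        if name not in preds.frame.columns:
            raise ValidationError(f"grouping covariate {name!r} not in prediction set")
        col = preds.frame[name]
        if col.dtype.kind == "f" and col.nunique() > 20:
            raise ValidationError(
                f"grouping covariate {name!r} looks continuous; bin it before grouping"
            )
    df = preds.frame.assign(_err=preds.predicted - preds.observed)
    rows = []
    for combo, grp in df.groupby(list(by), sort=True, observed=True):
        if not isinstance(combo, tuple):
            combo = (combo,)
        rows.append({**dict(zip(by, combo)), "bias": float(grp["_err"].mean()), "n": len(grp)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BlandAltmanData:
    """Difference-vs-mean agreement data with 1.96-SD limits of agreement."""

    mean: np.ndarray        # (y + yhat) / 2 per subject
    difference: np.ndarray  # yhat - y per subject
    mean_difference: float
    sd_difference: float    # sample SD (n - 1 denominator)
    lower_limit: float
    upper_limit: float
    suppressed: bool = False
    advisory: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "difference": self.difference})


def bland_altman(preds: PredictionSet, distinct_threshold: int = 5) -> BlandAltmanData:
    """Bland–Altman agreement construction for a prediction set.

    When the observed counts take fewer than ``distinct_threshold`` distinct
    values the data are still returned but flagged suppressed with an
    advisory, since the plot is uninformative for a narrow observed range.
    """
    if len(preds) < 2:
        raise ValidationError("bland_altman requires at least 2 subjects")
    y, yhat = preds.observed, preds.predicted
    diff = yhat - y
    m = (y + yhat) / 2.0
    dbar = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    n_distinct = len(np.unique(y))
    suppressed = n_distinct < distinct_threshold
    advisory = (
        f"observed counts take only {n_distinct} distinct values (< {distinct_threshold}); "
        "Bland-Altman limits carry limited information"
        if suppressed
        else None
    )
    return BlandAltmanData(
        mean=m,
        difference=diff,
        mean_difference=dbar,
        sd_difference=sd,
        lower_limit=dbar - BA_MULTIPLIER * sd,
        upper_limit=dbar + BA_MULTIPLIER * sd,
        suppressed=suppressed,
        advisory=advisory,
    )


@dataclass(frozen=True)
class CalibrationCurve:
    """Raw (observed, predicted) points plus a smoothed curve with a 95% band."""

    points: pd.DataFrame     # observed, predicted
    grid: np.ndarray
    fitted: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"observed": self.grid, "predicted": self.fitted, "lower": self.lower, "upper": self.upper}
        )


def _local_linear(x: np.ndarray, y: np.ndarray, grid: np.ndarray, span: float) -> np.ndarray:
    """Loess-style local-linear smoother with tricube weights on the nearest
    ``ceil(span * n)`` points."""
    n = len(x)
    k = max(int(math.ceil(span * n)), 3)
    out = np.empty(len(grid))
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        h = np.partition(d, min(k, n) - 1)[min(k, n) - 1]
        h = max(h, 1e-12)
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        sw = w.sum()
        xw = np.sum(w * x) / sw
        yw = np.sum(w * y) / sw
        sxx = np.sum(w * (x - xw) ** 2)
        if sxx < 1e-12:
            out[i] = yw
        else:
            slope = np.sum(w * (x - xw) * (y - yw)) / sxx
            out[i] = yw + slope * (g - xw)
    return out


def calibration_curve(
    preds: PredictionSet,
    span: float = 0.75,
    n_boot: int = 200,
    seed: int | None = None,
    grid_size: int = 40,
) -> CalibrationCurve:
    """Smoothed predicted-vs-observed calibration curve with bootstrap band.

    Local-linear smoother of predicted on observed over an even grid spanning
    the observed range; the 95% pointwise band comes from a seeded
    subject-level bootstrap.  With few distinct observed values the smoother
    falls back to group means by observed count.
    """
    if len(preds) < 10:
        raise ValidationError("calibration_curve requires n >= 10")
    y, yhat = preds.observed, preds.predicted
    rng = np.random.default_rng(seed)
    uniq = np.unique(y)
    if len(uniq) < 5:
        grid = uniq.astype(float)
        fitted = np.array([yhat[y == u].mean() for u in uniq])
        boots = np.empty((n_boot, len(grid)))
        for b in range(n_boot):
            idx = rng.integers(0, len(y), len(y))
            yb, pb = y[idx], yhat[idx]
            boots[b] = [pb[yb == u].mean() if (yb == u).any() else np.nan for u in uniq]
        lower = np.nanpercentile(boots, 2.5, axis=0)
        upper = np.nanpercentile(boots, 97.5, axis=0)
        method = "group_means"
    else:
        grid = np.linspace(y.min(), y.max(), grid_size)
        fitted = _local_linear(y, yhat, grid, span)
        boots = np.empty((n_boot, len(grid)))
        for b in range(n_boot):
            idx = rng.integers(0, len(y), len(y))
            boots[b] = _local_linear(y[idx], yhat[idx], grid, span)
        lower = np.percentile(boots, 2.5, axis=0)
        upper = np.percentile(boots, 97.5, axis=0)
        method = "local_linear"
    points = pd.DataFrame({"observed": y, "predicted": yhat})
    return CalibrationCurve(points, grid, fitted, lower, upper, method)


# ---------------------------------------------------------------------------
# assembling prediction sets and the model-comparison report
# ---------------------------------------------------------------------------


def build_prediction_set(
    fit,
    cohort: Cohort,
    horizon: float,
    pwp_method: str = "montecarlo",
    n_draws: int = 500,
    seed: int | None = None,
    label: str | None = None,
) -> PredictionSet:
    """Observed and predicted counts at ``horizon`` for every cohort subject."""
    frame = cohort.covariate_frame().reset_index(names="subject_id")
    y = cohort.counts(horizon)
    exposure = np.minimum(cohort.follow_up(), horizon)
    if isinstance(fit, CountModelFit):
        yhat = predict_counts(fit, frame, exposure)
        default = fit.model.lower()
    elif isinstance(fit, SurvivalModelFit) and fit.variant == AG:
        yhat = predict_counts_ag(fit, frame, horizon)
        default = "ag"
    elif isinstance(fit, SurvivalModelFit) and fit.variant == PWP_TT:
        yhat = predict_counts_pwp(fit, frame, horizon, method=pwp_method, n_draws=n_draws, seed=seed)
        default = "pwp"
    else:
        raise ValidationError(f"cannot build predictions from {type(fit).__name__}")
    out = frame.copy()
    out.insert(1, "observed", y)
    out.insert(2, "predicted", np.maximum(yhat, 0.0))
    return PredictionSet(out, float(horizon), label or default)


@dataclass(frozen=True)
class EvaluationReport:
    """Table-5-shaped model comparison plus optional subgroup bias tables."""

    rows: pd.DataFrame  # model, rmspe, mape, bias, n
    best: Mapping[str, str]  # metric -> model with smallest absolute value
    horizon: float
    subgroup_tables: Mapping[str, pd.DataFrame] = field(default_factory=dict)
    residual_summary: pd.DataFrame | None = None
    warnings_: tuple[str, ...] = ()

    def to_json(self) -> str:
        payload = {
            "horizon": self.horizon,
            "rows": self.rows.to_dict("records"),
            "best": dict(self.best),
            "warnings": list(self.warnings_),
            "subgroup_tables": {k: v.to_dict("records") for k, v in self.subgroup_tables.items()},
            "residual_summary": (
                self.residual_summary.to_dict("records") if self.residual_summary is not None else None
            ),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        payload = json.loads(text)
        rows = pd.DataFrame(payload["rows"])
        order = [c for c in ("model", "rmspe", "mape", "bias", "n") if c in rows.columns]
        return cls(
            rows=rows[order + [c for c in rows.columns if c not in order]],
            best=payload["best"],
            horizon=payload["horizon"],
            subgroup_tables={k: pd.DataFrame(v) for k, v in payload["subgroup_tables"].items()},
            residual_summary=(
                pd.DataFrame(payload["residual_summary"]) if payload["residual_summary"] else None
            ),
            warnings_=tuple(payload["warnings"]),
        )


def evaluate_all(
    cohort: Cohort,
    fits: Sequence,
    horizon: float,
    subgroup_by: Sequence[str] | None = None,
    pwp_method: str = "montecarlo",
    n_draws: int = 500,
    seed: int | None = None,
    subject_selection: str = "reaching_horizon",
) -> EvaluationReport:
    """Fit-comparison report across models on one cohort at one horizon.

    ``subject_selection='reaching_horizon'`` evaluates only subjects whose
    follow-up reaches the horizon (counts over the full (0, tau] window);
    ``'all'`` keeps everyone with per-subject truncation of both observed and
    predicted counts at min(follow_up_end, tau).
    """
    if subject_selection not in ("reaching_horizon", "all"):
        raise ValidationError(f"unknown subject_selection {subject_selection!r}")
    fit_horizons = {round(getattr(f, "horizon", horizon), 9) for f in fits}
    if len(fit_horizons) > 1:
        raise ValidationError(f"fits carry different horizons: {sorted(fit_horizons)}")
    if fit_horizons and horizon > max(fit_horizons) + 1e-9:
        raise ValidationError(
            f"evaluation horizon {horizon} exceeds the fitting horizon {max(fit_horizons)}"
        )
    eval_cohort = cohort
    notes: list[str] = []
    if subject_selection == "reaching_horizon":
        keep = cohort.follow_up() >= horizon
        if not keep.all():
            notes.append(
                f"evaluated on {int(keep.sum())}/{len(cohort)} subjects with follow-up >= {horizon}"
            )
        eval_cohort = cohort.subset(keep)
    if len(eval_cohort) == 0:
        raise ValidationError("no subjects reach the evaluation horizon")

    rows = []
    subgroup_tables: dict[str, pd.DataFrame] = {}
    resid_rows = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for fit in fits:
            ps = build_prediction_set(
                fit, eval_cohort, horizon, pwp_method=pwp_method, n_draws=n_draws, seed=seed
            )
            rows.append(
                {
                    "model": ps.model,
                    "rmspe": rmspe(ps),
                    "mape": mape(ps),
                    "bias": prediction_bias(ps),
                    "n": len(ps),
                }
            )
            if subgroup_by:
                subgroup_tables[ps.model] = subgroup_bias(ps, subgroup_by)
            if isinstance(fit, CountModelFit):
                d = deviance_residuals(fit, eval_cohort, horizon)
                resid_rows.append(
                    {
                        "model": ps.model,
                        "mean": float(np.mean(d)),
                        "sd": float(np.std(d, ddof=1)) if len(d) > 1 else 0.0,
                        "min": float(np.min(d)),
                        "max": float(np.max(d)),
                    }
                )
    notes.extend(str(w.message) for w in caught)

    table = pd.DataFrame(rows)
    best = {
        metric: table.loc[table[metric].abs().idxmin(), "model"] for metric in ("rmspe", "mape", "bias")
    }
    return EvaluationReport(
        rows=table,
        best=best,
        horizon=float(horizon),
        subgroup_tables=subgroup_tables,
        residual_summary=pd.DataFrame(resid_rows) if resid_rows else None,
        warnings_=tuple(notes),
    )
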