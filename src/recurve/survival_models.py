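"""Counting-process Cox partial-likelihood machinery for recurrent events.

Fits the Andersen-Gill (single stratum) and Prentice-Williams-Peterson
total-time (stratified by event number) models by Newton-Raphson on the
stratified partial likelihood with Breslow tie handling.  Risk sets use the
left-open, right-closed convention: a row ``(start, stop]`` is at risk at
event time t iff ``start < t <= stop``.

Variance comes in two flavours: the naive inverse observed information, and a
subject-clustered sandwich built from grouped score residuals — the
infinitesimal-jackknife estimate.  An exact leave-one-subject-out jackknife
is available as a small-sample cross-check.

Baseline cumulative hazards are Breslow step functions per stratum (reducing
to Nelson-Aalen at beta = 0), from which expected event counts at a horizon
are computed: directly for AG, and for PWP-TT either by Monte Carlo path
sampling through the stratified hazards (default, statistically faithful) or
by a fast plug-in sum that ignores the sequential conditioning.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._design import build_design, row_design
from .data_model import CovariateSchema, ValidationError
from .preprocess import AG, PWP_TT, CountingProcessTable

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Partial-likelihood maximization failed."""


@dataclass(frozen=True, eq=False)
class StepHazard:
    """Right-continuous cumulative-hazard step function H(t) = sum of jumps <= t."""

    times: np.ndarray  # ascending jump times
    jumps: np.ndarray
    cum: np.ndarray = None  # type: ignore[assignment]  # derived in __post_init__

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "jumps", np.asarray(self.jumps, dtype=float))
        if (np.diff(self.times) <= 0).any():
            raise ValidationError("StepHazard times must be strictly increasing")
        if (self.jumps < 0).any():
            raise ValidationError("StepHazard jumps must be >= 0")
        object.__setattr__(self, "cum", np.cumsum(self.jumps))

    def __call__(self, t) -> np.ndarray | float:
        idx = np.searchsorted(self.times, t, side="right")
        cum = np.concatenate([[0.0], self.cum])
        out = cum[idx]
        return float(out) if np.isscalar(t) else out

    @property
    def last_time(self) -> float:
        return float(self.times[-1]) if self.times.size else 0.0


@dataclass(frozen=True)
class SurvivalModelFit:
    """A fitted AG or PWP-TT counting-process Cox model."""

    variant: str
    coefficients: Mapping[str, float]
    naive_covariance: pd.DataFrame
    robust_covariance: pd.DataFrame
    baseline_cumhaz: Mapping[int, StepHazard]
    n_subjects: int
    n_events: int
    converged: bool
    schema: CovariateSchema
    covariate_names: tuple[str, ...]
    horizon: float

    @property
    def design_columns(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def robust_se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.robust_covariance)), index=self.robust_covariance.index)

    def naive_se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.naive_covariance)), index=self.naive_covariance.index)

    def summary_table(self, level: float = 0.95) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        se = self.robust_se()
        rows = []
        for name, b in self.coefficients.items():
            s = se[name]
            rows.append(
                {
                    "variable": name,
                    "hazard_ratio": math.exp(b),
                    "ci_low": math.exp(b - z * s),
                    "ci_high": math.exp(b + z * s),
                    "log_estimate": b,
                    "robust_se": s,
                    "naive_se": self.naive_se()[name],
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# partial likelihood internals
# ---------------------------------------------------------------------------


@dataclass
class _StratumData:
    """Precomputed per-stratum arrays independent of beta."""

    X: np.ndarray          # (n_rows, p)
    event_row_x: np.ndarray  # (n_event_rows, p) covariates of event rows
    lo: np.ndarray         # first event-time index each row is at risk for
    hi: np.ndarray         # one past the last event-time index
    event_time_idx: np.ndarray  # per event row, index of its event time
    d: np.ndarray          # (m,) tied-event counts per unique event time
    times: np.ndarray      # (m,) unique event times ascending
    row_subject: np.ndarray  # subject codes per row
    event_subjects: np.ndarray  # subject codes per event row


def _prepare_strata(table: CountingProcessTable, columns: Sequence[str], X_all: np.ndarray):
    df = table.data
    subj_codes, _ = pd.factorize(df["subject_id"], sort=False)
    strata = []
    for s in np.sort(df["stratum"].unique()):
        mask = (df["stratum"] == s).to_numpy()
        sub = df.loc[mask]
        X = X_all[mask]
        start = sub["start"].to_numpy(dtype=float)
        stop = sub["stop"].to_numpy(dtype=float)
        event = sub["event"].to_numpy() == 1
        ev_times = stop[event]
        if ev_times.size == 0:
            warnings.warn(f"stratum {s} has no events and is dropped from the fit", stacklevel=3)
            continue
        times, d = np.unique(ev_times, return_counts=True)
        lo = np.searchsorted(times, start, side="right")
        hi = np.searchsorted(times, stop, side="right")
        event_time_idx = np.searchsorted(times, ev_times)
        strata.append(
            (
                int(s),
                _StratumData(
                    X=X,
                    event_row_x=X[event],
                    lo=lo,
                    hi=hi,
                    event_time_idx=event_time_idx,
                    d=d.astype(float),
                    times=times,
                    row_subject=subj_codes[mask],
                    event_subjects=subj_codes[mask][event],
                ),
            )
        )
    if not strata:
        raise FitError("no stratum contains an event")
    return strata, subj_codes


def _range_accumulate(values: np.ndarray, lo: np.ndarray, hi: np.ndarray, m: int) -> np.ndarray:
    """Sum ``values[j]`` into positions [lo_j, hi_j) of an (m, ...) array."""
    shape = (m + 1,) + values.shape[1:]
    acc = np.zeros(shape)
    np.add.at(acc, lo, values)
    np.subtract.at(acc, hi, values)
    return np.cumsum(acc, axis=0)[:m]


def _stratum_quantities(sd: _StratumData, beta: np.ndarray, need_hessian: bool):
    eta = sd.X @ beta
    shift = eta.max() if eta.size else 0.0
    w = np.exp(eta - shift)  # stabilized weights; shift cancels except in loglik
    m = sd.times.size
    S0 = _range_accumulate(w, sd.lo, sd.hi, m)
    S1 = _range_accumulate(w[:, None] * sd.X, sd.lo, sd.hi, m)
    ev_eta = sd.event_row_x @ beta
    loglik = float(ev_eta.sum() - np.sum(sd.d * (np.log(S0) + shift)))
    xbar = S1 / S0[:, None]
    grad = sd.event_row_x.sum(axis=0) - (sd.d[:, None] * xbar).sum(axis=0)
    hess = None
    if need_hessian:
        p = sd.X.shape[1]
        wX = w[:, None] * sd.X
        outer = wX[:, :, None] * sd.X[:, None, :]
        S2 = _range_accumulate(outer.reshape(len(w), p * p), sd.lo, sd.hi, m).reshape(m, p, p)
        V = S2 / S0[:, None, None] - xbar[:, :, None] * xbar[:, None, :]
        hess = -(sd.d[:, None, None] * V).sum(axis=0)
    return loglik, grad, hess, (w, S0, S1, xbar, shift)


def fit_cox_counting(
    table: CountingProcessTable,
    covariates: Sequence[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> SurvivalModelFit:
    """Newton-Raphson fit of the stratified partial likelihood (Breslow ties).

    Returns coefficients, naive and robust (grouped score-residual sandwich,
    i.e. infinitesimal jackknife) covariances, and Breslow baseline cumulative
    hazards per stratum.
    """
    table.validate()
    names = tuple(covariates) if covariates is not None else table.covariate_names
    design = build_design(table.data, table.schema, names)
    columns = list(design.columns)
    X_all = design.to_numpy()
    n_events_total = int(table.data["event"].sum())
    if n_events_total < 1:
        raise FitError("counting-process table contains no events")
    tie_frac = 1 - table.data.loc[table.data["event"] == 1, "stop"].nunique() / max(n_events_total, 1)
    if tie_frac > 0.05:
        logger.info("tie-heavy data (%.0f%% tied events); Breslow approximation in use", 100 * tie_frac)

    strata, subj_codes = _prepare_strata(table, columns, X_all)
    p = len(columns)
    beta = np.zeros(p)
    converged = False
    loglik = -np.inf
    for _ in range(max_iter):
        ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
        for _, sd in strata:
            l_, g_, h_, _ = _stratum_quantities(sd, beta, need_hessian=True)
            ll += l_
            grad += g_
            hess += h_
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            warnings.warn(
                "fit_cox_counting: singular information matrix (monotone likelihood "
                "or collinear covariates); stopping early",
                stacklevel=2,
            )
            converged = False
            loglik = ll
            break
        # step-halving safeguard: never decrease the partial likelihood
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new = sum(_stratum_quantities(sd, cand, False)[0] for _, sd in strata)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2
        beta = beta + factor * step
        if np.max(np.abs(grad)) < 1e-9 or np.max(np.abs(factor * step)) < tol:
            converged = True
            loglik = ll
            break
        loglik = ll
    if p and np.max(np.abs(beta)) > 15:
        warnings.warn("fit_cox_counting: monotone likelihood suspected (|beta| > 15)", stacklevel=2)
        converged = False
    if not converged:
        warnings.warn("fit_cox_counting: Newton-Raphson did not converge", stacklevel=2)

    # information and grouped score residuals at the optimum.  The per-row
    # score residual is delta_j (x_j - xbar(t_j)) minus the martingale drift
    # integral of exp(eta_j) (x_j - xbar(t)) dH(t) over the row's risk span;
    # summing rows by subject gives the sandwich meat.
    info = np.zeros((p, p))
    n_subjects = int(table.data["subject_id"].nunique())
    U = np.zeros((n_subjects, p))
    for _, sd in strata:
        _, _, h_, aux = _stratum_quantities(sd, beta, need_hessian=True)
        info -= h_
        w, S0, S1, xbar, _ = aux
        A = sd.d / S0                              # dH at each event time
        B = sd.d[:, None] * S1 / S0[:, None] ** 2  # xbar(t) dH(t)
        CA = np.concatenate([[0.0], np.cumsum(A)])
        CB = np.concatenate([np.zeros((1, p)), np.cumsum(B, axis=0)], axis=0)
        drift = w[:, None] * (sd.X * (CA[sd.hi] - CA[sd.lo])[:, None] - (CB[sd.hi] - CB[sd.lo]))
        np.subtract.at(U, sd.row_subject, drift)
        ev_contrib = sd.event_row_x - xbar[sd.event_time_idx]
        np.add.at(U, sd.event_subjects, ev_contrib)

    try:
        naive = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        naive = np.linalg.pinv(info)
    robust = naive @ (U.T @ U) @ naive
    naive = (naive + naive.T) / 2
    robust = (robust + robust.T) / 2

    coeffs = dict(zip(columns, beta))
    fit = SurvivalModelFit(
        variant=table.representation,
        coefficients=coeffs,
        naive_covariance=pd.DataFrame(naive, index=columns, columns=columns),
        robust_covariance=pd.DataFrame(robust, index=columns, columns=columns),
        baseline_cumhaz={},
        n_subjects=n_subjects,
        n_events=n_events_total,
        converged=converged,
        schema=table.schema,
        covariate_names=names,
        horizon=table.horizon,
    )
    cumhaz = breslow_cumhaz(fit, table)
    return replace(fit, baseline_cumhaz=cumhaz)


def breslow_cumhaz(fit: SurvivalModelFit, table: CountingProcessTable) -> dict[int, StepHazard]:
    """Breslow baseline cumulative hazards per stratum at the fitted beta.

    Jump at event time t: (tied events at t) / sum_{at risk at t} exp(x beta).
    Equals the Nelson-Aalen estimator when beta = 0 on a single stratum.
    """
    design = build_design(table.data, table.schema, fit.covariate_names)
    beta = np.array([fit.coefficients[c] for c in design.columns])
    X_all = design.to_numpy()
    out: dict[int, StepHazard] = {}
    df = table.data
    for s in np.sort(df["stratum"].unique()):
        mask = (df["stratum"] == s).to_numpy()
        sub = df.loc[mask]
        event = sub["event"].to_numpy() == 1
        ev_times = sub["stop"].to_numpy(dtype=float)[event]
        if ev_times.size == 0:
            out[int(s)] = StepHazard(np.empty(0), np.empty(0))
            continue
        times, d = np.unique(ev_times, return_counts=True)
        start = sub["start"].to_numpy(dtype=float)
        stop = sub["stop"].to_numpy(dtype=float)
        lo = np.searchsorted(times, start, side="right")
        hi = np.searchsorted(times, stop, side="right")
        w = np.exp(X_all[mask] @ beta)
        S0 = _range_accumulate(w, lo, hi, times.size)
        out[int(s)] = StepHazard(times, d / S0)
    return out


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict_count_ag(fit: SurvivalModelFit, x: Mapping[str, object], tau: float) -> float:
    """Expected events over (0, tau] under the AG model: H0(tau) exp(x beta)."""
    if fit.variant != AG:
        raise ValidationError("predict_count_ag requires an AG fit")
    H0 = fit.baseline_cumhaz[1]
    if tau > H0.last_time:
        warnings.warn(
            f"tau={tau} beyond last observed event time {H0.last_time}; extrapolating by last value",
            stacklevel=2,
        )
    xb = float(row_design(x, fit.schema, fit.design_columns) @ np.array(list(fit.coefficients.values())))
    return float(H0(tau) * math.exp(xb))


def predict_counts_ag(fit: SurvivalModelFit, frame: pd.DataFrame, tau: float) -> np.ndarray:
    """Vectorized AG expected counts for rows of a covariate frame."""
    if fit.variant != AG:
        raise ValidationError("predict_counts_ag requires an AG fit")
    design = build_design(frame, fit.schema, fit.covariate_names)
    beta = np.array([fit.coefficients[c] for c in design.columns])
    H0 = fit.baseline_cumhaz[1]
    if tau > H0.last_time:
        warnings.warn(
            f"tau={tau} beyond last observed event time {H0.last_time}; extrapolating by last value",
            stacklevel=2,
        )
    return float(H0(tau)) * np.exp(design.to_numpy() @ beta)


def pool_sparse_strata(table: CountingProcessTable, min_events: int = 5) -> CountingProcessTable:
    """Pool PWP strata with fewer than ``min_events`` events into the last
    retained stratum (guards over-optimistic sparse-stratum hazards)."""
    if table.representation != PWP_TT:
        return table
    df = table.data
    ev_per_stratum = df.groupby("stratum")["event"].sum().sort_index()
    keep = 0
    for s, n_ev in ev_per_stratum.items():
        if n_ev >= min_events:
            keep = int(s)
        else:
            break
    keep = max(keep, 1)
    if keep == ev_per_stratum.index.max():
        return table
    warnings.warn(
        f"pooling PWP strata > {keep} (fewer than {min_events} events) into stratum {keep}",
        stacklevel=2,
    )
    new = df.copy()
    new.loc[new["stratum"] > keep, "stratum"] = keep
    return CountingProcessTable(
        new, table.representation, table.horizon, table.covariate_names, table.schema, pooled_after=keep
    )


def predict_count_pwp(
    fit: SurvivalModelFit,
    x: Mapping[str, object],
    tau: float,
    method: str = "montecarlo",
    n_draws: int = 1000,
    seed: int | None = None,
) -> float:
    """Expected events over (0, tau] under the PWP-TT model.

    ``montecarlo`` samples event paths through the stratified total-time
    hazards (event k drawn from the stratum-k hazard conditioned on occurring
    after event k-1) and averages the path length — seeded and statistically
    faithful.  ``plugin`` returns ``sum_k 1 - exp(-H_0k(tau) e^{x beta})``,
    fast but ignoring the sequential conditioning.  Predictions are bounded by
    the number of strata K.
    """
    frame = pd.DataFrame([dict(x)])
    return float(predict_counts_pwp(fit, frame, tau, method=method, n_draws=n_draws, seed=seed)[0])


def predict_counts_pwp(
    fit: SurvivalModelFit,
    frame: pd.DataFrame,
    tau: float,
    method: str = "montecarlo",
    n_draws: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Vectorized PWP-TT expected counts for rows of a covariate frame."""
    if fit.variant != PWP_TT:
        raise ValidationError("predict_counts_pwp requires a PWP-TT fit")
    if tau <= 0:
        return np.zeros(len(frame))
    design = build_design(frame, fit.schema, fit.covariate_names)
    beta = np.array([fit.coefficients[c] for c in design.columns])
    e_eta = np.exp(design.to_numpy() @ beta)
    strata = sorted(fit.baseline_cumhaz)
    if method == "plugin":
        total = np.zeros(len(frame))
        for s in strata:
            H = fit.baseline_cumhaz[s]
            total += 1.0 - np.exp(-float(H(tau)) * e_eta)
        return total
    if method != "montecarlo":
        raise ValidationError(f"unknown PWP prediction method {method!r}")
    if seed is None:
        raise ValidationError("montecarlo PWP prediction requires a seed")
    rng = np.random.default_rng(seed)
    n = len(frame)
    T = np.zeros((n, n_draws))          # time of last event per path
    active = np.ones((n, n_draws), dtype=bool)
    counts = np.zeros((n, n_draws))
    for s in strata:
        H = fit.baseline_cumhaz[s]
        if H.times.size == 0 or not active.any():
            break
        cum = H.cum
        times = H.times
        base = np.concatenate([[0.0], cum])[np.searchsorted(times, T, side="right")]
        E = rng.exponential(size=(n, n_draws))
        target = base + E / e_eta[:, None]
        idx = np.searchsorted(cum, target, side="left")
        reached = active & (idx < times.size)
        t_new = np.where(reached, times[np.minimum(idx, times.size - 1)], np.inf)
        happened = reached & (t_new <= tau)
        counts[happened] += 1
        T = np.where(happened, t_new, T)
        active = happened
    return counts.mean(axis=1)


def jackknife_covariance(
    table: CountingProcessTable, covariates: Sequence[str] | None = None
) -> pd.DataFrame:
    """Exact leave-one-subject-out jackknife covariance (small-n cross-check).

    Refits the model once per subject; use only when n_subjects is modest.
    """
    names = tuple(covariates) if covariates is not None else table.covariate_names
    full = fit_cox_counting(table, names)
    cols = list(full.coefficients)
    beta_full = np.array([full.coefficients[c] for c in cols])
    ids = table.data["subject_id"].unique()
    deltas = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sid in ids:
            sub = table.data[table.data["subject_id"] != sid]
            sub_table = CountingProcessTable(
                sub,
                table.representation,
                table.horizon,
                table.covariate_names,
                table.schema,
                pooled_after=table.pooled_after,
            )
            try:
                f = fit_cox_counting(sub_table, names)
            except FitError:
                continue
            deltas.append(np.array([f.coefficients[c] for c in cols]) - beta_full)
    D = np.asarray(deltas)
    g = len(D)
    cov = (g - 1) / g * (D.T @ D)
    return pd.DataFrame(cov, index=cols, columns=cols)
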