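"""Negative binomial and zero-inflated negative binomial count regressions.

Both models are fitted by direct maximization of the log-likelihood with
analytic gradients (NB2 parameterization: variance mu + alpha mu^2, alpha
optimized on the log scale for positivity).  Standard errors come from the
observed information (numerical Hessian at the optimum).  Counts are events
in ``(0, min(follow_up_end, horizon)]`` and an exposure offset
``log(min(follow_up_end, horizon))`` is included by default.

Exponentiated count coefficients are rate ratios; exponentiated logit-part
coefficients of the ZINB are odds ratios for being a structural zero.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import digamma, expit, gammaln
from statsmodels.tools.numdiff import approx_hess1

from ._design import build_design
from .data_model import Cohort, CovariateSchema, ValidationError

logger = logging.getLogger(__name__)

NB = "NB"
ZINB = "ZINB"

_MIN_LOG_ALPHA = -30.0  # exp(-30) ~ Poisson for all practical purposes


class FitError(RuntimeError):
    """Model fitting failed in a way that must not be silently ignored."""


@dataclass(frozen=True)
class CountModelFit:
    """A fitted NB or ZINB regression."""

    model: str
    count_coefficients: Mapping[str, float]
    dispersion: float
    zero_coefficients: Mapping[str, float] | None
    covariance: pd.DataFrame
    log_likelihood: float
    converged: bool
    n_used: int
    horizon: float
    use_offset: bool
    schema: CovariateSchema
    formula: tuple[str, ...]
    zero_formula: tuple[str, ...] | None = None

    @property
    def count_columns(self) -> tuple[str, ...]:
        return tuple(self.count_coefficients)

    @property
    def zero_columns(self) -> tuple[str, ...]:
        return tuple(self.zero_coefficients) if self.zero_coefficients else ()

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance)), index=self.covariance.index)

    def summary_table(self, level: float = 0.95) -> pd.DataFrame:
        """Exponentiated estimates with Wald confidence intervals, one row per
        free parameter (component column separates count and zero parts)."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        rows = []
        se = self.se()
        for comp, coefs in (("count", self.count_coefficients), ("zero", self.zero_coefficients or {})):
            for name, est in coefs.items():
                key = name if comp == "count" else f"zero:{name}"
                s = se.get(key, np.nan)
                rows.append(
                    {
                        "component": comp,
                        "variable": name,
                        "estimate": math.exp(est),
                        "ci_low": math.exp(est - z * s),
                        "ci_high": math.exp(est + z * s),
                        "log_estimate": est,
                        "se": s,
                    }
                )
        rows.append(
            {
                "component": "dispersion",
                "variable": "alpha",
                "estimate": self.dispersion,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "log_estimate": np.nan,
                "se": np.nan,
            }
        )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# likelihood pieces (t = 1/alpha throughout)
# ---------------------------------------------------------------------------


def _nb_loglik_terms(y: np.ndarray, mu: np.ndarray, t: float) -> np.ndarray:
    return (
        gammaln(y + t)
        - gammaln(t)
        - gammaln(y + 1)
        + t * (np.log(t) - np.log(t + mu))
        + y * (np.log(mu) - np.log(t + mu))
    )


def _poisson_loglik_terms(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    return y * np.log(mu) - mu - gammaln(y + 1)


def _nb_saturated_terms(y: np.ndarray, t: float | None) -> np.ndarray:
    """Per-observation log-likelihood at mu = y (alpha fixed); 0 when y == 0."""
    y = np.asarray(y, dtype=float)
    out = np.zeros_like(y)
    pos = y > 0
    yp = y[pos]
    if t is None:  # Poisson limit
        out[pos] = yp * np.log(yp) - yp - gammaln(yp + 1)
    else:
        out[pos] = (
            gammaln(yp + t)
            - gammaln(t)
            - gammaln(yp + 1)
            + t * (np.log(t) - np.log(t + yp))
            + yp * (np.log(yp) - np.log(t + yp))
        )
    return out


def _counts_and_exposure(cohort: Cohort, horizon: float) -> tuple[np.ndarray, np.ndarray]:
    y = cohort.counts(horizon).astype(float)
    exposure = np.minimum(cohort.follow_up(), horizon)
    return y, exposure


def _poisson_start(X: np.ndarray, y: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Newton iterations on the Poisson log-likelihood (concave) for a warm start."""
    beta = np.zeros(X.shape[1])
    for _ in range(50):
        eta = np.clip(X @ beta + offset, -30, 30)
        mu = np.exp(eta)
        grad = X.T @ (y - mu)
        hess = -(X * mu[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _logistic_fit(Z: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Newton logistic regression of binary w on Z (warm start only)."""
    gamma = np.zeros(Z.shape[1])
    for _ in range(50):
        p = expit(np.clip(Z @ gamma, -30, 30))
        grad = Z.T @ (w - p)
        W = p * (1 - p) + 1e-10
        hess = -(Z * W[:, None]).T @ Z
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(step)) > 5:
            step = step * (5 / np.max(np.abs(step)))
        gamma = gamma + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.clip(gamma, -15, 15)


# ---------------------------------------------------------------------------
# NB fit
# ---------------------------------------------------------------------------


def fit_nb(
    cohort: Cohort,
    formula: Sequence[str],
    horizon: float,
    dispersion: float | None = None,
    use_offset: bool = True,
) -> CountModelFit:
    """Maximum-likelihood NB2 regression of event counts at ``horizon``.

    ``dispersion`` fixes alpha (0 gives the Poisson limit); otherwise alpha is
    estimated jointly with the coefficients.
    """
    if len(cohort) < 2:
        raise FitError("fit_nb requires at least 2 subjects")
    y, exposure = _counts_and_exposure(cohort, horizon)
    if y.sum() == 0:
        raise FitError("all event counts are zero; the count model is degenerate")
    Xf = build_design(cohort.covariate_frame(), cohort.schema, formula, intercept=True)
    cols = list(Xf.columns)
    X = Xf.to_numpy()
    offset = np.log(exposure) if use_offset else np.zeros_like(exposure)

    beta0 = _poisson_start(X, y, offset)
    mu0 = np.exp(np.clip(X @ beta0 + offset, -30, 30))
    # method-of-moments start for alpha
    alpha0 = max(float(np.mean((y - mu0) ** 2 - mu0) / max(np.mean(mu0**2), 1e-12)), 1e-3)

    fixed_poisson = dispersion is not None and dispersion == 0
    fixed_alpha = dispersion is not None and dispersion > 0

    if fixed_poisson:

        def negll(params):
            mu = np.exp(np.clip(X @ params + offset, -300, 300))
            return -np.sum(_poisson_loglik_terms(y, mu))

        def grad(params):
            mu = np.exp(np.clip(X @ params + offset, -300, 300))
            return -(X.T @ (y - mu))

        x0 = beta0
    else:

        def unpack(params):
            beta = params[: len(cols)]
            la = float(params[len(cols)]) if not fixed_alpha else math.log(dispersion)
            return beta, np.clip(la, _MIN_LOG_ALPHA, 30.0)

        def negll(params):
            beta, la = unpack(params)
            t = math.exp(-la)
            mu = np.exp(np.clip(X @ beta + offset, -300, 300))
            return -np.sum(_nb_loglik_terms(y, mu, t))

        def grad(params):
            beta, la = unpack(params)
            t = math.exp(-la)
            mu = np.exp(np.clip(X @ beta + offset, -300, 300))
            gb = X.T @ (t * (y - mu) / (t + mu))
            if fixed_alpha:
                return -gb
            dt = np.sum(digamma(y + t) - digamma(t) + np.log(t) + 1 - np.log(t + mu) - (t + y) / (t + mu))
            return -np.concatenate([gb, [-t * dt]])

        x0 = np.concatenate([beta0, [math.log(alpha0)]]) if not fixed_alpha else beta0

    res = optimize.minimize(negll, x0, jac=grad, method="BFGS", options={"maxiter": 500, "gtol": 1e-8})
    # polish with Nelder-Mead if BFGS stalled
    if not res.success:
        res2 = optimize.minimize(negll, res.x, method="Nelder-Mead", options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-10})
        if res2.fun < res.fun:
            res = res2
    converged = bool(np.max(np.abs(grad(res.x))) < 1e-3 * max(1.0, abs(res.fun)))
    if not converged:
        warnings.warn("fit_nb: optimizer did not reach a small gradient; inspect the fit", stacklevel=2)

    if fixed_poisson:
        beta_hat = res.x
        alpha_hat = 0.0
        param_names = cols
    elif fixed_alpha:
        beta_hat = res.x
        alpha_hat = float(dispersion)
        param_names = cols
    else:
        beta_hat = res.x[: len(cols)]
        alpha_hat = math.exp(float(np.clip(res.x[len(cols)], _MIN_LOG_ALPHA, 30.0)))
        param_names = cols + ["log_alpha"]

    cov = _observed_information_cov(negll, res.x, param_names)
    return CountModelFit(
        model=NB,
        count_coefficients=dict(zip(cols, beta_hat)),
        dispersion=alpha_hat,
        zero_coefficients=None,
        covariance=cov,
        log_likelihood=-float(res.fun),
        converged=converged,
        n_used=len(y),
        horizon=float(horizon),
        use_offset=use_offset,
        schema=cohort.schema,
        formula=tuple(formula),
    )


def _observed_information_cov(negll, x_hat: np.ndarray, names: Sequence[str]) -> pd.DataFrame:
    try:
        H = approx_hess1(x_hat, negll)
        cov = np.linalg.inv(H)
        # symmetrize; clip tiny negative diagonal from numerical error
        cov = (cov + cov.T) / 2
    except np.linalg.LinAlgError:
        cov = np.full((len(x_hat), len(x_hat)), np.nan)
    return pd.DataFrame(cov, index=list(names), columns=list(names))


# ---------------------------------------------------------------------------
# ZINB fit
# ---------------------------------------------------------------------------


def fit_zinb(
    cohort: Cohort,
    count_formula: Sequence[str],
    zero_formula: Sequence[str] | None = None,
    horizon: float = None,  # type: ignore[assignment]
    use_offset: bool = True,
) -> CountModelFit:
    """Joint MLE of a logit structural-zero component and an NB count component.

    Mixture likelihood: zeros contribute ``pi + (1 - pi) NB(0)``, positive
    counts ``(1 - pi) NB(y)``.  Warm-started from the NB fit plus a logistic
    regression on the zero indicator, with a low-inflation second start.
    """
    if horizon is None:
        raise ValidationError("fit_zinb requires a horizon")
    if len(cohort) < 2:
        raise FitError("fit_zinb requires at least 2 subjects")
    if zero_formula is None:
        zero_formula = list(count_formula)
    y, exposure = _counts_and_exposure(cohort, horizon)
    if y.sum() == 0:
        raise FitError("all event counts are zero; the count model is degenerate")
    frame = cohort.covariate_frame()
    Xf = build_design(frame, cohort.schema, count_formula, intercept=True)
    Zf = build_design(frame, cohort.schema, zero_formula, intercept=True)
    ccols, zcols = list(Xf.columns), list(Zf.columns)
    X, Z = Xf.to_numpy(), Zf.to_numpy()
    offset = np.log(exposure) if use_offset else np.zeros_like(exposure)
    p, q = len(ccols), len(zcols)
    zero_mask = y == 0

    def unpack(params):
        return params[:q], params[q : q + p], float(np.clip(params[-1], _MIN_LOG_ALPHA, 30.0))

    def negll(params):
        gamma, beta, la = unpack(params)
        t = math.exp(-la)
        mu = np.exp(np.clip(X @ beta + offset, -300, 300))
        zeta = np.clip(Z @ gamma, -300, 300)
        log_nb = _nb_loglik_terms(y, mu, t)
        # log L = -log(1+e^zeta) + log( e^zeta * 1[y==0] + e^{log_nb} )
        ll = -np.logaddexp(0.0, zeta)
        with np.errstate(over="ignore"):
            ll = ll + np.where(zero_mask, np.logaddexp(zeta, log_nb), log_nb)
        return -np.sum(ll)

    def grad(params):
        gamma, beta, la = unpack(params)
        t = math.exp(-la)
        mu = np.exp(np.clip(X @ beta + offset, -300, 300))
        zeta = np.clip(Z @ gamma, -300, 300)
        pi = expit(zeta)
        log_p0 = t * (np.log(t) - np.log(t + mu))
        p0 = np.exp(log_p0)
        L0 = pi + (1 - pi) * p0  # likelihood of an observed zero
        # gamma part
        dg = np.where(zero_mask, pi * (1 - pi) * (1 - p0) / L0, -pi)
        g_gamma = Z.T @ dg
        # beta part
        nb_score_eta = t * (y - mu) / (t + mu)
        zero_score_eta = (1 - pi) * p0 * (-t * mu / (t + mu)) / L0
        g_beta = X.T @ np.where(zero_mask, zero_score_eta, nb_score_eta)
        # dispersion part (d/dt then chain to log alpha)
        dlogp0_dt = np.log(t) + 1 - np.log(t + mu) - t / (t + mu)
        nb_dt = digamma(y + t) - digamma(t) + np.log(t) + 1 - np.log(t + mu) - (t + y) / (t + mu)
        dt = np.where(zero_mask, (1 - pi) * p0 * dlogp0_dt / L0, nb_dt)
        g_la = -t * np.sum(dt)
        return -np.concatenate([g_gamma, g_beta, [g_la]])

    nb_fit = fit_nb(cohort, count_formula, horizon, use_offset=use_offset)
    beta_nb = np.array([nb_fit.count_coefficients[c] for c in ccols])
    la_nb = math.log(max(nb_fit.dispersion, 1e-8))
    gamma_logit = _logistic_fit(Z, zero_mask.astype(float))
    starts = [
        np.concatenate([gamma_logit, beta_nb, [la_nb]]),
        np.concatenate([np.r_[-4.0, np.zeros(q - 1)], beta_nb, [la_nb]]),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(negll, x0, jac=grad, method="BFGS", options={"maxiter": 1000, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    res = best
    converged = bool(np.max(np.abs(grad(res.x))) < 1e-3 * max(1.0, abs(res.fun)))
    if not converged:
        warnings.warn("fit_zinb: optimizer did not reach a small gradient; inspect the fit", stacklevel=2)
    gamma_hat, beta_hat, la_hat = unpack(res.x)
    if np.max(np.abs(gamma_hat[1:] if q > 1 else gamma_hat)) > 12:
        warnings.warn("fit_zinb: possible separation in the logit component", stacklevel=2)

    names = [f"zero:{c}" for c in zcols] + ccols + ["log_alpha"]
    cov = _observed_information_cov(negll, res.x, names)
    return CountModelFit(
        model=ZINB,
        count_coefficients=dict(zip(ccols, beta_hat)),
        dispersion=math.exp(la_hat),
        zero_coefficients=dict(zip(zcols, gamma_hat)),
        covariance=cov,
        log_likelihood=-float(res.fun),
        converged=converged,
        n_used=len(y),
        horizon=float(horizon),
        use_offset=use_offset,
        schema=cohort.schema,
        formula=tuple(count_formula),
        zero_formula=tuple(zero_formula),
    )


# ---------------------------------------------------------------------------
# prediction and residuals
# ---------------------------------------------------------------------------


def _mu_pi(fit: CountModelFit, frame: pd.DataFrame, exposure: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Xf = build_design(frame, fit.schema, fit.formula, intercept=True)
    beta = np.array([fit.count_coefficients[c] for c in Xf.columns])
    offset = np.log(exposure) if fit.use_offset else np.zeros(len(frame))
    mu = np.exp(np.clip(Xf.to_numpy() @ beta + offset, -300, 300))
    if fit.model == ZINB:
        Zf = build_design(frame, fit.schema, fit.zero_formula, intercept=True)
        gamma = np.array([fit.zero_coefficients[c] for c in Zf.columns])
        pi = expit(np.clip(Zf.to_numpy() @ gamma, -300, 300))
    else:
        pi = np.zeros(len(frame))
    return mu, pi


def predict_counts(fit: CountModelFit, frame: pd.DataFrame, exposure: np.ndarray | float) -> np.ndarray:
    """Vectorized predicted counts for rows of a covariate frame."""
    exposure = np.broadcast_to(np.asarray(exposure, dtype=float), (len(frame),))
    mu, pi = _mu_pi(fit, frame, exposure)
    return (1 - pi) * mu


def predict_count(fit: CountModelFit, x: Mapping[str, object], exposure: float) -> float:
    """Predicted event count for one subject over ``exposure`` days.

    NB: ``exposure * exp(x beta)``; ZINB: ``(1 - pi(x)) * exposure * exp(x beta)``
    (with the offset convention the fit used).
    """
    frame = pd.DataFrame([dict(x)])
    return float(predict_counts(fit, frame, exposure)[0])


def deviance_residuals(fit: CountModelFit, cohort: Cohort, horizon: float | None = None) -> np.ndarray:
    """Per-subject deviance residuals ``sign(y - yhat) sqrt(2 (l_sat - l_fit))``.

    The saturated likelihood evaluates each observation at mu = y with alpha
    held at its estimate; for the ZINB the saturated model additionally frees
    pi per point, attaining its maximum at the observed zero/non-zero pattern
    (so saturated zeros contribute 0).  ``sum(d_i^2)`` is the model deviance.
    """
    horizon = fit.horizon if horizon is None else horizon
    y, exposure = _counts_and_exposure(cohort, horizon)
    frame = cohort.covariate_frame()
    mu, pi = _mu_pi(fit, frame, exposure)
    yhat = (1 - pi) * mu
    t = None if fit.dispersion == 0 else 1.0 / fit.dispersion

    if fit.model == NB:
        fitted = _poisson_loglik_terms(y, mu) if t is None else _nb_loglik_terms(y, mu, t)
        saturated = _nb_saturated_terms(y, t)
    else:
        zeta = np.log(pi) - np.log1p(-pi)
        log_nb = _nb_loglik_terms(y, mu, t)
        fitted = -np.logaddexp(0.0, zeta) + np.where(y == 0, np.logaddexp(zeta, log_nb), log_nb)
        saturated = _nb_saturated_terms(y, t)  # zeros already contribute 0
    gap = np.maximum(2.0 * (saturated - fitted), 0.0)
    return np.sign(y - yhat) * np.sqrt(gap)
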