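"""Single-SNP analysis models: logistic, Cox PH, and EM mixture-cure Cox.

All three estimators consume the observed cohort columns only
(``genotype``, ``obs_time``, ``event``) — the background score and the
simulation-truth columns are deliberately ignored, mimicking a genome-wide
association analysis that tests one SNP at a time.

The mixture-cure fitter alternates an E-step, which computes each censored
subject's posterior probability of being at risk, with M-steps that refit a
fractionally-weighted logistic regression (incidence), a weighted Breslow
partial likelihood (latency), and the Breslow baseline survival with its
tail forced to zero beyond the last event time.  Standard errors come from
a nonparametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

__all__ = [
    "FitResult",
    "CureFit",
    "BaselineSurvival",
    "IdentifiabilityError",
    "fit_logistic",
    "fit_cox",
    "breslow_baseline",
    "estep_weights",
    "fit_cure_cox",
    "observed_loglik",
]

_MAX_ABS_COEF = 30.0  # beyond this the likelihood is effectively monotone


class IdentifiabilityError(ValueError):
    """The cure component cannot be identified from the given data."""


@dataclass
class FitResult:
    """One coefficient estimate on the log scale (log-OR or log-HR)."""

    estimate: float
    se: float
    p_value: float
    converged: bool
    n_iter: int
    intercept: float | None = None

    def record(self, analysis: str) -> dict:
        return {
            "analysis": analysis,
            "estimate": self.estimate,
            "se": self.se,
            "p": self.p_value,
            "converged": self.converged,
            "iterations": self.n_iter,
        }


class BaselineSurvival:
    """Breslow baseline survival step function with a zero tail.

    Non-increasing, 1 before the first event time, ``exp(-cumhaz)`` at each
    event time, and exactly 0 beyond the last event time so that late
    censored subjects are pushed toward the cured class in the E-step.
    """

    def __init__(self, times: np.ndarray, cumhaz: np.ndarray):
        self.times = np.asarray(times, dtype=float)
        self.cumhaz = np.asarray(cumhaz, dtype=float)
        self.surv = np.exp(-self.cumhaz)

    @property
    def last_event_time(self) -> float:
        return float(self.times[-1])

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        s = np.where(idx == 0, 1.0, self.surv[np.maximum(idx - 1, 0)])
        s = np.where(t > self.times[-1], 0.0, s)
        return s if s.ndim else float(s)

    def cumulative_hazard(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        h = np.where(idx == 0, 0.0, self.cumhaz[np.maximum(idx - 1, 0)])
        return h if h.ndim else float(h)

    def increments(self) -> np.ndarray:
        return np.diff(self.cumhaz, prepend=0.0)


@dataclass
class CureFit:
    """Joint fit of the mixture-cure Cox model."""

    logistic_part: FitResult
    survival_part: FitResult
    baseline_survival: BaselineSurvival
    em_iters: int
    em_converged: bool
    bootstrap_reps_used: int
    loglik_trace: list = field(default_factory=list)


def _wald_p(estimate: float, se: float) -> float:
    if not np.isfinite(se) or se <= 0:
        return float("nan")
    return float(2.0 * norm.sf(abs(estimate) / se))


# ---------------------------------------------------------------------------
# logistic regression (IRLS / Newton-Raphson), fractional responses allowed
# ---------------------------------------------------------------------------

def _logistic_nr(x: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """Maximize the Bernoulli likelihood of y (possibly fractional) on [1, x].

    Returns (intercept, slope, se_slope, converged, n_iter).
    """
    n = x.size
    if np.ptp(y) < 1e-12:  # constant response: intercept diverges
        return float("nan"), float("nan"), float("nan"), False, 0
    X = np.column_stack([np.ones(n), x])
    beta = np.zeros(2)
    eta = X @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        wd = np.maximum(mu * (1.0 - mu), 1e-12)
        grad = X.T @ (y - mu)
        info = (X * wd[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            return float(beta[0]), float(beta[1]), float("nan"), False, it
        # step-halving keeps the ascent monotone on awkward fractional data
        factor = 1.0
        for _ in range(25):
            cand = beta + factor * step
            eta_c = X @ cand
            ll_c = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum())
            if ll_c >= ll - 1e-12:
                break
            factor *= 0.5
        beta = beta + factor * step
        eta = X @ beta
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        if np.max(np.abs(factor * step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > _MAX_ABS_COEF:
            converged = False
            break
    if np.max(np.abs(beta)) > _MAX_ABS_COEF:
        converged = False
    mu = expit(eta)
    wd = np.maximum(mu * (1.0 - mu), 1e-12)
    info = (X * wd[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        se = float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        se = float("nan")
    return float(beta[0]), float(beta[1]), se, converged, it


def fit_logistic(cohort: pd.DataFrame, weights: np.ndarray | None = None) -> FitResult:
    """Logistic regression of event status (or fractional weights) on genotype.

    With ``weights`` given, they are used as the fractional response — the
    form needed by the EM M-step, where the response is the posterior
    at-risk probability.  Complete separation is reported as
    ``converged=False``, never as an exception.
    """
    x = cohort["genotype"].to_numpy(dtype=float)
    if weights is None:
        y = cohort["event"].to_numpy(dtype=float)
    else:
        y = np.asarray(weights, dtype=float)
        if y.shape != x.shape:
            raise ValueError("weights must have one entry per subject")
        if np.any((y < 0) | (y > 1)):
            raise ValueError("fractional responses must lie in [0, 1]")
    intercept, slope, se, converged, it = _logistic_nr(x, y)
    return FitResult(
        estimate=slope,
        se=se,
        p_value=_wald_p(slope, se) if converged else float("nan"),
        converged=converged,
        n_iter=it,
        intercept=intercept,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow partial likelihood, Newton-Raphson)
# ---------------------------------------------------------------------------

def _cox_nr(
    time: np.ndarray,
    event: np.ndarray,
    x: np.ndarray,
    w: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-9,
):
    """Maximize the weighted Breslow partial likelihood in the 1-D coefficient.

    Weights enter both the event terms and the risk-set sums; subjects with
    (numerically) zero weight drop out entirely.  Returns
    (beta, se, converged, n_iter).
    """
    keep = w > 1e-12
    time, event, x, w = time[keep], event[keep], x[keep], w[keep]
    if not np.any(event):
        return float("nan"), float("nan"), False, 0
    order = np.argsort(time, kind="stable")
    t, d, xx, ww = time[order], event[order], x[order], w[order]
    ev = np.flatnonzero(d)
    risk_start = np.searchsorted(t, t[ev], side="left")
    we, xe = ww[ev], xx[ev]
    # no covariate variation among weighted subjects -> flat likelihood
    mean_x = np.average(xx, weights=ww)
    if np.average((xx - mean_x) ** 2, weights=ww) < 1e-12:
        return float("nan"), float("nan"), False, 0

    def suffix(a: np.ndarray) -> np.ndarray:
        return np.cumsum(a[::-1])[::-1]

    beta = 0.0
    info = float("nan")
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r = ww * np.exp(beta * xx)
        s0 = suffix(r)[risk_start]
        s1 = suffix(r * xx)[risk_start]
        s2 = suffix(r * xx * xx)[risk_start]
        mu = s1 / s0
        grad = float(np.sum(we * (xe - mu)))
        info = float(np.sum(we * (s2 / s0 - mu * mu)))
        if not np.isfinite(info) or info <= 0:
            return beta, float("nan"), False, it
        step = grad / info
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(beta) > _MAX_ABS_COEF:  # monotone likelihood
            return beta, float("nan"), False, it
        if abs(step) < tol:
            converged = True
            break
    se = float(1.0 / np.sqrt(info))
    return float(beta), se, converged, it


def fit_cox(cohort: pd.DataFrame, weights: np.ndarray | None = None) -> FitResult:
    """Cox PH fit of observed time/event on genotype (Breslow ties).

    With all weights 1 (or omitted) this is the traditional single-SNP Cox
    analysis; fractional weights give the latency M-step of the cure model.
    Monotone likelihoods (all events at a covariate extreme) are flagged as
    non-converged.
    """
    time = cohort["obs_time"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(dtype=bool)
    x = cohort["genotype"].to_numpy(dtype=float)
    if np.any(time <= 0):
        raise ValueError("obs_time must be positive")
    w = np.ones_like(time) if weights is None else np.asarray(weights, dtype=float)
    beta, se, converged, it = _cox_nr(time, event, x, w)
    return FitResult(
        estimate=beta,
        se=se,
        p_value=_wald_p(beta, se) if converged else float("nan"),
        converged=converged,
        n_iter=it,
    )


def _baseline_core(
    time: np.ndarray, event: np.ndarray, x: np.ndarray, w: np.ndarray, beta: float
) -> BaselineSurvival:
    order = np.argsort(time, kind="stable")
    t, d, xx, ww = time[order], event[order], x[order], w[order]
    ev = np.flatnonzero(d)
    if ev.size == 0:
        raise ValueError("no events: baseline hazard undefined")
    r = ww * np.exp(beta * xx)
    s0 = np.cumsum(r[::-1])[::-1]
    risk_start = np.searchsorted(t, t[ev], side="left")
    denom = s0[risk_start]
    if np.any(denom <= 0):
        raise ValueError("empty (zero-weight) risk set at an event time")
    # group tied event times (Breslow): summed weighted events over one denominator
    times_ev = t[ev]
    uniq, inverse = np.unique(times_ev, return_inverse=True)
    num = np.bincount(inverse, weights=ww[ev])
    den = np.zeros(uniq.size)
    den[inverse] = denom  # same denominator for every event at a tied time
    cumhaz = np.cumsum(num / den)
    return BaselineSurvival(uniq, cumhaz)


def breslow_baseline(
    cohort: pd.DataFrame, beta: float, weights: np.ndarray | None = None
) -> BaselineSurvival:
    """Breslow baseline survival at the given coefficient and weights.

    At beta=0 with unit weights this reduces to exp(-Nelson-Aalen).
    """
    time = cohort["obs_time"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(dtype=bool)
    x = cohort["genotype"].to_numpy(dtype=float)
    w = np.ones_like(time) if weights is None else np.asarray(weights, dtype=float)
    return _baseline_core(time, event, x, w, beta)


def _estep_core(
    time: np.ndarray,
    event: np.ndarray,
    x: np.ndarray,
    intercept: float,
    log_or: float,
    log_hr: float,
    baseline: BaselineSurvival,
) -> np.ndarray:
    w = np.ones(time.size)
    cens = ~event
    if np.any(cens):
        pi = expit(intercept + log_or * x[cens])
        surv = baseline(time[cens]) ** np.exp(log_hr * x[cens])
        denom = np.maximum(1.0 - pi + pi * surv, 1e-300)
        w[cens] = pi * surv / denom
    return np.clip(w, 0.0, 1.0)


def estep_weights(
    cohort: pd.DataFrame,
    logistic_params: tuple[float, float],
    beta: float,
    baseline_survival: BaselineSurvival,
) -> np.ndarray:
    """Posterior at-risk probabilities given the current model parameters.

    Subjects with events are at risk with certainty (weight 1); a censored
    subject's weight is ``pi*S / (1 - pi + pi*S)`` with ``pi`` its logistic
    at-risk probability and ``S`` its conditional survival.  Censored
    subjects beyond the last event time get weight 0 via the zero tail.
    """
    intercept, log_or = logistic_params
    return _estep_core(
        cohort["obs_time"].to_numpy(dtype=float),
        cohort["event"].to_numpy(dtype=bool),
        cohort["genotype"].to_numpy(dtype=float),
        intercept,
        log_or,
        beta,
        baseline_survival,
    )


def observed_loglik(
    time: np.ndarray,
    event: np.ndarray,
    x: np.ndarray,
    intercept: float,
    log_or: float,
    log_hr: float,
    baseline: BaselineSurvival,
) -> float:
    """Observed-data log likelihood of the semiparametric mixture.

    Events contribute ``pi * dLambda0(t) * exp(bx) * S0(t)^exp(bx)``;
    censored subjects contribute ``1 - pi + pi * S0(t)^exp(bx)``.
    """
    pi = expit(intercept + log_or * x)
    theta = np.exp(log_hr * x)
    cumhaz = baseline.cumulative_hazard(time)
    ll = 0.0
    if np.any(event):
        jump = np.diff(baseline.cumhaz, prepend=0.0)
        pos = np.searchsorted(baseline.times, time[event])
        ll += float(
            np.sum(
                np.log(np.maximum(pi[event], 1e-300))
                + np.log(np.maximum(jump[pos], 1e-300))
                + log_hr * x[event]
                - theta[event] * cumhaz[event]
            )
        )
    cens = ~event
    if np.any(cens):
        surv = baseline(time[cens]) ** theta[cens]
        ll += float(np.sum(np.log(np.maximum(1.0 - pi[cens] + pi[cens] * surv, 1e-300))))
    return ll


def _em(
    time: np.ndarray,
    event: np.ndarray,
    x: np.ndarray,
    max_iter: int,
    tol: float,
    track_loglik: bool = False,
):
    """Run the EM to convergence; returns the point fit as a dict.

    Initialization is deterministic: logistic part from the naive
    event-indicator fit, survival part from the unit-weight Cox fit,
    baseline at those values.
    """
    # --- initialization -----------------------------------------------------
    c, b_or, _, conv_l, _ = _logistic_nr(x, event.astype(float))
    if not conv_l or not np.isfinite(b_or):
        p_event = float(np.clip(event.mean(), 1e-6, 1 - 1e-6))
        c, b_or = float(logit(p_event)), 0.0
    b_hr, _, conv_c, _ = _cox_nr(time, event, x, np.ones(time.size))
    if not conv_c or not np.isfinite(b_hr):
        b_hr = 0.0
    w = np.ones(time.size)
    baseline = _baseline_core(time, event, x, w, b_hr)

    trace: list[float] = []
    converged = False
    ok = True
    it = 0
    se_or = float("nan")
    for it in range(1, max_iter + 1):
        w = _estep_core(time, event, x, c, b_or, b_hr, baseline)
        c_new, b_or_new, se_or, conv_l, _ = _logistic_nr(x, w)
        b_hr_new, se_hr, conv_c, _ = _cox_nr(time, event, x, w)
        if not (conv_l and conv_c):
            ok = False
            c_new = c_new if np.isfinite(c_new) else c
            b_or_new = b_or_new if np.isfinite(b_or_new) else b_or
            b_hr_new = b_hr_new if np.isfinite(b_hr_new) else b_hr
        baseline = _baseline_core(time, event, x, w, b_hr_new)
        delta = max(abs(c_new - c), abs(b_or_new - b_or), abs(b_hr_new - b_hr))
        c, b_or, b_hr = c_new, b_or_new, b_hr_new
        if track_loglik:
            trace.append(observed_loglik(time, event, x, c, b_or, b_hr, baseline))
        if not ok:
            break
        if delta < tol:
            converged = True
            break
    # SEs from the last inner fits are conditional on the weights; the
    # reported uncertainty comes from the bootstrap instead.
    return {
        "intercept": c,
        "log_or": b_or,
        "log_hr": b_hr,
        "se_or_naive": se_or,
        "baseline": baseline,
        "weights": w,
        "n_iter": it,
        "converged": converged and ok,
        "loglik_trace": trace,
    }


def fit_cure_cox(
    cohort: pd.DataFrame,
    max_iter: int = 500,
    tol: float = 1e-6,
    bootstrap_reps: int = 100,
    seed: int | None = None,
    track_loglik: bool = False,
) -> CureFit:
    """Fit the semiparametric mixture-cure Cox model by EM.

    Parameters
    ----------
    max_iter, tol
        EM stops when the largest absolute change of (logistic intercept,
        log-OR, log-HR) drops below ``tol``.
    bootstrap_reps
        Nonparametric bootstrap replicates for the standard errors (resample
        subjects with replacement, refit the EM; SE = SD of the converged
        replicate estimates).  0 skips the bootstrap (SEs become NaN).
    seed
        Governs the bootstrap resampling; the EM itself is deterministic.

    Raises
    ------
    IdentifiabilityError
        If the cohort has no censored subjects or no events: the cure
        fraction is then 0 or 1 and the logistic part is unidentified.
    """
    time = cohort["obs_time"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(dtype=bool)
    x = cohort["genotype"].to_numpy(dtype=float)
    n = time.size
    if not np.any(~event):
        raise IdentifiabilityError(
            "no censored subjects: empirical cure fraction is 0, logistic part unidentified"
        )
    if not np.any(event):
        raise IdentifiabilityError(
            "no events: empirical cure fraction is 1, model unidentified"
        )

    point = _em(time, event, x, max_iter, tol, track_loglik=track_loglik)

    boot_or: list[float] = []
    boot_hr: list[float] = []
    rng = np.random.default_rng(seed)
    for _ in range(bootstrap_reps):
        idx = rng.integers(0, n, size=n)
        tb, db, xb = time[idx], event[idx], x[idx]
        if not np.any(db) or not np.any(~db):
            continue
        fit_b = _em(tb, db, xb, max_iter, tol)
        if fit_b["converged"]:
            boot_or.append(fit_b["log_or"])
            boot_hr.append(fit_b["log_hr"])
    used = len(boot_or)
    se_or = float(np.std(boot_or, ddof=1)) if used >= 2 else float("nan")
    se_hr = float(np.std(boot_hr, ddof=1)) if used >= 2 else float("nan")

    logistic_part = FitResult(
        estimate=point["log_or"],
        se=se_or,
        p_value=_wald_p(point["log_or"], se_or),
        converged=point["converged"],
        n_iter=point["n_iter"],
        intercept=point["intercept"],
    )
    survival_part = FitResult(
        estimate=point["log_hr"],
        se=se_hr,
        p_value=_wald_p(point["log_hr"], se_hr),
        converged=point["converged"],
        n_iter=point["n_iter"],
    )
    return CureFit(
        logistic_part=logistic_part,
        survival_part=survival_part,
        baseline_survival=point["baseline"],
        em_iters=point["n_iter"],
        em_converged=point["converged"],
        bootstrap_reps_used=used,
        loglik_trace=point["loglik_trace"],
    )
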