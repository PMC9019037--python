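"""Kaplan-Meier estimation, log-rank testing and Cox regression.

All three are written against the same right-censored data layout:
a positive time, a binary event indicator (1 = event, 0 = censored), and
either a two-level group label (KM / log-rank) or a covariate matrix
(Cox).  Subjects censored exactly at an event time are counted at risk
for that time.  The Cox partial likelihood is maximized by
Newton-Raphson with Efron's tie correction (Breslow available by flag);
Wald 95% confidence intervals are exp(beta +/- 1.96 * SE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KmCurve",
    "LogRankResult",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
]


def _validate(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.shape != event.shape or time.ndim != 1:
        raise ValueError("time and event must be one-dimensional and equally long")
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("times must be finite and positive")
    if not np.all(np.isin(event, (0, 1))):
        raise ValueError("event must be binary (0 censored / 1 event)")
    return time, event.astype(int)


@dataclass
class KmCurve:
    """Product-limit survival step function."""

    event_times: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def evaluate(self, t: float | np.ndarray) -> np.ndarray:
        """S(t), right-continuous, S(0) = 1."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]


@dataclass
class LogRankResult:
    observed: pd.Series  # events per group
    expected: pd.Series
    chi_square: float
    p_value: float
    variance: float


@dataclass
class CoxResult:
    coefficients: pd.Series
    hazard_ratios: pd.Series
    standard_errors: pd.Series
    ci_lower: pd.Series  # on the hazard-ratio scale
    ci_upper: pd.Series
    converged: bool
    n_iterations: int
    log_likelihood: float


def km_estimate(time, event) -> KmCurve:
    """Kaplan-Meier product-limit estimator."""
    time, event = _validate(time, event)
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    n = t_s.size
    et = np.unique(t_s[e_s == 1])
    if et.size == 0:
        return KmCurve(np.array([]), np.array([]), np.array([], int), np.array([], int))
    left = np.searchsorted(t_s, et, side="left")
    at_risk = n - left
    ev_times = t_s[e_s == 1]
    d = np.searchsorted(ev_times, et, side="right") - np.searchsorted(ev_times, et, side="left")
    surv = np.cumprod(1.0 - d / at_risk)
    return KmCurve(et, surv, at_risk, d)


def logrank_test(time, event, group) -> LogRankResult:
    """Two-group log-rank test (O-E with hypergeometric variance, df = 1)."""
    time, event = _validate(time, event)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(levels)}")
    g1 = group == levels[0]

    order = np.argsort(time, kind="stable")
    t_s, e_s, g_s = time[order], event[order], g1[order].astype(float)
    n = t_s.size
    et = np.unique(t_s[e_s == 1])
    if et.size == 0:
        raise ValueError("no events observed")

    left = np.searchsorted(t_s, et, side="left")
    n_risk = n - left
    cum_g = np.concatenate([[0.0], np.cumsum(g_s)])
    n1_risk = cum_g[n] - cum_g[left]

    ev_mask = e_s == 1
    ev_times = t_s[ev_mask]
    ev_g = g_s[ev_mask]
    l2 = np.searchsorted(ev_times, et, side="left")
    r2 = np.searchsorted(ev_times, et, side="right")
    d = (r2 - l2).astype(float)
    cum_evg = np.concatenate([[0.0], np.cumsum(ev_g)])
    d1 = cum_evg[r2] - cum_evg[l2]

    frac = n1_risk / n_risk
    e1 = d * frac
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * frac * (1.0 - frac) * (n_risk - d) / (n_risk - 1.0)
    v = np.where(n_risk > 1, v, 0.0)

    o1, e1_tot, var = float(d1.sum()), float(e1.sum()), float(v.sum())
    total = float(d.sum())
    if var == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (o1 - e1_tot) ** 2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    observed = pd.Series({str(levels[0]): o1, str(levels[1]): total - o1})
    expected = pd.Series({str(levels[0]): e1_tot, str(levels[1]): total - e1_tot})
    return LogRankResult(observed, expected, float(chi2), p, var)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


def _cox_quantities(beta, t_s, e_s, x_s, ties):
    """Log partial likelihood, gradient and information at beta.

    Rows must be sorted by descending time so that risk sets are cumulative
    prefixes.
    """
    n, k = x_s.shape
    eta = x_s @ beta
    eta = eta - eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * x_s
    wxx = np.einsum("i,ij,il->ijl", w, x_s, x_s)

    s0 = np.cumsum(w)
    s1 = np.cumsum(wx, axis=0)
    s2 = np.cumsum(wxx, axis=0)

    loglik = 0.0
    grad = np.zeros(k)
    info = np.zeros((k, k))

    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        # rows i..j share a time; risk set = rows 0..j
        ev = np.arange(i, j + 1)[e_s[i : j + 1] == 1]
        d = ev.size
        if d > 0:
            s0_r, s1_r, s2_r = s0[j], s1[j], s2[j]
            sum_eta = float(eta[ev].sum())
            sum_x = x_s[ev].sum(axis=0)
            loglik += sum_eta
            grad += sum_x
            if ties == "efron" and d > 1:
                w_d = w[ev].sum()
                wx_d = wx[ev].sum(axis=0)
                wxx_d = wxx[ev].sum(axis=0)
                for l in range(d):
                    f = l / d
                    phi0 = s0_r - f * w_d
                    phi1 = s1_r - f * wx_d
                    phi2 = s2_r - f * wxx_d
                    loglik -= np.log(phi0)
                    grad -= phi1 / phi0
                    info += phi2 / phi0 - np.outer(phi1, phi1) / phi0**2
            else:  # breslow, or a single event
                loglik -= d * np.log(s0_r)
                grad -= d * s1_r / s0_r
                info += d * (s2_r / s0_r - np.outer(s1_r, s1_r) / s0_r**2)
        i = j + 1
    return loglik, grad, info


def _prepare_design(time, event, covariates):
    time, event = _validate(time, event)
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        x = covariates.to_numpy(float)
    elif isinstance(covariates, pd.Series):
        names = [str(covariates.name or "x0")]
        x = covariates.to_numpy(float)[:, None]
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{i}" for i in range(x.shape[1])]
    if x.shape[0] != time.size:
        raise ValueError("covariate rows must match the number of subjects")
    if event.sum() < 1:
        raise ValueError("Cox regression needs at least one event")
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < x.shape[1]:
        raise ValueError("covariate design matrix is rank deficient")
    order = np.argsort(-time, kind="stable")
    return time[order], event[order], x[order], names


def cox_fit(
    time,
    event,
    covariates,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Cox proportional-hazards fit by Newton-Raphson.

    Convergence when max |delta beta| < ``tol`` within ``max_iter``
    iterations.  A monotone likelihood (complete separation) surfaces as a
    non-convergence flag carrying the last iterate.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    t_s, e_s, x_s, names = _prepare_design(time, event, covariates)
    k = x_s.shape[1]
    beta = np.zeros(k)
    converged = False
    n_iter = 0
    loglik = -np.inf
    for n_iter in range(1, max_iter + 1):
        loglik, grad, info = _cox_quantities(beta, t_s, e_s, x_s, ties)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        # step-halving if the likelihood would diverge numerically
        beta_new = beta + step
        if np.any(np.abs(beta_new) > 500):
            break
        beta = beta_new
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    loglik, grad, info = _cox_quantities(beta, t_s, e_s, x_s, ties)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    z = stats.norm.ppf(0.975)
    coef = pd.Series(beta, index=names)
    se_s = pd.Series(se, index=names)
    return CoxResult(
        coefficients=coef,
        hazard_ratios=np.exp(coef),
        standard_errors=se_s,
        ci_lower=np.exp(coef - z * se_s),
        ci_upper=np.exp(coef + z * se_s),
        converged=converged,
        n_iterations=n_iter,
        log_likelihood=float(loglik),
    )


def cox_score_test(time, event, covariates, ties: str = "efron") -> tuple[float, float]:
    """Score (Rao) test of beta = 0: U(0)' I(0)^-1 U(0) ~ chi2(k).

    For a single binary covariate with no tied event times this statistic
    coincides with the log-rank chi-square.
    """
    t_s, e_s, x_s, _ = _prepare_design(time, event, covariates)
    _, grad, info = _cox_quantities(np.zeros(x_s.shape[1]), t_s, e_s, x_s, ties)
    chi2 = float(grad @ np.linalg.solve(info, grad))
    p = float(stats.chi2.sf(chi2, df=x_s.shape[1]))
    return chi2, p
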