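"""Kaplan-Meier estimation, log-rank comparison and Cox regression.

The Cox proportional-hazards model is fitted by Newton-Raphson on the Efron
tie-corrected partial likelihood (Breslow available by flag), with
step-halving whenever a Newton step would decrease the log partial
likelihood. Standard errors come from the inverse observed information;
per-covariate inference is Wald (z = beta/SE, 95% CI = exp(beta +/- 1.96 SE)).

Multivariate model building follows the clinical-table convention this
pipeline reproduces: every covariate is first fitted alone, and those with
univariate Wald p strictly below 0.200 enter a single joint fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KaplanMeierFit",
    "CoxFit",
    "km_fit",
    "logrank",
    "cox_fit",
    "cox_loglik",
    "cox_score",
    "select_by_entry_p",
    "multivariate_selection",
]

logger = logging.getLogger(__name__)


@dataclass
class KaplanMeierFit:
    """Product-limit survival curve: one row per distinct event time."""

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit."""

    covariates: List[str]
    coef: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_value: np.ndarray
    log_likelihood: float
    converged: bool
    n: int
    n_events: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hazard_ratio": self.hazard_ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_value,
            },
            index=self.covariates,
        )


def _check_surv(times, events) -> Tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.size != e.size:
        raise ValueError("times and events must align")
    if (t < 0).any():
        raise ValueError("times must be nonnegative")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0/1")
    return t, e


def km_fit(times: Sequence[float], events: Sequence[int]) -> KaplanMeierFit:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i), where d_i is
    the number of events and n_i the number at risk at t_i. Subjects
    censored at t leave the risk set after t (ties between censoring and
    events at the same time keep the censored subject at risk).
    """
    t, e = _check_surv(times, events)
    ev_times = np.unique(t[e == 1])
    at_risk = np.array([(t >= u).sum() for u in ev_times], dtype=int)
    d = np.array([((t == u) & (e == 1)).sum() for u in ev_times], dtype=int)
    surv = np.cumprod(1.0 - d / at_risk) if ev_times.size else np.empty(0)
    return KaplanMeierFit(ev_times, at_risk, d, surv)


def logrank(
    times: Sequence[float],
    events: Sequence[int],
    group: Sequence[int],
) -> Tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p on 1 df).

    At each distinct event time, the group-1 event count is compared with
    its hypergeometric expectation given the margins; the statistic is
    (sum(O1 - E1))^2 / sum(V).
    """
    t, e = _check_surv(times, events)
    g = np.asarray(group, dtype=int)
    if set(np.unique(g)) - {0, 1}:
        raise ValueError("group must be binary 0/1")
    if (g == 0).sum() == 0 or (g == 1).sum() == 0:
        raise ValueError("both groups must be non-empty")
    ev_times = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    for u in ev_times:
        at_risk = t >= u
        n = at_risk.sum()
        n1 = (at_risk & (g == 1)).sum()
        d = ((t == u) & (e == 1)).sum()
        d1 = ((t == u) & (e == 1) & (g == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(stats.chi2.sf(stat, df=1))


def _efron_terms(
    beta: np.ndarray,
    X: np.ndarray,
    t: np.ndarray,
    e: np.ndarray,
    ties: str,
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, score vector and information matrix.

    Risk-set sums are suffix cumulative sums over the time-sorted data, so
    one evaluation costs O(n p^2 + n_event_times p^2).
    """
    n, p = X.shape
    order = np.argsort(t, kind="stable")
    ts, es, Xs = t[order], e[order], X[order]
    eta = Xs @ beta
    # extended precision in the accumulations keeps the score resolvable
    # down to ~1e-9 even with thousands of subjects
    w = np.exp(eta).astype(np.longdouble)
    wx = w[:, None] * Xs
    wxx = w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :])
    # cum*[i] = sum over subjects with time >= ts[i]
    cw = np.cumsum(w[::-1])[::-1]
    cwx = np.cumsum(wx[::-1], axis=0)[::-1]
    cwxx = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = np.longdouble(0.0)
    score = np.zeros(p, dtype=np.longdouble)
    info = np.zeros((p, p), dtype=np.longdouble)
    ev_times = np.unique(ts[es == 1])
    for u in ev_times:
        first = np.searchsorted(ts, u, side="left")
        last = np.searchsorted(ts, u, side="right")
        dead = np.flatnonzero(es[first:last] == 1) + first
        d = dead.size
        s0_r = cw[first]
        s1_r = cwx[first]
        s2_r = cwxx[first]
        s0_d = w[dead].sum()
        s1_d = wx[dead].sum(axis=0)
        s2_d = wxx[dead].sum(axis=0)

        ll += eta[dead].sum()
        score += Xs[dead].sum(axis=0)
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            s0 = s0_r - frac * s0_d
            s1 = s1_r - frac * s1_d
            s2 = s2_r - frac * s2_d
            ll -= np.log(s0)
            score -= s1 / s0
            info += s2 / s0 - np.outer(s1, s1) / s0**2
    return float(ll), score.astype(float), info.astype(float)


def cox_loglik(beta, X, times, events, ties: str = "efron") -> float:
    """Efron (or Breslow) log partial likelihood at ``beta``."""
    t, e = _check_surv(times, events)
    return _efron_terms(np.asarray(beta, float), np.asarray(X, float), t, e, ties)[0]


def cox_score(beta, X, times, events, ties: str = "efron") -> np.ndarray:
    """Analytic score (gradient of the log partial likelihood) at ``beta``."""
    t, e = _check_surv(times, events)
    return _efron_terms(np.asarray(beta, float), np.asarray(X, float), t, e, ties)[1]


def cox_fit(
    X,
    times,
    events,
    covariate_names: Optional[Sequence[str]] = None,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-7,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Convergence when the largest score component falls below ``tol`` (or
    after ``max_iter`` iterations, in which case the fit is flagged
    unconverged with a warning — monotone partial likelihoods from perfect
    separation land here). Step-halving guards each Newton step.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    t, e = _check_surv(times, events)
    if e.sum() == 0:
        raise ValueError("no events: Cox model is unidentifiable")
    n, p = X.shape
    if covariate_names is None:
        covariate_names = [f"x{i + 1}" for i in range(p)]
    const = X.std(axis=0) == 0
    if const.any():
        bad = [covariate_names[i] for i in np.flatnonzero(const)]
        raise ValueError(f"constant covariate(s): {bad}")

    beta = np.zeros(p)
    ll, score, info = _efron_terms(beta, X, t, e, ties)
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            logger.warning("singular information matrix; stopping")
            break
        if np.max(np.abs(step)) < 1e-10:
            # stationary to machine precision even if the score criterion
            # is below floating-point resolution
            converged = True
            break
        # step-halving: never accept a step that lowers the likelihood
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, score_new, info_new = _efron_terms(cand, X, t, e, ties)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, score, info = cand, ll_new, score_new, info_new
    else:
        if np.max(np.abs(score)) < tol:
            converged = True
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    if converged and (np.abs(beta) > 15).any():
        # the score can vanish at arbitrarily large coefficients when the
        # partial likelihood is monotone (perfect separation)
        converged = False
    if not converged:
        logger.warning(
            "Cox fit did not converge (max |score| = %.3g, max |coef| = %.3g); "
            "possible monotone likelihood / perfect separation",
            float(np.max(np.abs(score))),
            float(np.max(np.abs(beta))),
        )
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        hr, lo, hi = np.exp(beta), np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
    return CoxFit(
        covariates=list(covariate_names),
        coef=beta,
        se=se,
        hazard_ratio=hr,
        ci_low=lo,
        ci_high=hi,
        p_value=pvals,
        log_likelihood=float(ll),
        converged=converged,
        n=n,
        n_events=int(e.sum()),
    )


def select_by_entry_p(p_values: Mapping[str, float], entry_p: float = 0.200) -> List[str]:
    """Covariates whose univariate p is strictly below the entry threshold.

    Input order is preserved so the joint model's covariate order is the
    table's.
    """
    return [name for name, p in p_values.items() if p < entry_p]


def multivariate_selection(
    data: pd.DataFrame,
    covariates: Sequence[str],
    time_col: str,
    event_col: str,
    entry_p: float = 0.200,
    ties: str = "efron",
) -> Tuple[Dict[str, CoxFit], Optional[CoxFit], List[str]]:
    """Univariate Cox fits, then a joint fit of covariates with p < entry_p.

    Returns (univariate fits by covariate, multivariate fit or None,
    selected covariate names). Selection is strict inequality; when nothing
    qualifies the multivariate fit is None (logged) and only the univariate
    results stand.
    """
    uni: Dict[str, CoxFit] = {}
    for cov in covariates:
        sub = data[[cov, time_col, event_col]].dropna()
        uni[cov] = cox_fit(
            sub[cov].to_numpy(dtype=float),
            sub[time_col].to_numpy(dtype=float),
            sub[event_col].to_numpy(dtype=int),
            covariate_names=[cov],
            ties=ties,
        )
    selected = select_by_entry_p(
        {c: float(uni[c].p_value[0]) for c in covariates}, entry_p
    )
    if not selected:
        logger.warning("no covariate passed the multivariate entry rule")
        return uni, None, []
    sub = data[list(selected) + [time_col, event_col]].dropna()
    multi = cox_fit(
        sub[list(selected)].to_numpy(dtype=float),
        sub[time_col].to_numpy(dtype=float),
        sub[event_col].to_numpy(dtype=int),
        covariate_names=list(selected),
        ties=ties,
    )
    return uni, multi, selected
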