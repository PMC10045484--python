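"""Prognostic stage: Cox risk score, median dichotomization, KM, log-rank.

The Cox proportional-hazards model is fit by Newton-Raphson on the Breslow
tie-corrected partial likelihood (Efron available behind a flag via the
same machinery).  The linear risk score is
``score_j = sum_g beta_g * z_gj`` over signature genes, where ``z`` is the
per-gene z-scored expression across the cohort (a flag disables the
z-scoring).  Cohorts are dichotomized at the median risk score (ties go
low), compared by Kaplan-Meier curves and the log-rank test, and ranked by
Harrell's concordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.utils import concordance_index
from scipy.stats import chi2

from .types import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "CoxModel",
    "RiskScore",
    "KMEstimate",
    "LogRankResult",
    "cox_fit",
    "cox_loglik",
    "risk_score",
    "dichotomize",
    "km_estimate",
    "logrank_test",
    "concordance",
]


@dataclass
class CoxModel:
    coef: dict
    loglik: float
    converged: bool
    n_events: int
    ties: str = "breslow"


@dataclass
class RiskScore:
    sample_id: str
    score: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError(f"non-finite risk score for {self.sample_id!r}")


@dataclass
class KMEstimate:
    times: np.ndarray           # distinct event times
    at_risk: np.ndarray         # n at risk just before each time
    events: np.ndarray          # events at each time
    survival: np.ndarray        # S(t) at each time

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
        return s


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    observed: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)


def _design(records, covariate_names):
    X = np.empty((len(records), len(covariate_names)))
    for i, r in enumerate(records):
        for j, c in enumerate(covariate_names):
            if c not in r.covariates:
                raise ValueError(f"sample {r.sample_id!r} is missing covariate {c!r}")
            X[i, j] = float(r.covariates[c])
    return X


def cox_loglik(beta: np.ndarray, times: np.ndarray, events: np.ndarray,
               X: np.ndarray, ties: str = "breslow") -> float:
    """Breslow (or Efron) tie-corrected Cox partial log-likelihood."""
    beta = np.asarray(beta, dtype=np.float64)
    eta = X @ beta
    theta = np.exp(eta)
    ll = 0.0
    for t in np.unique(times[events == 1]):
        risk = times >= t
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        ll += eta[dead].sum()
        if ties == "breslow":
            ll -= d * np.log(theta[risk].sum())
        elif ties == "efron":
            s_risk = theta[risk].sum()
            s_dead = theta[dead].sum()
            for l in range(d):
                ll -= np.log(s_risk - l / d * s_dead)
        else:
            raise ValueError(f"unknown ties method {ties!r}")
    return float(ll)


def cox_fit(records, covariate_names, ties: str = "breslow",
            tol: float = 1e-9, max_iter: int = 100) -> CoxModel:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Convergence: successive partial log-likelihoods differ by less than
    ``tol`` (or ``max_iter`` iterations).  Raises for zero-variance
    covariates (naming them) and for monotone likelihood / perfect
    separation once any ``|beta|`` exceeds 50.
    """
    covariate_names = list(covariate_names)
    if not covariate_names:
        raise ValueError("need at least one covariate")
    records = list(records)
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    X = _design(records, covariate_names)
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError("no events in the data; Cox model is not identifiable")
    if n_events < 10:
        log.warning("only %d events; coefficient estimates will be unstable", n_events)
    var = X.var(axis=0)
    for j, v in enumerate(var):
        if v == 0:
            raise ValueError(f"covariate {covariate_names[j]!r} has zero variance")

    k = len(covariate_names)
    beta = np.zeros(k)
    event_times = np.unique(times[events == 1])
    risk_masks = [times >= t for t in event_times]
    dead_masks = [(times == t) & (events == 1) for t in event_times]

    def loglik_grad_hess(b):
        eta = X @ b
        theta = np.exp(eta)
        ll = 0.0
        grad = np.zeros(k)
        hess = np.zeros((k, k))
        for risk, dead in zip(risk_masks, dead_masks):
            d = int(dead.sum())
            Xr = X[risk]
            th = theta[risk]
            if ties == "breslow":
                denoms = [th.sum()]
                sub = [0.0]
            elif ties == "efron":
                s_dead = theta[dead].sum()
                denoms = [th.sum() - l / d * s_dead for l in range(d)]
                sub = [l / d for l in range(d)]
            else:
                raise ValueError(f"unknown ties method {ties!r}")
            ll += eta[dead].sum()
            s1_full = Xr.T @ th
            s2_full = (Xr * th[:, None]).T @ Xr
            if ties == "efron":
                Xd = X[dead]
                thd = theta[dead]
                s1_dead = Xd.T @ thd
                s2_dead = (Xd * thd[:, None]).T @ Xd
            if ties == "breslow":
                s0 = denoms[0]
                s1 = s1_full
                s2 = s2_full
                ll -= d * np.log(s0)
                grad += X[dead].sum(axis=0) - d * s1 / s0
                hess -= d * (s2 / s0 - np.outer(s1, s1) / s0 ** 2)
            else:
                grad += X[dead].sum(axis=0)
                for s0, f in zip(denoms, sub):
                    s1 = s1_full - f * s1_dead
                    s2 = s2_full - f * s2_dead
                    ll -= np.log(s0)
                    grad -= s1 / s0
                    hess -= s2 / s0 - np.outer(s1, s1) / s0 ** 2
        return ll, grad, hess

    ll_old, grad, hess = loglik_grad_hess(beta)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as e:
            raise ValueError(f"singular information matrix: {e}") from e
        # step-halving keeps the likelihood non-decreasing
        factor = 1.0
        for _ in range(30):
            beta_new = beta + factor * step
            ll_new = cox_loglik(beta_new, times, events, X, ties=ties)
            if ll_new >= ll_old - 1e-14:
                break
            factor /= 2.0
        beta = beta_new
        if np.any(np.abs(beta) > 50):
            raise ValueError(
                "divergence guard: |beta| > 50 — monotone likelihood "
                "(perfect separation) suspected")
        if abs(ll_new - ll_old) < tol:
            ll_old = ll_new
            converged = True
            break
        ll_old = ll_new
        _, grad, hess = loglik_grad_hess(beta)
    if not converged:
        raise ValueError(f"Cox fit did not converge in {max_iter} iterations")
    return CoxModel(coef={c: float(b) for c, b in zip(covariate_names, beta)},
                    loglik=float(ll_old), converged=True, n_events=n_events, ties=ties)


def zscore_genes(m: ExpressionMatrix) -> np.ndarray:
    """Per-gene z-score across the cohort (population sd)."""
    mu = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        bad = [m.gene_ids[i] for i in np.flatnonzero(sd[:, 0] == 0)[:5]]
        raise ValueError(f"zero-variance genes cannot be z-scored: {bad}")
    return (m.values - mu) / sd


def risk_score(expr: ExpressionMatrix, model: CoxModel, zscore: bool = True) -> list:
    """Linear risk score ``sum_g beta_g * z_gj`` per sample.

    ``expr`` is genes x samples; model covariates must all be present as
    genes (missing ones are listed in the error).  By default expression is
    z-scored per gene across the cohort first.
    """
    genes = list(model.coef.keys())
    missing = [g for g in genes if g not in set(expr.gene_ids)]
    if missing:
        raise ValueError(f"model genes absent from matrix: {missing}")
    sub = expr.subset_genes(genes)
    values = zscore_genes(sub) if zscore else sub.values
    beta = np.array([model.coef[g] for g in genes])
    scores = beta @ values
    return [RiskScore(sample_id=s, score=float(v)) for s, v in zip(sub.obs_ids, scores)]


def dichotomize(scores) -> tuple:
    """Median split of risk scores into ``{"high", "low"}`` groups.

    Returns ``(labels, threshold)`` where ``labels`` maps sample_id to group;
    scores above the median are high, ties at the median go low.  All-equal
    scores raise.
    """
    scores = list(scores)
    if len(scores) < 2:
        raise ValueError("need >= 2 samples to dichotomize")
    vals = np.array([s.score for s in scores])
    if np.all(vals == vals[0]):
        raise ValueError("degenerate split: all risk scores identical "
                         "(are all coefficients zero?)")
    threshold = float(np.median(vals))
    labels = {s.sample_id: ("high" if s.score > threshold else "low") for s in scores}
    return labels, threshold


def km_estimate(records, group=None) -> KMEstimate:
    """Product-limit survival estimate (events precede censorings at ties)."""
    records = list(records)
    if group is not None:
        records = [r for r in records if group.get(r.sample_id) is not None]
    if not records:
        raise ValueError("no records for KM estimation")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    mask = tbl["observed"] > 0
    ev_times = tbl.index[mask].to_numpy(dtype=float)
    at_risk = tbl.loc[mask, "at_risk"].to_numpy(dtype=float)
    ev = tbl.loc[mask, "observed"].to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(ev_times).to_numpy(dtype=float)
    return KMEstimate(times=ev_times, at_risk=at_risk, events=ev, survival=surv)


def logrank_test(records, groups) -> LogRankResult:
    """Two-group log-rank test with hypergeometric variance at event times.

    ``groups`` maps sample_id to a group label; exactly two labels are
    required and each group must contain at least one record.
    """
    records = list(records)
    labels = sorted({groups[r.sample_id] for r in records if r.sample_id in groups})
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {labels}")
    times = np.array([r.time for r in records if r.sample_id in groups])
    events = np.array([r.event for r in records if r.sample_id in groups])
    gvec = np.array([groups[r.sample_id] for r in records if r.sample_id in groups])
    n_a = int((gvec == labels[0]).sum())
    n_b = int((gvec == labels[1]).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("each group must contain at least one record")
    is_a = gvec == labels[0]

    o_minus_e = 0.0
    var_sum = 0.0
    obs = {labels[0]: 0.0, labels[1]: 0.0}
    exp = {labels[0]: 0.0, labels[1]: 0.0}
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & is_a).sum()
        dead = (times == t) & (events == 1)
        d = dead.sum()
        d1 = (dead & is_a).sum()
        e1 = d * n1 / n
        obs[labels[0]] += float(d1)
        obs[labels[1]] += float(d - d1)
        exp[labels[0]] += float(e1)
        exp[labels[1]] += float(d - e1)
        o_minus_e += d1 - e1
        if n > 1:
            var_sum += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var_sum == 0:
        raise ValueError("log-rank variance is zero (no comparable event times)")
    chi_square = float(o_minus_e ** 2 / var_sum)
    p = float(chi2.sf(chi_square, df=1))
    return LogRankResult(chi_square=chi_square, p_value=p, observed=obs, expected=exp)


def concordance(records, scores) -> float:
    """Harrell's C: higher risk score should pair with shorter survival.

    Ties in score count 0.5; raises when no comparable pairs exist.
    """
    records = list(records)
    score_map = {s.sample_id: s.score for s in scores}
    missing = [r.sample_id for r in records if r.sample_id not in score_map]
    if missing:
        raise ValueError(f"records without scores: {missing[:5]}")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    pred = np.array([score_map[r.sample_id] for r in records])
    try:
        # lifelines' convention: higher prediction = longer survival
        return float(concordance_index(times, -pred, events))
    except ZeroDivisionError as e:
        raise ValueError("no comparable pairs for concordance") from e
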