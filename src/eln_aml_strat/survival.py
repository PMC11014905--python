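"""Survival statistics for comparing risk stratifications.

From-first-principles implementations of the procedures used to validate a
risk classification against censored time-to-event outcomes:

* Kaplan–Meier product-limit curves with Greenwood variance and log-log
  pointwise confidence intervals;
* reverse Kaplan–Meier median follow-up;
* the k-group log-rank test and its pairwise variant;
* Cox proportional-hazards regression (Newton–Raphson on the partial
  likelihood, Efron or Breslow tie handling, Wald intervals), with optional
  support for one binary time-dependent covariate defined by a per-subject
  state-entry time — which also yields the Mantel–Byar test as the score
  test of that covariate;
* censoring at an intervening event (e.g. transplant) for sensitivity
  analyses;
* Harrell's concordance index and a paired comparison of two scores with a
  leave-one-out jackknife standard error;
* the category-based net reclassification improvement (NRI) at a time
  horizon with censoring handled by cell-wise Kaplan–Meier estimates.

All estimators take a :class:`SurvData` (parallel arrays of times, event
indicators and optional covariates/group labels).  Times are in months.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SurvData",
    "SurvCurve",
    "CoxFit",
    "LogrankResult",
    "MantelByarResult",
    "CompareCResult",
    "NriResult",
    "ConvergenceError",
    "km_fit",
    "survival_at",
    "reverse_km_median_followup",
    "logrank_test",
    "cox_fit",
    "censor_at_event",
    "mantel_byar_test",
    "harrell_c",
    "compare_c",
    "nri_censored",
]

logger = logging.getLogger(__name__)

Z_95 = float(stats.norm.ppf(0.975))


class ConvergenceError(RuntimeError):
    """Partial-likelihood maximization failed (cap hit or monotone likelihood)."""


@dataclass(frozen=True)
class SurvData:
    """Censored survival data: one entry per subject.

    ``event`` is True for an observed event, False for right censoring.
    ``covariates`` maps names to real vectors; ``group`` holds optional
    per-subject labels for grouped comparisons.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: dict[str, np.ndarray] = field(default_factory=dict)
    group: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=bool)
        if time.ndim != 1 or time.shape != event.shape:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if time.size == 0:
            raise ValueError("at least one subject required")
        if not np.all(np.isfinite(time)) or np.any(time < 0):
            raise ValueError("times must be finite and >= 0")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)
        covs = {k: np.asarray(v, dtype=float) for k, v in self.covariates.items()}
        for k, v in covs.items():
            if v.shape != time.shape:
                raise ValueError(f"covariate {k!r} length mismatch")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"covariate {k!r} contains non-finite values")
        object.__setattr__(self, "covariates", covs)
        if self.group is not None:
            g = np.asarray(self.group)
            if g.shape != time.shape:
                raise ValueError("group length mismatch")
            object.__setattr__(self, "group", g)

    def __len__(self) -> int:
        return int(self.time.size)

    def subset(self, mask: np.ndarray) -> "SurvData":
        mask = np.asarray(mask, dtype=bool)
        return SurvData(
            time=self.time[mask],
            event=self.event[mask],
            covariates={k: v[mask] for k, v in self.covariates.items()},
            group=None if self.group is None else self.group[mask],
        )


@dataclass(frozen=True)
class SurvCurve:
    """Product-limit estimate: step function over the distinct event times."""

    times: np.ndarray          # distinct event times, increasing
    survival: np.ndarray       # S(t) just after each event time
    variance: np.ndarray       # Greenwood variance of S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    conf_level: float
    max_follow_up: float


@dataclass(frozen=True)
class CoxFit:
    """Proportional-hazards fit: coefficients on the log-hazard scale."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p: np.ndarray
    loglik: float
    loglik_null: float
    score_stat: float          # global score test at beta = 0
    score_p: float
    n: int
    n_events: int
    n_iter: int
    converged: bool
    ties: str


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p: float
    groups: tuple


@dataclass(frozen=True)
class MantelByarResult:
    """Score test of a binary time-dependent state plus the companion Cox fit."""

    statistic: float
    p: float
    cox: Optional[CoxFit]
    n_entered: int
    defined: bool


@dataclass(frozen=True)
class CompareCResult:
    c_a: float
    c_b: float
    delta: float        # C_b - C_a
    se: float
    p: float
    n: int


@dataclass(frozen=True)
class NriResult:
    """Category NRI at a horizon; total = event + nonevent components."""

    horizon: float
    event_component: float
    nonevent_component: float
    total: float
    ci_lower: float
    ci_upper: float
    n: int
    n_up: int
    n_down: int
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def _km_table(time: np.ndarray, event: np.ndarray):
    """Distinct event times with numbers at risk and event counts."""
    t = np.sort(time)
    event_times, d = np.unique(time[event], return_counts=True)
    n_at_risk = t.size - np.searchsorted(t, event_times, side="left")
    return event_times, n_at_risk.astype(float), d.astype(float)


def km_fit(data: SurvData, conf_level: float = 0.95) -> SurvCurve:
    """Kaplan–Meier product-limit estimator.

    Pointwise confidence intervals use the log(-log) transform, which keeps
    the bounds inside [0, 1]; the variance is Greenwood's formula.
    """
    times, n, d = _km_table(data.time, data.event)
    if times.size == 0:
        return SurvCurve(
            times=np.empty(0),
            survival=np.empty(0),
            variance=np.empty(0),
            ci_lower=np.empty(0),
            ci_upper=np.empty(0),
            n_at_risk=np.empty(0, dtype=int),
            n_events=np.empty(0, dtype=int),
            conf_level=conf_level,
            max_follow_up=float(data.time.max()),
        )
    surv = np.cumprod(1.0 - d / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(n > d, d / (n * (n - d)), np.inf)
        gw = np.cumsum(gw_terms)
        var = surv**2 * gw
        var = np.where(surv > 0, var, 0.0)

        z = stats.norm.ppf(0.5 + conf_level / 2.0)
        inner = surv > 0
        strictly = inner & (surv < 1)
        sigma = np.zeros_like(surv)
        sigma[strictly] = np.sqrt(gw[strictly]) / np.abs(np.log(surv[strictly]))
        lo = np.where(surv > 0, surv ** np.exp(z * sigma), 0.0)
        hi = np.where(surv > 0, surv ** np.exp(-z * sigma), 0.0)
        lo = np.where(surv >= 1, surv, lo)
        hi = np.where(surv >= 1, surv, hi)
    return SurvCurve(
        times=times,
        survival=surv,
        variance=var,
        ci_lower=lo,
        ci_upper=hi,
        n_at_risk=n.astype(int),
        n_events=d.astype(int),
        conf_level=conf_level,
        max_follow_up=float(data.time.max()),
    )


def survival_at(curve: SurvCurve, t: float) -> dict:
    """Evaluate the step function S(t) with its pointwise CI.

    Beyond the last follow-up time the last value is carried forward and the
    result is flagged as truncated.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    truncated = t > curve.max_follow_up
    idx = int(np.searchsorted(curve.times, t, side="right")) - 1
    if idx < 0:
        return {"t": t, "estimate": 1.0, "ci_lower": 1.0, "ci_upper": 1.0, "truncated": truncated}
    return {
        "t": t,
        "estimate": float(curve.survival[idx]),
        "ci_lower": float(curve.ci_lower[idx]),
        "ci_upper": float(curve.ci_upper[idx]),
        "truncated": bool(truncated),
    }


def reverse_km_median_followup(data: SurvData) -> dict:
    """Median follow-up by the reverse Kaplan–Meier method.

    The censoring indicator is inverted (censorings become the events) and
    the KM median of that distribution is returned.  When the median is not
    reached the value is ``None`` with ``reached`` False.
    """
    inverted = SurvData(time=data.time, event=~data.event)
    curve = km_fit(inverted)
    below = curve.survival <= 0.5
    if not below.any():
        return {"median_months": None, "reached": False}
    return {"median_months": float(curve.times[np.argmax(below)]), "reached": True}


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def _logrank_stat(data: SurvData, labels: np.ndarray, groups: Sequence) -> tuple[float, int]:
    k = len(groups)
    gidx = np.searchsorted(groups, labels)
    event_times = np.unique(data.time[data.event])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = data.time >= t
        n = float(at_risk.sum())
        dying = at_risk & data.event & (data.time == t)
        d = float(dying.sum())
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gidx[dying], minlength=k).astype(float)
        O += d_g
        E += d * n_g / n
        if n > 1:
            frac = n_g / n
            vt = d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
            V += vt
    u = (O - E)[:-1]
    Vm = V[:-1, :-1]
    try:
        stat = float(u @ np.linalg.solve(Vm, u))
    except np.linalg.LinAlgError:
        stat = float(u @ np.linalg.pinv(Vm) @ u)
    return stat, k - 1


def logrank_test(data: SurvData, pairwise: bool = False):
    """Log-rank test across the groups of ``data``.

    With ``pairwise=True`` returns one two-group test per group pair,
    unadjusted for multiplicity (adjust downstream if needed).
    """
    if data.group is None:
        raise ValueError("logrank_test requires group labels")
    groups = np.unique(data.group)
    if groups.size < 2:
        raise ValueError("at least two groups required")
    if pairwise:
        results = []
        for a, b in combinations(groups, 2):
            mask = (data.group == a) | (data.group == b)
            sub = data.subset(mask)
            stat, df = _logrank_stat(sub, sub.group, np.array([a, b]))
            results.append(
                LogrankResult(
                    statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)), groups=(a, b)
                )
            )
        return results
    stat, df = _logrank_stat(data, data.group, groups)
    return LogrankResult(
        statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)), groups=tuple(groups)
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def _cox_quantities(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str,
    td_entry: Optional[np.ndarray],
):
    """Partial log-likelihood, gradient and observed information.

    ``td_entry``, when given, appends one binary time-dependent covariate
    whose value for subject j at event time t is 1[td_entry_j <= t]
    (NaN entry = never enters the state).
    """
    n, p0 = X.shape
    p = p0 + (1 if td_entry is not None else 0)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for t in np.unique(time[event]):
        at_risk = time >= t
        if td_entry is None:
            Xt = X
        else:
            state = (td_entry <= t).astype(float)
            Xt = np.column_stack([X, state]) if p0 else state[:, None]
        xr = Xt[at_risk]
        r = np.exp(xr @ beta)
        s0 = r.sum()
        s1 = xr.T @ r
        s2 = (xr * r[:, None]).T @ xr
        dying = at_risk & event & (time == t)
        xd = Xt[dying]
        d = xd.shape[0]
        ll += float((xd @ beta).sum())
        if ties == "breslow":
            ll -= d * math.log(s0)
            m1 = s1 / s0
            grad += xd.sum(axis=0) - d * m1
            info += d * (s2 / s0 - np.outer(m1, m1))
        else:  # efron
            rd = np.exp(xd @ beta)
            sd0 = rd.sum()
            sd1 = xd.T @ rd
            sd2 = (xd * rd[:, None]).T @ xd
            grad += xd.sum(axis=0)
            for l in range(d):
                f = l / d
                den = s0 - f * sd0
                num1 = s1 - f * sd1
                num2 = s2 - f * sd2
                ll -= math.log(den)
                m1 = num1 / den
                grad -= m1
                info += num2 / den - np.outer(m1, m1)
    return ll, grad, info


def cox_fit(
    data: SurvData,
    covariates: Optional[Sequence[str]] = None,
    ties: str = "efron",
    td_entry: Optional[np.ndarray] = None,
    td_name: str = "td_state",
    max_iter: int = 100,
    tol: float = 1e-9,
    conf_level: float = 0.95,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    All requested covariates are entered jointly with no selection.  Efron
    tie handling is the default; Breslow is available for oracle comparisons.
    ``td_entry`` adds one binary time-dependent covariate (state entry times,
    NaN for subjects who never enter); its name is ``td_name``.

    Raises :class:`ConvergenceError` on iteration-cap overrun or a monotone
    likelihood (perfect separation), and :class:`ValueError` for constant
    covariates or data without events.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    names = tuple(covariates) if covariates is not None else tuple(data.covariates)
    X = (
        np.column_stack([data.covariates[c] for c in names])
        if names
        else np.empty((len(data), 0))
    )
    if td_entry is None and X.shape[1] == 0:
        raise ValueError("at least one covariate required")
    for j, c in enumerate(names):
        if np.ptp(X[:, j]) == 0.0:
            raise ValueError(f"covariate {c!r} is constant")
    if not data.event.any():
        raise ValueError("no events in the data")
    entry = None
    if td_entry is not None:
        entry = np.asarray(td_entry, dtype=float)
        if entry.shape != data.time.shape:
            raise ValueError("td_entry length mismatch")
        if np.any(entry[~np.isnan(entry)] < 0):
            raise ValueError("state entry times must be >= 0")
        entry = np.where(np.isnan(entry), np.inf, entry)
        if not np.isfinite(entry).any():
            raise ValueError("td_entry never enters the state for any subject")
        names = names + (td_name,)

    p = len(names)
    beta = np.zeros(p)
    ll, grad, info = _cox_quantities(beta, X, data.time, data.event, ties, entry)
    ll_null = ll
    # global score test at beta = 0
    try:
        score_stat = float(grad @ np.linalg.solve(info, grad))
    except np.linalg.LinAlgError:
        score_stat = float(grad @ np.linalg.pinv(info) @ grad)
    score_p = float(stats.chi2.sf(score_stat, p))

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # step-halving on overshoot
        new_beta = beta + step
        new = _cox_quantities(new_beta, X, data.time, data.event, ties, entry)
        halvings = 0
        while new[0] < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new = _cox_quantities(new_beta, X, data.time, data.event, ties, entry)
            halvings += 1
        beta = new_beta
        new_ll, grad, info = new
        if np.any(np.abs(beta) > 50):
            raise ConvergenceError(
                "monotone partial likelihood (perfect separation suspected); "
                f"coefficients diverged: {dict(zip(names, beta))}"
            )
        if abs(new_ll - ll) <= tol * (abs(ll) + tol):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if not converged:
        raise ConvergenceError(f"no convergence within {max_iter} iterations")
    if np.any(np.abs(beta) > 20):
        # likelihood saturates as |beta| -> inf under perfect separation
        raise ConvergenceError(
            "monotone partial likelihood (perfect separation suspected); "
            f"coefficients: {dict(zip(names, beta))}"
        )

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    hr = np.exp(beta)
    wald = beta / se
    return CoxFit(
        names=names,
        coef=beta,
        se=se,
        hr=hr,
        ci_lower=np.exp(beta - z * se),
        ci_upper=np.exp(beta + z * se),
        p=2.0 * stats.norm.sf(np.abs(wald)),
        loglik=float(ll),
        loglik_null=float(ll_null),
        score_stat=score_stat,
        score_p=score_p,
        n=len(data),
        n_events=int(data.event.sum()),
        n_iter=n_iter,
        converged=converged,
        ties=ties,
    )


# ---------------------------------------------------------------------------
# Intervening events
# ---------------------------------------------------------------------------

def censor_at_event(data: SurvData, intervening_time: np.ndarray) -> SurvData:
    """Censor each subject at an intervening event (NaN = none).

    A subject whose intervening time is at or before the observed time is
    censored there; a tie with the event time resolves to censored (the
    subject did reach the intervening event).  Never increases a time and
    never creates events.
    """
    it = np.asarray(intervening_time, dtype=float)
    if it.shape != data.time.shape:
        raise ValueError("intervening_time length mismatch")
    has = ~np.isnan(it)
    if np.any(it[has] > data.time[has]):
        raise ValueError("intervening_time exceeds observed time for some subject")
    time = np.where(has, it, data.time)
    event = np.where(has, False, data.event)
    return SurvData(time=time, event=event, covariates=dict(data.covariates), group=data.group)


def mantel_byar_test(
    data: SurvData, state_entry_time: np.ndarray, ties: str = "efron"
) -> MantelByarResult:
    """Mantel–Byar test for a time-dependent binary state (e.g. transplant).

    Subjects contribute person-time to the "without" state before their entry
    time and to the "with" state afterwards, avoiding immortal-time bias.
    The test statistic is the partial-likelihood score test of the
    time-dependent indicator at zero; the companion Cox fit estimates its
    hazard ratio.  When no subject ever enters the state the test is
    undefined and flagged.
    """
    entry = np.asarray(state_entry_time, dtype=float)
    if entry.shape != data.time.shape:
        raise ValueError("state_entry_time length mismatch")
    has = ~np.isnan(entry)
    if np.any(entry[has] > data.time[has]):
        raise ValueError("state entry after observed time")
    if not has.any():
        return MantelByarResult(
            statistic=float("nan"), p=float("nan"), cox=None, n_entered=0, defined=False
        )
    fit = cox_fit(SurvData(data.time, data.event), td_entry=entry, ties=ties)
    return MantelByarResult(
        statistic=fit.score_stat,
        p=fit.score_p,
        cox=fit,
        n_entered=int(has.sum()),
        defined=True,
    )


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def _concordance_matrices(score: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Pairwise comparable/concordance weights (higher score = higher risk)."""
    ti = time[:, None]
    tj = time[None, :]
    ei = event[:, None]
    ej = event[None, :]
    comparable = ((ti < tj) & ei) | ((ti == tj) & ei & ~ej)
    si = score[:, None]
    sj = score[None, :]
    weight = np.where(si > sj, 1.0, np.where(si == sj, 0.5, 0.0))
    return comparable, weight


def harrell_c(score: np.ndarray, data: SurvData) -> float:
    """Harrell's concordance index for a risk score under censoring.

    A pair is comparable when the ordering of the two event times is known;
    a tied score contributes 1/2.  Higher scores must indicate higher risk.
    """
    score = np.asarray(score, dtype=float)
    if score.shape != data.time.shape:
        raise ValueError("score length mismatch")
    comparable, weight = _concordance_matrices(score, data.time, data.event)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs under censoring")
    return float(weight[comparable].sum() / n_comp)


def compare_c(score_a: np.ndarray, score_b: np.ndarray, data: SurvData) -> CompareCResult:
    """Paired comparison of two risk scores on the same subjects.

    Reports dC = C_b - C_a with a leave-one-out jackknife standard error of
    the paired difference and a two-sided normal-approximation p-value.
    """
    score_a = np.asarray(score_a, dtype=float)
    score_b = np.asarray(score_b, dtype=float)
    n = len(data)
    if score_a.shape != data.time.shape or score_b.shape != data.time.shape:
        raise ValueError("score length mismatch")

    def loo_c(score):
        comparable, weight = _concordance_matrices(score, data.time, data.event)
        w = np.where(comparable, weight, 0.0)
        m = comparable.astype(float)
        W, M = w.sum(), m.sum()
        if M == 0:
            raise ValueError("no comparable pairs under censoring")
        w_i = w.sum(axis=0) + w.sum(axis=1)
        m_i = m.sum(axis=0) + m.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c_loo = (W - w_i) / (M - m_i)
        c_loo = np.where(M - m_i > 0, c_loo, W / M)
        return W / M, c_loo

    c_a, loo_a = loo_c(score_a)
    c_b, loo_b = loo_c(score_b)
    delta = c_b - c_a
    d_loo = loo_b - loo_a
    se = math.sqrt((n - 1) / n * float(np.sum((d_loo - d_loo.mean()) ** 2)))
    if se == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(delta) / se))
    return CompareCResult(c_a=float(c_a), c_b=float(c_b), delta=float(delta), se=se, p=p, n=n)


# ---------------------------------------------------------------------------
# Net reclassification improvement
# ---------------------------------------------------------------------------

def _km_event_prob(time: np.ndarray, event: np.ndarray, horizon: float) -> tuple[float, bool]:
    """KM estimate of P(event by horizon); flag when follow-up is shorter."""
    curve = km_fit(SurvData(time, event))
    est = survival_at(curve, horizon)
    return 1.0 - est["estimate"], bool(est["truncated"])


def _nri_point(
    old_rank: np.ndarray,
    new_rank: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float,
    restrict: bool,
    flags: Optional[list[str]] = None,
) -> tuple[float, float]:
    up = new_rank > old_rank
    down = new_rank < old_rank
    if restrict:
        keep = up | down
        if not keep.any():
            if flags is not None:
                flags.append("no_reclassified_subjects")
            return 0.0, 0.0
        up, down = up[keep], down[keep]
        time, event = time[keep], event[keep]
    n = time.size
    p_up = up.sum() / n
    p_down = down.sum() / n

    p_event_all, trunc = _km_event_prob(time, event, horizon)
    if flags is not None and trunc:
        flags.append("horizon_beyond_follow_up")
    ev_up = ev_down = 0.0
    if up.any():
        ev_up, _ = _km_event_prob(time[up], event[up], horizon)
    elif flags is not None:
        flags.append("empty_up_cell")
    if down.any():
        ev_down, _ = _km_event_prob(time[down], event[down], horizon)
    elif flags is not None:
        flags.append("empty_down_cell")

    if p_event_all <= 0.0:
        if flags is not None:
            flags.append("no_events_by_horizon")
        event_comp = 0.0
    else:
        event_comp = (p_up * ev_up - p_down * ev_down) / p_event_all
    p_nonevent_all = 1.0 - p_event_all
    if p_nonevent_all <= 0.0:
        if flags is not None:
            flags.append("no_nonevents_by_horizon")
        nonevent_comp = 0.0
    else:
        nonevent_comp = (p_down * (1.0 - ev_down) - p_up * (1.0 - ev_up)) / p_nonevent_all
    return event_comp, nonevent_comp


def nri_censored(
    groups_old: Sequence,
    groups_new: Sequence,
    data: SurvData,
    horizon: float,
    categories: Sequence = ("favorable", "intermediate", "adverse"),
    n_boot: int = 1000,
    seed: int = 0,
    restrict_to_reclassified: bool = False,
) -> NriResult:
    """Category-based NRI at a time horizon under censoring.

    Upward/downward movement is judged on the shared ordered category scale.
    Event probabilities by the horizon within the up-moved, down-moved and
    overall sets are estimated by Kaplan–Meier (robust to censoring); without
    censoring this reduces exactly to the closed-form category NRI computed
    from the 2x2 up/down x event/non-event counts.  The CI is a seeded
    percentile bootstrap over subjects.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    cats = list(categories)
    old_rank = np.array([cats.index(g) for g in groups_old])
    new_rank = np.array([cats.index(g) for g in groups_new])
    if old_rank.shape != data.time.shape or new_rank.shape != data.time.shape:
        raise ValueError("group assignments must match the data length")

    flags: list[str] = []
    ev, ne = _nri_point(
        old_rank, new_rank, data.time, data.event, horizon, restrict_to_reclassified, flags
    )
    total = ev + ne

    rng = np.random.default_rng(seed)
    n = len(data)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bev, bne = _nri_point(
            old_rank[idx],
            new_rank[idx],
            data.time[idx],
            data.event[idx],
            horizon,
            restrict_to_reclassified,
        )
        boots[b] = bev + bne
    lo, hi = np.percentile(boots, [2.5, 97.5])

    up = new_rank > old_rank
    down = new_rank < old_rank
    return NriResult(
        horizon=float(horizon),
        event_component=float(ev),
        nonevent_component=float(ne),
        total=float(total),
        ci_lower=float(lo),
        ci_upper=float(hi),
        n=n,
        n_up=int(up.sum()),
        n_down=int(down.sum()),
        flags=tuple(dict.fromkeys(flags)),
    )
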