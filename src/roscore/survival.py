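"""From-scratch survival statistics.

Kaplan-Meier product-limit estimation with Greenwood variance, the
unweighted log-rank test with hypergeometric variance, Cox proportional
hazards by Newton-Raphson (Efron or Breslow tie handling), the
censoring-aware survival median, Pearson correlation, and the
Mann-Whitney ROC AUC.

Conventions:
  * event = 1 means the event (death) was observed; 0 means right-censored.
  * censored observations at an event time count as at-risk at that time.
  * the survival median is the first event time with S(t) <= 1/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "CoxFit",
    "RocCurve",
    "km_estimate",
    "km_median",
    "logrank_test",
    "cox_fit",
    "pearson_r",
    "auc_mann_whitney",
    "ConstantCovariateError",
]

_Z975 = 1.959963984540054  # Phi^-1(0.975)


class ConstantCovariateError(ValueError):
    """A model covariate takes a single value and cannot be estimated."""


def _clean_surv(times, events):
    t = np.asarray(times, dtype=float).ravel()
    e = np.asarray(events).ravel()
    if t.size == 0:
        raise ValueError("need at least one observation")
    if t.size != e.size:
        raise ValueError(f"times ({t.size}) and events ({e.size}) differ in length")
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    e = e.astype(float)
    if not np.all(np.isin(e, (0.0, 1.0))):
        raise ValueError("events must be coded 0 (censored) / 1 (event)")
    return t, e.astype(int)


def _revcumsum(a, axis=0):
    return np.flip(np.cumsum(np.flip(a, axis=axis), axis=axis), axis=axis)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    """Product-limit estimate over the distinct event times.

    ``survival[i]`` is S(t) just after ``event_times[i]``; S = 1 before the
    first event time. ``greenwood_se`` is the Greenwood standard error of
    S at each event time (NaN once S reaches 0).
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    greenwood_se: np.ndarray
    n: int

    @property
    def median(self) -> float | None:
        """First event time with S(t) <= 1/2, or None if never reached."""
        hit = np.nonzero(self.survival <= 0.5 + 1e-12)[0]
        if hit.size == 0:
            return None
        return float(self.event_times[hit[0]])

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation of S at arbitrary times."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def to_dict(self) -> dict:
        return {
            "event_times": self.event_times.tolist(),
            "survival": self.survival.tolist(),
            "at_risk": self.at_risk.tolist(),
            "events": self.events.tolist(),
            "greenwood_se": self.greenwood_se.tolist(),
            "n": self.n,
            "median": self.median,
        }


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    All-censored input yields a curve identically 1 with no event times
    (median undefined); this is not an error.
    """
    t, e = _clean_surv(times, events)
    n = t.size
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    ut = np.unique(ts)
    at_risk = n - np.searchsorted(ts, ut, side="left")
    inv = np.searchsorted(ut, ts)
    d = np.bincount(inv[es == 1], minlength=ut.size)
    keep = d > 0
    ut, at_risk, d = ut[keep], at_risk[keep], d[keep]
    surv = np.cumprod(1.0 - d / at_risk)
    # Greenwood: var(S) = S^2 * sum d / (n (n - d)); undefined when S hits 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.nan)
        se = surv * np.sqrt(np.cumsum(terms))
    return SurvivalCurve(
        event_times=ut,
        survival=surv,
        at_risk=at_risk,
        events=d,
        greenwood_se=se,
        n=n,
    )


def km_median(curve: SurvivalCurve) -> float | None:
    """Censoring-aware median: smallest event time with S(t) <= 1/2."""
    return curve.median


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p: float
    groups: list
    observed: np.ndarray
    expected: np.ndarray

    def to_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "p": self.p,
            "groups": [str(g) for g in self.groups],
            "observed": self.observed.tolist(),
            "expected": self.expected.tolist(),
        }


def logrank_test(times, events, group_labels) -> LogRankResult:
    """Unweighted log-rank test across two or more groups.

    Observed-minus-expected event counts accumulated over the distinct
    event times, with the hypergeometric covariance; the statistic is the
    quadratic form over G-1 groups, referred to chi-square(G-1).
    """
    t, e = _clean_surv(times, events)
    g = np.asarray(group_labels).ravel()
    if g.size != t.size:
        raise ValueError("group_labels must match times in length")
    labels, gi = np.unique(g, return_inverse=True)
    G = labels.size
    if G < 2:
        raise ValueError("log-rank test needs at least two groups")

    order = np.argsort(t, kind="stable")
    ts, es, gs = t[order], e[order], gi[order]
    ut = np.unique(ts)
    inv = np.searchsorted(ut, ts)
    m = ut.size

    onehot = np.zeros((ts.size, G))
    onehot[np.arange(ts.size), gs] = 1.0
    n_at_risk = _revcumsum(onehot)[np.searchsorted(ts, ut, side="left")]  # (m, G)
    d_jg = np.zeros((m, G))
    np.add.at(d_jg, (inv[es == 1], gs[es == 1]), 1.0)

    has_event = d_jg.sum(axis=1) > 0
    Nj = n_at_risk.sum(axis=1)
    Dj = d_jg.sum(axis=1)
    P = n_at_risk / Nj[:, None]
    expected = Dj[:, None] * P

    # hypergeometric variance factor; zero when only one subject remains
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(Nj > 1, Dj * (Nj - Dj) / (Nj - 1), 0.0)
    c = np.where(has_event, c, 0.0)

    O = d_jg.sum(axis=0)
    E = expected[has_event].sum(axis=0)
    V = np.diag((c[:, None] * P).sum(axis=0)) - np.einsum("j,jg,jh->gh", c, P, P)

    U = (O - E)[: G - 1]
    Vr = V[: G - 1, : G - 1]
    # pinv guards the degenerate no-variance case (e.g. a single event time)
    chi2 = float(U @ np.linalg.pinv(Vr) @ U)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, G - 1))
    return LogRankResult(
        chi_square=chi2,
        df=G - 1,
        p=p,
        groups=list(labels),
        observed=O,
        expected=E,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """Partial-likelihood fit; one row per covariate.

    ``ci_low``/``ci_high`` are Wald limits exp(beta +/- 1.96 se);
    ``score_chi2`` is the score test statistic at beta = 0.
    """

    names: list
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    loglik: float
    loglik_null: float
    score_chi2: float
    converged: bool
    ties: str
    n: int
    n_events: int
    warnings: list = field(default_factory=list)

    def row(self, name: str) -> dict:
        i = self.names.index(name)
        return {
            "name": name,
            "coef": float(self.coef[i]),
            "se": float(self.se[i]),
            "hr": float(self.hr[i]),
            "ci_low": float(self.ci_low[i]),
            "ci_high": float(self.ci_high[i]),
            "p": float(self.p[i]),
        }

    def to_dict(self) -> dict:
        return {
            "terms": [self.row(nm) for nm in self.names],
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "score_chi2": self.score_chi2,
            "converged": self.converged,
            "ties": self.ties,
            "n": self.n,
            "n_events": self.n_events,
            "warnings": list(self.warnings),
        }


def cox_fit(
    times,
    events,
    covariates,
    names=None,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Cox proportional-hazards regression.

    Newton-Raphson on the log partial likelihood starting from beta = 0,
    with step-halving whenever a step would decrease the likelihood.
    Tied event times are handled by the Efron correction by default
    (``ties="breslow"`` for the simpler approximation).

    Raises :class:`ConstantCovariateError` for a covariate with no
    variation. A fit that fails to converge within ``max_iter`` iterations
    (monotone likelihood / perfect separation) is returned with
    ``converged=False`` and a warning, not raised.
    """
    t, e = _clean_surv(times, events)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n != t.size:
        raise ValueError("covariate rows must match times")
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite (complete cases only)")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than covariates ({p})")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method: {ties!r}")
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    names = list(names)
    if len(names) != p:
        raise ValueError("names length must match covariate count")
    for j in range(p):
        if np.ptp(X[:, j]) == 0.0:
            raise ConstantCovariateError(f"covariate {names[j]!r} is constant")
    n_events = int(e.sum())
    if n_events == 0:
        raise ValueError("no events observed; partial likelihood is undefined")

    xbar = X.mean(axis=0)
    order = np.argsort(t, kind="stable")
    ts = t[order]
    ds = e[order].astype(bool)
    Xs = (X - xbar)[order]

    ut, first = np.unique(ts, return_index=True)
    inv = np.searchsorted(ut, ts)
    g_ev = inv[ds]
    d_all = np.bincount(g_ev, minlength=ut.size)
    J = np.nonzero(d_all)[0]
    dj = d_all[J]
    total = int(dj.sum())
    reps = dj
    offs = np.repeat(np.cumsum(dj) - dj, dj)
    frac = (np.arange(total) - offs) / np.repeat(dj, dj).astype(float)
    if ties == "breslow":
        frac = np.zeros(total)
    fJ = first[J]
    Xev = Xs[ds]
    sum_x_ev = Xev.sum(axis=0)
    # map each event to its position among event times (for bincounts)
    ev_pos = np.searchsorted(J, g_ev)

    def quantities(beta):
        eta = Xs @ beta
        eta = eta - eta.max()  # shift-invariant partial likelihood
        w = np.exp(eta)
        S0 = _revcumsum(w)[fJ]
        S1 = _revcumsum(w[:, None] * Xs)[fJ]
        S2 = _revcumsum((w[:, None] * Xs)[:, :, None] * Xs[:, None, :])[fJ]
        wev = w[ds]
        s0D = np.bincount(ev_pos, weights=wev, minlength=J.size)
        s1D = np.empty((J.size, p))
        s2D = np.empty((J.size, p, p))
        for a in range(p):
            s1D[:, a] = np.bincount(ev_pos, weights=wev * Xev[:, a], minlength=J.size)
            for b in range(a, p):
                v = np.bincount(ev_pos, weights=wev * Xev[:, a] * Xev[:, b], minlength=J.size)
                s2D[:, a, b] = v
                s2D[:, b, a] = v
        R0 = np.repeat(S0, reps) - frac * np.repeat(s0D, reps)
        R1 = np.repeat(S1, reps, axis=0) - frac[:, None] * np.repeat(s1D, reps, axis=0)
        R2 = np.repeat(S2, reps, axis=0) - frac[:, None, None] * np.repeat(s2D, reps, axis=0)
        mu = R1 / R0[:, None]
        ll = float(eta[ds].sum() - np.log(R0).sum())
        grad = sum_x_ev - mu.sum(axis=0)
        info = (R2 / R0[:, None, None]).sum(axis=0) - mu.T @ mu
        return ll, grad, info

    beta = np.zeros(p)
    ll, grad, info = quantities(beta)
    ll_null = ll
    try:
        score_chi2 = float(grad @ np.linalg.solve(info, grad))
    except np.linalg.LinAlgError:
        score_chi2 = float("nan")
    converged = False
    warn_msgs = []
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            warn_msgs.append("singular information matrix; stopping early")
            break
        lam = 1.0
        for _ in range(30):
            ll_new, grad_new, info_new = quantities(beta + lam * step)
            if ll_new >= ll - 1e-12:
                break
            lam /= 2.0
        beta = beta + lam * step
        delta = float(np.max(np.abs(lam * step)))
        ll, grad, info = ll_new, grad_new, info_new
        if delta < tol:
            converged = True
            break
    if not converged:
        msg = "Cox fit did not converge (possible monotone likelihood / separation)"
        warn_msgs.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(
        names=names,
        coef=beta,
        se=se,
        hr=np.exp(beta),
        ci_low=np.exp(beta - _Z975 * se),
        ci_high=np.exp(beta + _Z975 * se),
        p=pvals,
        loglik=ll,
        loglik_null=ll_null,
        score_chi2=score_chi2,
        converged=converged,
        ties=ties,
        n=n,
        n_events=n_events,
        warnings=warn_msgs,
    )


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(tstat), n - 2))
    return r, p


# ---------------------------------------------------------------------------
# Mann-Whitney AUC / ROC
# ---------------------------------------------------------------------------


@dataclass
class RocCurve:
    """ROC curve for a score oriented so that higher predicts the positive class.

    ``auc`` is the Mann-Whitney concordance probability
    P(score_pos > score_neg) + 0.5 P(tie), computed via midranks.
    Operating points are one per distinct threshold (predict positive when
    score >= threshold), plus the trivial (sens 0, spec 1) point.
    """

    auc: float
    sensitivity: np.ndarray
    specificity: np.ndarray
    thresholds: np.ndarray
    positive_class: str = "1"
    n_positive: int = 0
    n_negative: int = 0

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
            "positive_class": self.positive_class,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }


def auc_mann_whitney(score, label, positive_class: str = "1") -> RocCurve:
    """AUC and operating points for binary labels (1 = positive class)."""
    s = np.asarray(score, dtype=float).ravel()
    y = np.asarray(label).ravel().astype(float)
    if s.size != y.size:
        raise ValueError("score and label must be paired")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be 0/1")
    pos = y == 1.0
    n_pos = int(pos.sum())
    n_neg = int(s.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    ranks = stats.rankdata(s)  # midranks
    auc = float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))

    thr = np.unique(s)[::-1]
    idx = np.argsort(-s, kind="stable")
    y_sorted = y[idx]
    s_sorted = s[idx]
    # cumulative counts at each distinct threshold (>= threshold is positive call)
    last_of_thr = np.searchsorted(-s_sorted, -thr, side="right") - 1
    tp = np.cumsum(y_sorted)[last_of_thr]
    fp = np.cumsum(1.0 - y_sorted)[last_of_thr]
    sens = np.concatenate([[0.0], tp / n_pos])
    spec = np.concatenate([[1.0], 1.0 - fp / n_neg])
    return RocCurve(
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        thresholds=np.concatenate([[np.inf], thr]),
        positive_class=positive_class,
        n_positive=n_pos,
        n_negative=n_neg,
    )
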