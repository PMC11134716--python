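"""Survival and rank statistics used throughout the pipeline.

Implements the Kaplan-Meier product-limit estimator, univariable Cox
regression for a binary covariate (Efron tie correction, Newton-Raphson),
the two-group log-rank test and the tie-corrected Kruskal-Wallis test.

The Cox routine exploits the binary covariate: at every distinct event time
the partial-likelihood terms depend only on four counts (at-risk and event
counts per group), so the score and information are closed forms and the
whole fit is a handful of vectorized Newton steps.  Samples censored at an
event time are kept in the risk set for that time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import ValidationError

logger = logging.getLogger("sahr")

#: |beta| beyond this is treated as a monotone-likelihood (non-identified) fit
BETA_BOUND = float(np.log(50.0))


class MonotoneLikelihoodWarning(UserWarning):
    """The Cox partial likelihood has no finite maximizer; HR was capped."""


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KaplanMeierFit:
    """Product-limit estimate: survival drops at each distinct event time."""

    event_times: np.ndarray   # sorted distinct times with >= 1 event
    survival: np.ndarray      # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def evaluate(self, t: float | np.ndarray) -> np.ndarray:
        """Step-function value S(t); S = 1 before the first event."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        padded = np.concatenate([[1.0], self.survival])
        return padded[idx]


def km_estimate(times, events) -> KaplanMeierFit:
    """Kaplan-Meier product-limit estimator.

    ``times`` non-negative, ``events`` 1 for an observed event and 0 for
    censoring.  Censorings tied with an event time count as at risk for
    that event.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValidationError("km_estimate: empty input")
    _check_surv(times, events)
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order].astype(int)
    uniq = np.unique(t[e == 1])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    n = len(t)
    for tau in uniq:
        r = int(np.sum(t >= tau))
        d = int(np.sum((t == tau) & (e == 1)))
        s *= 1.0 - d / r
        surv.append(s)
        at_risk.append(r)
        n_ev.append(d)
    return KaplanMeierFit(
        event_times=uniq,
        survival=np.asarray(surv),
        n_at_risk=np.asarray(at_risk),
        n_events=np.asarray(n_ev),
    )


def _check_surv(times, events) -> None:
    if np.any(np.asarray(times, dtype=float) < 0):
        raise ValidationError("survival times must be non-negative")
    ev = np.asarray(events)
    if not np.isin(ev, [0, 1]).all():
        raise ValidationError("event indicators must be 0 or 1")


# ---------------------------------------------------------------------------
# Cox regression, binary covariate
# ---------------------------------------------------------------------------


@dataclass
class SurvivalFit:
    """Result of a two-group survival comparison.

    ``hr`` is exp(beta) for group 1 vs group 0.  ``flagged`` marks a
    monotone-likelihood fit whose coefficient was capped at ``log(50)``;
    such hazard ratios must never be consumed without their flag.
    """

    beta: float
    hr: float
    se: float
    hr_ci: tuple[float, float]
    wald_p: float
    logrank_p: float
    n_per_group: tuple[int, int]
    n_events: int
    flagged: bool = False
    km_by_group: dict | None = None


def _efron_tables(times, events, group):
    """Per-distinct-event-time counts (d, d1, n0, n1)."""
    order = np.argsort(times, kind="stable")
    t, e, x = times[order], events[order].astype(int), group[order].astype(int)
    ev_times = np.unique(t[e == 1])
    d = np.zeros(len(ev_times))
    d1 = np.zeros(len(ev_times))
    n0 = np.zeros(len(ev_times))
    n1 = np.zeros(len(ev_times))
    for j, tau in enumerate(ev_times):
        ev_here = (t == tau) & (e == 1)
        at_risk = t >= tau
        d[j] = ev_here.sum()
        d1[j] = (ev_here & (x == 1)).sum()
        n1[j] = (at_risk & (x == 1)).sum()
        n0[j] = (at_risk & (x == 0)).sum()
    return d, d1, n0, n1


def _efron_expand(d, d1, n0, n1):
    """Expand the tie sums: one row per (event time j, within-tie index l)."""
    d_int = d.astype(int)
    reps = np.repeat(np.arange(len(d)), d_int)
    l = np.concatenate([np.arange(k) for k in d_int]) if len(d_int) else np.array([])
    frac = l / d[reps]
    return reps, frac


def efron_loglik(beta: float, d, d1, n0, n1) -> float:
    """Efron-corrected Cox partial log-likelihood for a binary covariate."""
    reps, frac = _efron_expand(d, d1, n0, n1)
    eb = np.exp(beta)
    s0 = n0[reps] + n1[reps] * eb - frac * ((d - d1)[reps] + d1[reps] * eb)
    return float(np.sum(beta * d1) - np.sum(np.log(s0)))


def _efron_score_info(beta: float, d, d1, n0, n1):
    reps, frac = _efron_expand(d, d1, n0, n1)
    eb = np.exp(beta)
    a = (n1[reps] - frac * d1[reps]) * eb          # weighted sum of x*exp(bx)
    b = n0[reps] + n1[reps] * eb - frac * ((d - d1)[reps] + d1[reps] * eb)
    mu = a / b
    score = float(np.sum(d1) - np.sum(mu))
    info = float(np.sum(mu - mu**2))               # x binary: S2 == S1
    return score, info


def cox_binary(times, events, group, compute_km: bool = False) -> SurvivalFit:
    """Univariable Cox regression for a binary group indicator.

    Newton-Raphson from beta=0 with step-halving, Efron tie correction,
    convergence at |dbeta| < 1e-8 (max 50 iterations).  A coefficient
    escaping ``(-log 50, log 50)`` marks a monotone likelihood: the result
    is returned capped and ``flagged`` with a warning rather than silently.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    group = np.asarray(group)
    _check_surv(times, events)
    if not np.isin(group, [0, 1]).all():
        raise ValidationError("group labels must be 0 or 1")
    n1 = int(np.sum(group == 1))
    n0 = int(np.sum(group == 0))
    if n0 == 0 or n1 == 0:
        raise ValidationError("both groups must be nonempty")
    n_events = int(np.sum(events))
    if n_events == 0:
        raise ValidationError("no events observed")

    d, d1, g0, g1 = _efron_tables(times, events, group)
    beta = 0.0
    ll = efron_loglik(beta, d, d1, g0, g1)
    flagged = False
    for _ in range(50):
        score, info = _efron_score_info(beta, d, d1, g0, g1)
        if info <= 0:
            flagged = True
            break
        step = score / info
        # step-halving on likelihood decrease
        new_beta = beta + step
        new_ll = efron_loglik(new_beta, d, d1, g0, g1)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll = efron_loglik(new_beta, d, d1, g0, g1)
            halvings += 1
        beta, ll = new_beta, new_ll
        if abs(beta) > BETA_BOUND:
            flagged = True
            break
        if abs(step) < 1e-8:
            break

    if flagged:
        beta = float(np.clip(beta, -BETA_BOUND, BETA_BOUND))
        warnings.warn(
            "monotone partial likelihood: no finite hazard-ratio estimate; "
            f"coefficient capped at ±log(50) (n={n0}+{n1}, events={n_events})",
            MonotoneLikelihoodWarning,
            stacklevel=2,
        )
    _, info = _efron_score_info(beta, d, d1, g0, g1)
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    wald_p = float(2.0 * sps.norm.sf(abs(z)))
    ci = (float(np.exp(beta - 1.959963984540054 * se)),
          float(np.exp(beta + 1.959963984540054 * se)))
    lr_p = logrank(times, events, group)

    km = None
    if compute_km:
        km = {
            0: km_estimate(times[group == 0], events[group == 0]),
            1: km_estimate(times[group == 1], events[group == 1]),
        }
    return SurvivalFit(
        beta=float(beta),
        hr=float(np.exp(beta)),
        se=se,
        hr_ci=ci,
        wald_p=wald_p,
        logrank_p=lr_p,
        n_per_group=(n0, n1),
        n_events=n_events,
        flagged=flagged,
        km_by_group=km,
    )


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


def logrank(times, events, group) -> float:
    """Two-group log-rank test p-value (chi-squared, 1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    group = np.asarray(group)
    _check_surv(times, events)
    if np.sum(group == 0) == 0 or np.sum(group == 1) == 0:
        raise ValidationError("both groups must be nonempty")
    d, d1, n0, n1 = _efron_tables(times, events, group)
    if len(d) == 0:
        raise ValidationError("no events observed")
    n = n0 + n1
    o_minus_e = np.sum(d1 - d * n1 / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d * (n1 / n) * (n0 / n) * (n - d) / np.where(n > 1, n - 1, np.inf)
    var = float(np.sum(v))
    if var <= 0:
        return 1.0
    chi2 = o_minus_e**2 / var
    return float(sps.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------


def kruskal_wallis(values, group_labels) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H test across k >= 2 groups.

    Returns ``(H, p)`` with p from chi-squared with k-1 degrees of freedom.
    Degenerate all-tied data yields H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if values.shape != labels.shape:
        raise ValidationError("values and group labels must align")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValidationError("kruskal_wallis needs at least 2 groups")
    sizes = np.array([np.sum(labels == g) for g in groups])
    if (sizes == 0).any():
        raise ValidationError("every group must be nonempty")
    n = len(values)
    ranks = sps.rankdata(values)
    h = 12.0 / (n * (n + 1)) * sum(
        sz * (ranks[labels == g].mean() - (n + 1) / 2.0) ** 2
        for g, sz in zip(groups, sizes)
    )
    # tie correction
    _, tie_counts = np.unique(values, return_counts=True)
    correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n**3 - n)
    if correction <= 0:
        return 0.0, 1.0  # all observations identical
    h /= correction
    p = float(sps.chi2.sf(h, df=len(groups) - 1))
    return float(h), p
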