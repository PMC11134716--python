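"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive every statistic from its textbook
definition (plain Python loops, no reuse of package internals) so that
agreement with the vectorized implementations is an actual cross-check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from sahr import (
    SimulationConfig,
    median_of_ratios_normalize,
    simulate_cohort,
    test_differential,
)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def brute_km(times, events):
    """Product-limit estimator straight from the definition."""
    times = list(map(float, times))
    events = list(map(int, events))
    ev_times = sorted({t for t, e in zip(times, events) if e == 1})
    surv = []
    s = 1.0
    for tau in ev_times:
        at_risk = sum(1 for t in times if t >= tau)
        deaths = sum(1 for t, e in zip(times, events) if t == tau and e == 1)
        s *= 1.0 - deaths / at_risk
        surv.append(s)
    return ev_times, surv


def brute_efron_loglik(beta, times, events, group):
    """Efron partial log-likelihood, nested-loop definition."""
    ll = 0.0
    ev_times = sorted({t for t, e in zip(times, events) if e == 1})
    for tau in ev_times:
        tied = [x for t, e, x in zip(times, events, group) if t == tau and e == 1]
        risk = [x for t, x in zip(times, group) if t >= tau]
        d = len(tied)
        sum_risk = sum(math.exp(beta * x) for x in risk)
        sum_tied = sum(math.exp(beta * x) for x in tied)
        ll += beta * sum(tied)
        for el in range(d):
            ll -= math.log(sum_risk - el / d * sum_tied)
    return ll


def brute_maximize_efron(times, events, group, lo=-10.0, hi=10.0, tol=1e-10):
    """Golden-section maximization of the brute-force Efron likelihood."""
    phi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - phi * (b - a)
    d = a + phi * (b - a)
    fc = brute_efron_loglik(c, times, events, group)
    fd = brute_efron_loglik(d, times, events, group)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = brute_efron_loglik(c, times, events, group)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = brute_efron_loglik(d, times, events, group)
    return (a + b) / 2.0


def brute_bh(p_values):
    """Step-up BH from the definition: adj_(i) = min_{j>=i} m p_(j) / j."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank, i in enumerate(order, start=1):
        adj[i] = min(min(m * p[j] / (order.index(j) + 1) for j in order[rank - 1:]), 1.0)
    return adj


def random_survival_instance(rng, n_max=8, with_ties=True):
    """A tiny random censored two-group sample (may include heavy ties)."""
    n = int(rng.integers(4, n_max + 1))
    if with_ties:
        times = rng.integers(1, 5, n).astype(float)
    else:
        times = rng.exponential(1.0, n)
    events = rng.integers(0, 2, n)
    group = rng.integers(0, 2, n)
    return times, events, group


# ---------------------------------------------------------------------------
# cohort fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with planted effects, normalized, with DEG table."""
    cfg = SimulationConfig(
        n_genes=200, n_tumor=160, n_normal=40, planted_hr=3.0, seed=42
    )
    expr, clinical, truth = simulate_cohort(cfg)
    expr = median_of_ratios_normalize(expr)
    deg = test_differential(expr, clinical.data.loc[expr.sample_ids, "condition"])
    return expr, clinical, truth, deg


@pytest.fixture()
def tiny_expression_tsv(tmp_path):
    path = tmp_path / "counts.tsv"
    path.write_text(
        "gene_id\tS1\tS2\n"
        "GA\t10\t20\n"
        "GB\t0\t5\n"
        "GC\t7\t7\n"
    )
    return path


@pytest.fixture()
def tiny_clinical_tsv(tmp_path):
    path = tmp_path / "clinical.tsv"
    path.write_text(
        "sample_id\tcondition\tos_time\tos_event\tstage\tsplit\n"
        "S1\ttumor\t420\t1\tStage IIA\ttrain\n"
        "S2\tnormal\t\t\t\t\n"
    )
    return path
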