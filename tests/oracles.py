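"""Independent brute-force oracles used by the test-suite.

Everything here recomputes quantities from first principles (definitions,
enumeration, grid search) without touching the implementation or the
libraries standing behind it, so that agreement is evidence rather than
tautology.
"""

from __future__ import annotations

import math

import numpy as np


# -- Benjamini–Hochberg step-up ---------------------------------------------

def bh_oracle(pvalues):
    """Literal step-up definition: sort, multiply by m/i, enforce
    monotonicity from the largest p downward, clip at 1, unsort."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = np.inf
    for rank_from_top in range(m - 1, -1, -1):
        i = rank_from_top + 1
        idx = order[rank_from_top]
        running_min = min(running_min, p[idx] * m / i)
        adj[idx] = min(running_min, 1.0)
    return adj


# -- unweighted average linkage ---------------------------------------------

def average_linkage_oracle(d: np.ndarray):
    """Agglomerate by rescanning all pairwise unweighted average distances
    at every step.  Returns a list of (frozenset_a, frozenset_b, height)
    merges over original leaf indices."""
    n = d.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pts_a, pts_b = clusters[a], clusters[b]
                avg = np.mean([d[i, j] for i in pts_a for j in pts_b])
                if best is None or avg < best[0]:
                    best = (avg, a, b)
        avg, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((clusters[a], clusters[b], avg))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges


def linkage_merge_sets(Z: np.ndarray, n: int):
    """Decode a scipy linkage matrix into the same (set_a, set_b, height)
    merge list as :func:`average_linkage_oracle`."""
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step, (a, b, h, _) in enumerate(Z):
        sa, sb = members[int(a)], members[int(b)]
        merges.append((sa, sb, float(h)))
        members[n + step] = sa | sb
    return merges


# -- silhouette --------------------------------------------------------------

def silhouette_oracle(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point s(i) = (b - a)/max(a, b) from raw pairwise means;
    singleton clusters score 0."""
    n = len(labels)
    out = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            out[i] = 0.0
            continue
        a = np.mean([d[i, j] for j in same])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == other])
            for other in set(labels) - {labels[i]}
        )
        out[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return out


# -- rank correlation --------------------------------------------------------

def midranks(x):
    """Average ranks for ties, from the definition."""
    x = np.asarray(x, dtype=float)
    out = np.empty(len(x))
    for i, v in enumerate(x):
        less = np.sum(x < v)
        eq = np.sum(x == v)
        out[i] = less + (eq + 1) / 2.0
    return out


def spearman_oracle(x, y) -> float:
    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


# -- Cox partial likelihood (Efron ties) -------------------------------------

def cox_efron_loglik(beta: float, times, events, x) -> float:
    """Efron-approximation partial log-likelihood for one covariate."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for t in np.unique(times[events == 1]):
        D = np.where((times == t) & (events == 1))[0]
        R = np.where(times >= t)[0]
        d = len(D)
        sum_risk = np.sum(np.exp(beta * x[R]))
        sum_tied = np.sum(np.exp(beta * x[D]))
        ll += beta * np.sum(x[D])
        for ell in range(d):
            ll -= math.log(sum_risk - (ell / d) * sum_tied)
    return ll


def cox_mle_grid(times, events, x, lo=-8.0, hi=8.0, tol=1e-6) -> float:
    """Maximize the Efron partial likelihood by golden-section search."""
    phi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc = cox_efron_loglik(c, times, events, x)
    fd = cox_efron_loglik(d, times, events, x)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = cox_efron_loglik(c, times, events, x)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = cox_efron_loglik(d, times, events, x)
    return (a + b) / 2


# -- log-rank (two groups, by hand) ------------------------------------------

def logrank_oracle(times, events, groups):
    """Observed-minus-expected chi-square for two groups from risk tables."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    g1 = np.unique(groups)[0]
    O = E = V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == g1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == g1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    stat = (O - E) ** 2 / V if V > 0 else 0.0
    return stat


# -- set partition ------------------------------------------------------------

def partition_oracle(sets: dict):
    """Enumerate membership patterns gene by gene."""
    contrasts = list(sets)
    regions: dict[frozenset, set] = {}
    for g in set().union(*sets.values()):
        patt = frozenset(c for c in contrasts if g in sets[c])
        regions.setdefault(patt, set()).add(g)
    return regions
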