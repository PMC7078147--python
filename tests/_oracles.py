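"""Independent brute-force oracles used to validate the implementation.

Everything here is written with explicit loops and elementary formulas,
deliberately sharing no code with the package.
"""

from __future__ import annotations

import math
from itertools import combinations


def pearson_overlap(x, y, lag):
    """Pearson correlation of x[i] vs y[i+lag] over the overlap window,
    computed with explicit loops.  Returns None when undefined."""
    n = len(x)
    assert len(y) == n
    pairs = []
    for i in range(n):
        j = i + lag
        if 0 <= j < n:
            pairs.append((x[i], y[j]))
    if len(pairs) < 2:
        return None
    mx = sum(p[0] for p in pairs) / len(pairs)
    my = sum(p[1] for p in pairs) / len(pairs)
    sxx = sum((p[0] - mx) ** 2 for p in pairs)
    syy = sum((p[1] - my) ** 2 for p in pairs)
    sxy = sum((p[0] - mx) * (p[1] - my) for p in pairs)
    if sxx == 0.0 or syy == 0.0:
        return None
    return sxy / math.sqrt(sxx * syy)


def exhaustive_kmeans_1d(values, k):
    """Globally optimal 1-D k-means by exhaustive search over contiguous
    partitions of the sorted values (optimal 1-D clusters are contiguous).

    Returns (best_sse, partition) with the partition a tuple of sorted
    value-blocks.
    """
    v = sorted(values)
    n = len(v)
    assert 1 <= k <= n
    best_sse = None
    best_parts = None
    for cuts in combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        sse = 0.0
        parts = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            block = v[a:b]
            mu = sum(block) / len(block)
            sse += sum((x - mu) ** 2 for x in block)
            parts.append(tuple(block))
        if best_sse is None or sse < best_sse - 1e-15:
            best_sse = sse
            best_parts = tuple(parts)
    return best_sse, best_parts


def km_product_limit(times_events):
    """Product-limit estimate from (time, event) pairs, via explicit
    risk-set tabulation.  Returns a list of (event_time, S(t)) steps and the
    median (earliest time with S <= 0.5, or None if never reached)."""
    data = sorted(times_events)
    s = 1.0
    steps = []
    median = None
    distinct_event_times = sorted({t for t, e in data if e == 1})
    for t in distinct_event_times:
        at_risk = sum(1 for ti, _ in data if ti >= t)
        deaths = sum(1 for ti, e in data if ti == t and e == 1)
        s *= (1.0 - deaths / at_risk)
        steps.append((t, s))
        if median is None and s <= 0.5:
            median = t
    return steps, median


def logrank_two_group(group_a, group_b):
    """Two-sample log-rank O-E/V by explicit risk-set tabulation.

    ``group_a``/``group_b`` are lists of (time, event).  Returns
    (O_a, E_a, V, chi2).
    """
    all_events = sorted({t for t, e in group_a + group_b if e == 1})
    O = E = V = 0.0
    for t in all_events:
        na = sum(1 for ti, _ in group_a if ti >= t)
        nb = sum(1 for ti, _ in group_b if ti >= t)
        n = na + nb
        d = sum(1 for ti, e in group_a + group_b if ti == t and e == 1)
        da = sum(1 for ti, e in group_a if ti == t and e == 1)
        O += da
        E += d * na / n
        if n > 1:
            V += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V if V > 0 else 0.0
    return O, E, V, chi2
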