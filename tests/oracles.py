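"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: direct scans, exhaustive
enumeration, and the textbook step-up formula, written without reference to
the package's own code paths.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np


def one_to_one_pairs_oracle(clusters):
    """Brute-force one-to-one filter: count member multiplicities directly."""
    singles = [
        (c.yeast_members[0][0], c.human_members[0][0])
        for c in clusters
        if len(c.yeast_members) == 1 and len(c.human_members) == 1
    ]
    y_counts = Counter(y for y, _ in singles)
    h_counts = Counter(h for _, h in singles)
    return {(y, h) for y, h in singles if y_counts[y] == 1 and h_counts[h] == 1}


def humanize_oracle(records, translate):
    """Set-based node/edge construction with explicit best-record selection."""
    best = {}
    for rec in records:
        a, b = translate(rec.query_gene), translate(rec.array_gene)
        if a is None or b is None or a == b:
            continue
        key = tuple(sorted((a, b)))
        if key not in best or (rec.epsilon, rec.p_value) < best[key]:
            best[key] = (rec.epsilon, rec.p_value)
    nodes = {g for key in best for g in key}
    return nodes, best


def bh_oracle(p_values):
    """Textbook step-up: adj_(i) = min_{j>=i} p_(j) * m / j, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running_min = 1.0
    for rank in range(m - 1, -1, -1):
        value = p[order[rank]] * m / (rank + 1)
        running_min = min(running_min, value)
        adj_sorted[rank] = min(running_min, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def _midranks(values):
    values = np.asarray(values, dtype=float)
    order = np.argsort(values)
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def signed_rank_p_oracle(diffs):
    """Exhaustive two-sided signed-rank p over all sign assignments.

    Zero differences are dropped; |d| is midranked. The two-sided p is the
    fraction of sign assignments whose |W - E[W]| is at least as extreme as
    observed, where W is the positive-rank sum.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = _midranks(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    center = total / 2
    obs_dev = abs(w_obs - center)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - center) >= obs_dev - 1e-12:
            count += 1
    return count / 2**n


def mannwhitney_p_oracle(x, y):
    """Exhaustive two-sided Mann-Whitney p over all group relabelings."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n_x = x.size
    idx = range(pooled.size)

    def u_of(subset):
        xs = pooled[list(subset)]
        ys = np.delete(pooled, list(subset))
        return float(
            (xs[:, None] > ys[None, :]).sum()
            + 0.5 * (xs[:, None] == ys[None, :]).sum()
        )

    u_obs = u_of(range(n_x))
    mean_u = n_x * y.size / 2
    obs_dev = abs(u_obs - mean_u)
    count = 0
    total = 0
    for subset in itertools.combinations(idx, n_x):
        total += 1
        if abs(u_of(subset) - mean_u) >= obs_dev - 1e-12:
            count += 1
    return count / total


def incident_edges_oracle(edges, seeds):
    """All edges with at least one seed endpoint, as canonical pairs."""
    seeds = set(seeds)
    return {tuple(sorted(e)) for e in edges if e[0] in seeds or e[1] in seeds}


def zero_filter_oracle(tumor, normal):
    """Row indices where every value in both matrices is strictly positive."""
    keep = []
    for i in range(tumor.shape[0]):
        if all(v > 0 for v in tumor[i]) and all(v > 0 for v in normal[i]):
            keep.append(i)
    return keep


def marker_split_oracle(expr):
    """Mean-cutoff partition, <= mean goes low."""
    cutoff = sum(expr.values()) / len(expr)
    low = {k for k, v in expr.items() if v <= cutoff}
    high = {k for k, v in expr.items() if v > cutoff}
    return low, high, cutoff


def category_matrix_oracle(edges, labels, default="unassigned"):
    counts = Counter()
    for u, v in edges:
        cu, cv = labels.get(u, default), labels.get(v, default)
        counts[tuple(sorted((cu, cv)))] += 1
    return dict(counts)
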