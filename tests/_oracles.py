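"""Independent brute-force reference implementations used only by tests.

Each oracle is written from the mathematical definition, independent of the
package code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def bh_stepup(pvalues):
    """Benjamini-Hochberg step-up from the definition.

    adj_(i) = min_{j >= i} min(1, m * p_(j) / j) on the sorted values,
    mapped back to the input order.
    """
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj_sorted = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        val = min(1.0, m * p[order[pos]] / (pos + 1))
        running = min(running, val)
        adj_sorted[pos] = running
    out = [0.0] * m
    for pos, i in enumerate(order):
        out[i] = adj_sorted[pos]
    return out


def combine_pi(lfc_row, adjp_row, require_all_present=True):
    """Direction-consistency + closest-to-zero combination for one gene.

    Returns (combined_pi, direction) or None if the gene is excluded.
    Inputs are per-comparison log2 fold-changes and adjusted p's; NaN marks
    a missing comparison.
    """
    pairs = [(l, q) for l, q in zip(lfc_row, adjp_row) if not math.isnan(l)]
    if not pairs:
        return None
    if require_all_present and len(pairs) < len(lfc_row):
        return None
    signs = {(-1 if l < 0 else (1 if l > 0 else 0)) for l, _ in pairs}
    if len(signs) != 1 or 0 in signs:
        return None
    pis = [l * (-math.log10(max(q, 1e-300))) for l, q in pairs]
    best = min(pis, key=abs)
    return best, ("down" if signs == {-1} else "up")


def average_linkage(points_or_dist, is_distance=False):
    """Quadratic-time UPGMA agglomeration from the definition.

    Returns the merge history as a list of (frozenset_a, frozenset_b, height)
    over original leaf indices, in merge order.
    """
    if is_distance:
        d0 = np.asarray(points_or_dist, dtype=float)
        n = d0.shape[0]
    else:
        pts = np.asarray(points_or_dist, dtype=float)
        n = pts.shape[0]
        d0 = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                ca, cb = clusters[a], clusters[b]
                d = np.mean([d0[i, j] for i in ca for j in cb])
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        merges.append((clusters[a], clusters[b], d))
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return merges


def hypergeom_upper_tail(k, N, K, n):
    """P(X >= k) for the hypergeometric by direct enumeration."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        if n - x > N - K:
            continue
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


def tom_reference(adjacency):
    """Topological overlap from the definition, with explicit loops."""
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    w = np.eye(n)
    k = a.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            w[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return w
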