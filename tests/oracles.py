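"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (exhaustive enumeration) and shares no
code with the package: spanning trees by edge-subset enumeration, shortest
paths by simple-path DFS, the Wilcoxon null by full label enumeration and
Benjamini-Hochberg by the literal step-up definition.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def enumerate_spanning_trees(n: int, edges: list[tuple[int, int]]):
    """Yield every spanning tree (as a frozenset of edges) of an n-node graph."""
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[rb] = ra
        if ok:
            yield frozenset(subset)


def brute_force_mst_distance(
    weights: np.ndarray, excluded: frozenset[tuple[int, int]] = frozenset()
) -> float | None:
    """Minimal total 1/w distance over all spanning trees; None if none spans."""
    n = weights.shape[0]
    edges = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if weights[i, j] > 0 and (i, j) not in excluded
    ]
    best = None
    for tree in enumerate_spanning_trees(n, edges):
        total = sum(1.0 / weights[i, j] for i, j in tree)
        if best is None or total < best:
            best = total
    return best


def brute_force_shortest_paths(d: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by exhaustive simple-path enumeration."""
    n = d.shape[0]
    out = np.full((n, n), np.inf)
    np.fill_diagonal(out, 0.0)
    adjacency = [
        [j for j in range(n) if j != i and np.isfinite(d[i, j])] for i in range(n)
    ]

    for src in range(n):
        best = out[src]

        def dfs(node, dist, visited):
            for nxt in adjacency[node]:
                if nxt in visited:
                    continue
                nd = dist + d[node, nxt]
                if nd < best[nxt]:
                    best[nxt] = nd
                dfs(nxt, nd, visited | {nxt})

        dfs(src, 0.0, {src})
    return out


def exact_wilcoxon_two_sided(x, y) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Returns ``(W_x, p)`` matching the convention of doubling the smaller
    tail (capped at 1).  Assumes no ties.
    """
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    ranks = {v: r + 1 for r, v in enumerate(pooled)}
    n = len(x)
    w_obs = sum(ranks[v] for v in x)
    all_ranks = list(ranks.values())
    dist = [sum(c) for c in itertools.combinations(all_ranks, n)]
    total = comb(len(pooled), n)
    le = sum(w <= w_obs for w in dist)
    ge = sum(w >= w_obs for w in dist)
    p = min(1.0, 2.0 * min(le, ge) / total)
    return float(w_obs), p


def stepup_bh(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(prev, m * p[idx] / rank_from_top)
        q[idx] = val
        prev = val
    return q
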