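"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and libraries) they check:
betweenness/closeness come from exhaustive BFS all-pairs enumeration,
the hypergeometric tail from exact integer combinatorics, and BH from a
literal transcription of the step-up rule.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def bfs_all_pairs(adj: dict, nodes: list):
    """Distances and shortest-path counts for every ordered pair.

    Returns (dist, sigma) as n x n arrays over ``nodes`` order; dist is
    np.inf for unreachable pairs.
    """
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in nodes:
        si = index[s]
        dist[si, si] = 0.0
        sigma[si, si] = 1.0
        q = deque([s])
        while q:
            u = q.popleft()
            ui = index[u]
            for w in adj[u]:
                wi = index[w]
                if dist[si, wi] == np.inf:
                    dist[si, wi] = dist[si, ui] + 1
                    q.append(w)
                if dist[si, wi] == dist[si, ui] + 1:
                    sigma[si, wi] += sigma[si, ui]
    return dist, sigma


def _adjacency(g) -> tuple[dict, list]:
    nodes = sorted(g.nodes())
    adj = {v: sorted(g.neighbors(v)) for v in nodes}
    return adj, nodes


def brute_betweenness(g, normalized: bool = True) -> dict:
    """Betweenness by direct enumeration of sigma_st(v)/sigma_st over all
    ordered (s, t) pairs with s != v != t."""
    adj, nodes = _adjacency(g)
    n = len(nodes)
    dist, sigma = bfs_all_pairs(adj, nodes)
    values = {}
    for vi, v in enumerate(nodes):
        through = dist[:, vi][:, None] + dist[vi, :][None, :]
        finite = np.isfinite(dist)
        on_path = finite & (through == dist) & (sigma > 0)
        on_path[vi, :] = False
        on_path[:, vi] = False
        np.fill_diagonal(on_path, False)
        contrib = np.zeros((n, n))
        contrib[on_path] = (
            sigma[:, vi][:, None] * sigma[vi, :][None, :]
        )[on_path] / sigma[on_path]
        total = contrib.sum()  # ordered pairs: each unordered pair counted twice
        if normalized:
            values[v] = total / ((n - 1) * (n - 2)) if n > 2 else 0.0
        else:
            values[v] = total / 2.0
    return values


def brute_closeness(g) -> dict:
    """Reciprocal mean BFS distance to the node's reachable peers."""
    adj, nodes = _adjacency(g)
    dist, _ = bfs_all_pairs(adj, nodes)
    values = {}
    for vi, v in enumerate(nodes):
        d = dist[vi]
        reach = np.isfinite(d) & (d > 0)
        values[v] = float(reach.sum() / d[reach].sum()) if reach.any() else 0.0
    return values


def hypergeom_pmf_exact(k: int, K: int, n: int, N: int) -> float:
    """P(X = k) via exact integer binomials."""
    if k < 0 or k > min(K, n) or n - k > N - K:
        return 0.0
    return math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)


def hypergeom_upper_tail_exact(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by direct summation of the exact PMF."""
    return sum(hypergeom_pmf_exact(j, K, n, N) for j in range(k, min(K, n) + 1))


def bh_stepup_reference(pvals) -> list[float]:
    """Literal Benjamini-Hochberg step-up: sort, take running minima of
    m*p_(j)/j from the largest rank down, map back to input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        adjusted[i] = running
    return adjusted
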