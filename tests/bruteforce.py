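"""Independent brute-force oracles for the graph metrics and exact tests.

Deliberately naive: Floyd-Warshall distances, explicit neighbor-pair
triangle counting, shortest-path enumeration over all simple paths, and
hypergeometric enumeration for the exact test. These never share code with
the package implementation they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def is_connected(adj: np.ndarray) -> bool:
    return bool(np.isfinite(floyd_warshall(adj)).all())


def char_path_length(adj: np.ndarray) -> float:
    dist = floyd_warshall(adj)
    # largest component, ordered pairs
    comps = []
    seen = set()
    for i in range(adj.shape[0]):
        if i in seen:
            continue
        comp = [j for j in range(adj.shape[0]) if np.isfinite(dist[i, j])]
        seen.update(comp)
        comps.append(comp)
    comp = max(comps, key=len)
    vals = [dist[i, j] for i in comp for j in comp if i != j]
    return float(np.mean(vals))


def global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    dist = floyd_warshall(adj)
    total = sum(
        1.0 / dist[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(dist[i, j])
    )
    return total / (n * (n - 1))


def clustering_coefficient(adj: np.ndarray) -> float:
    n = adj.shape[0]
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        e = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b]
        )
        cs.append(2.0 * e / (k * (k - 1)))
    return float(np.mean(cs))


def local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    effs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            effs.append(0.0)
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        effs.append(global_efficiency(sub))
    return float(np.mean(effs))


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Enumerate every shortest path of every pair; count pass-throughs."""
    n = adj.shape[0]
    dist = floyd_warshall(adj)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(dist[s, t]):
            continue
        length = int(dist[s, t])
        # all simple paths of exactly the geodesic length
        paths = []
        for mid in itertools.permutations(
            [v for v in range(n) if v not in (s, t)], length - 1
        ):
            nodes = (s, *mid, t)
            if all(adj[nodes[i], nodes[i + 1]] for i in range(length)):
                paths.append(nodes)
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc / ((n - 1) * (n - 2) / 2.0)


def connected_graphs(n: int):
    """Yield the adjacency matrix of every connected labeled graph on n
    nodes (2^(n(n-1)/2) patterns filtered)."""
    pairs = list(itertools.combinations(range(n), 2))
    for bits in range(2 ** len(pairs)):
        adj = np.zeros((n, n), dtype=np.uint8)
        for b, (i, j) in enumerate(pairs):
            if bits >> b & 1:
                adj[i, j] = adj[j, i] = 1
        if is_connected(adj):
            yield adj


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided p by enumerating every table with the observed
    margins and summing point probabilities <= the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point_prob(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = point_prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = point_prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total
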