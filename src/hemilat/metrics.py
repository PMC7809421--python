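"""Binary graph metrics and the degree-preserving small-world null model.

Implements the five global network measures used throughout the analysis —
characteristic path length Lp, global efficiency Eglob, clustering
coefficient Cp, local efficiency Elocal, and small-worldness sigma — plus
normalized per-node betweenness centrality, on simple undirected binary
graphs (hop-count distances).

Definitions
-----------
* ``Lp = 1/(N(N-1)) * sum_{i != j} L_ij`` with ``L_ij`` the shortest-path hop
  count; on disconnected graphs it is evaluated on the largest connected
  component (recorded in a component note) so it stays finite.
* ``Eglob = 1/(N(N-1)) * sum_{i != j} 1/L_ij`` with ``1/inf = 0``; no
  component restriction is needed.
* ``Cp = 1/N * sum_i 2 E_i / (k_i (k_i - 1))`` where ``k_i`` is the degree of
  node i and ``E_i`` the number of edges among its neighbors; nodes with
  ``k_i < 2`` contribute 0 (they stay in the 1/N average).
* ``Elocal = 1/N * sum_i Eglob(G[neighbors(i)])`` — the global efficiency of
  each node's neighborhood subgraph (node itself excluded); nodes with fewer
  than two neighbors contribute 0.
* betweenness of node n = fraction of shortest paths between pairs (a, b),
  a, b != n, that pass through n, accumulated Brandes-style and normalized by
  ``(N-1)(N-2)/2``.
* ``sigma = (Cp/Cran) / (Lp/Lran)`` against the mean clustering ``Cran`` and
  path length ``Lran`` of degree-preserving double-edge-swap references
  (``orientation="printed"`` returns the reciprocal ``(Lp/Lran)/(Cp/Cran)``).

All-pairs distances and the Brandes accumulation are level-synchronous and
vectorized (boolean frontier expansion over all sources at once), which keeps
the per-network cost low enough for the replicate calibration experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .atlas import ROI_NAMES
from .connectome import HemisphereNetwork
from .errors import ComputationError, InputError

log = logging.getLogger(__name__)

GLOBAL_METRICS = ("Lp", "Eglob", "Cp", "Elocal", "sigma")


@dataclass
class RandomReferenceSummary:
    """Mean clustering and path length over degree-matched references."""

    n_random: int
    lran: float
    cran: float
    seed: int


@dataclass
class NetworkMetricSet:
    """All global measures plus per-node profiles for one hemisphere network.

    ``node_profiles`` columns: label, degree, neighbor_edges,
    local_efficiency, betweenness. ``component_note`` records any
    largest-component restriction applied to Lp / sigma.
    """

    lp: float
    eglob: float
    cp: float
    elocal: float
    sigma: float
    node_profiles: pd.DataFrame
    random_summary: RandomReferenceSummary | None = None
    component_note: str = ""

    def value(self, metric: str) -> float:
        return {
            "Lp": self.lp,
            "Eglob": self.eglob,
            "Cp": self.cp,
            "Elocal": self.elocal,
            "sigma": self.sigma,
        }[metric]


def _adjacency(network) -> np.ndarray:
    """Accept a HemisphereNetwork or a raw symmetric 0/1 ndarray."""
    adj = network.adjacency if isinstance(network, HemisphereNetwork) else network
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise InputError(f"adjacency must be square, got shape {adj.shape}")
    return adj.astype(np.uint8)


def shortest_paths(network) -> np.ndarray:
    """All-pairs hop-count distance matrix; ``inf`` marks unreachable pairs.

    Breadth-first search as boolean frontier expansion from all sources at
    once.
    """
    adj = _adjacency(network)
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = reached.copy()
    a_bool = adj.astype(bool)
    d = 0
    while frontier.any():
        d += 1
        nxt = (frontier @ a_bool) & ~reached
        dist[nxt] = d
        reached |= nxt
        frontier = nxt
    return dist


def _inverse_distance_sum(adj: np.ndarray) -> float:
    """``sum_{i != j} 1/L_ij`` without materializing the distance matrix."""
    n = adj.shape[0]
    reached = np.eye(n, dtype=bool)
    frontier = reached.copy()
    a_bool = adj.astype(bool)
    total = 0.0
    d = 0
    while frontier.any():
        d += 1
        nxt = (frontier @ a_bool) & ~reached
        total += nxt.sum() / d
        reached |= nxt
        frontier = nxt
    return total


def connected_components(network) -> list[np.ndarray]:
    """Index arrays of the connected components, largest first."""
    adj = _adjacency(network)
    dist = shortest_paths(adj)
    return _components_from_dist(dist)


def _components_from_dist(dist: np.ndarray) -> list[np.ndarray]:
    finite = np.isfinite(dist)
    unseen = set(range(dist.shape[0]))
    comps = []
    while unseen:
        i = next(iter(unseen))
        comp = np.flatnonzero(finite[i])
        comps.append(comp)
        unseen -= set(comp.tolist())
    comps.sort(key=len, reverse=True)
    return comps


def char_path_length(network) -> float:
    """Characteristic path length: mean hop distance over ordered reachable
    pairs of the largest connected component.

    Equals ``1/(N(N-1)) * sum L_ij`` on connected graphs. Raises
    :class:`ComputationError` for graphs with no edges.
    """
    adj = _adjacency(network)
    if adj.sum() == 0:
        raise ComputationError("characteristic path length undefined: no edges")
    dist = shortest_paths(adj)
    comp = _components_from_dist(dist)[0]
    sub = dist[np.ix_(comp, comp)]
    off = ~np.eye(len(comp), dtype=bool)
    return float(sub[off].mean())


def global_efficiency(network) -> float:
    """Mean inverse shortest-path length over ordered pairs, with
    ``1/inf = 0`` for unreachable pairs."""
    adj = _adjacency(network)
    n = adj.shape[0]
    if n < 2:
        return 0.0
    return _inverse_distance_sum(adj) / (n * (n - 1))


def _degrees_and_neighbor_edges(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = adj.sum(axis=1).astype(int)
    a = adj.astype(np.int64)
    # diag(A^3)/2 counts edges among each node's neighbors
    tri = np.einsum("ij,jk,ki->i", a, a, a) // 2
    return k, tri


def _clustering_values(adj: np.ndarray) -> np.ndarray:
    k, tri = _degrees_and_neighbor_edges(adj)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(k >= 2, 2.0 * tri / (k * (k - 1.0)), 0.0)


def clustering_coefficient(network) -> float:
    return float(_clustering_values(_adjacency(network)).mean())


def _node_local_efficiencies(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    a_bool = adj.astype(bool)
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a_bool[i])
        m = nbrs.size
        if m < 2:
            continue
        sub = a_bool[np.ix_(nbrs, nbrs)]
        out[i] = _inverse_distance_sum(sub) / (m * (m - 1))
    return out


def local_efficiency(network) -> float:
    """Mean over nodes of the global efficiency of the neighborhood
    subgraph (the node itself excluded)."""
    adj = _adjacency(network)
    return float(_node_local_efficiencies(adj).mean())


def betweenness(network) -> np.ndarray:
    """Normalized betweenness centrality per node.

    Brandes path counting and dependency accumulation, vectorized over all
    sources (level-synchronous BFS). Pair dependencies over unordered pairs
    excluding the node, divided by ``(N-1)(N-2)/2``, giving values in [0, 1].
    """
    adj = _adjacency(network)
    n = adj.shape[0]
    if n < 3:
        raise InputError(f"betweenness needs >= 3 nodes, got {n}")
    a = adj.astype(np.float64)
    # sigma[s, v]: number of shortest s -> v paths; dist[s, v]: hop count
    sigma = np.eye(n)
    dist = np.full((n, n), -1, dtype=np.int64)
    np.fill_diagonal(dist, 0)
    frontier = np.eye(n, dtype=bool)
    visited = frontier.copy()
    d = 0
    while frontier.any():
        d += 1
        counts = (sigma * frontier) @ a
        new = (counts > 0) & ~visited
        sigma[new] = counts[new]
        dist[new] = d
        visited |= new
        frontier = new
    # backward accumulation of pair dependencies, level by level
    delta = np.zeros((n, n))
    safe_sigma = np.where(sigma > 0, sigma, 1.0)
    for level in range(d, 0, -1):
        at_level = dist == level
        coef = np.where(at_level, (1.0 + delta) / safe_sigma, 0.0)
        contrib = (coef @ a) * sigma
        below = dist == level - 1
        delta[below] += contrib[below]
    np.fill_diagonal(delta, 0.0)
    bc = delta.sum(axis=0) / 2.0  # each unordered pair counted from both ends
    return bc / ((n - 1) * (n - 2) / 2.0)


def random_reference(network, seed: int, swap_factor: int = 10):
    """Degree-preserving randomization by attempted double edge swaps.

    ``swap_factor * |E|`` swaps are attempted; swaps that would create a
    self-loop or duplicate edge are rejected. Connectivity of the result is
    not enforced. A graph admitting no valid swap (fewer than 2 edges) is
    returned unchanged with a warning. Returns the same type as the input
    (HemisphereNetwork in, HemisphereNetwork out).
    """
    adj = _adjacency(network).copy()
    rng = np.random.default_rng(seed)
    edge_idx = np.argwhere(np.triu(adj, 1))
    m = len(edge_idx)
    if m < 2:
        log.warning("random_reference: graph admits no valid swap (|E|=%d)", m)
        return _like(network, adj)
    n_attempts = swap_factor * m
    picks = rng.integers(m, size=(n_attempts, 2)).tolist()
    flips = rng.integers(2, size=n_attempts).tolist()
    edges = [tuple(e) for e in edge_idx.tolist()]
    for (e, f), flip in zip(picks, flips):
        if e == f:
            continue
        a, b = edges[e]
        c, d = edges[f]
        if flip:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, c] or adj[b, d]:
            continue
        adj[a, b] = adj[b, a] = 0
        adj[c, d] = adj[d, c] = 0
        adj[a, c] = adj[c, a] = 1
        adj[b, d] = adj[d, b] = 1
        edges[e] = (a, c)
        edges[f] = (b, d)
    return _like(network, adj)


def _like(network, adj: np.ndarray):
    if isinstance(network, HemisphereNetwork):
        return HemisphereNetwork(
            side=network.side, node_labels=list(network.node_labels), adjacency=adj
        )
    return adj


def _clustering_and_lcc_path_length(adj: np.ndarray) -> tuple[float, float]:
    """Fast (Cp, Lp) for the reference loop; Lp on the largest component."""
    c = _clustering_values(adj)
    dist = shortest_paths(adj)
    finite = np.isfinite(dist)
    comp_sizes = finite.sum(axis=1)
    members = comp_sizes == comp_sizes.max()
    sub = dist[np.ix_(members, members)]
    sub = sub[np.isfinite(sub) & (sub > 0)]
    lp = float(sub.mean()) if sub.size else float("nan")
    return float(c.mean()), lp


def small_worldness(
    network,
    n_random: int = 100,
    seed: int = 0,
    swap_factor: int = 10,
    orientation: str = "standard",
) -> tuple[float, RandomReferenceSummary]:
    """Small-worldness sigma against degree-preserving random references.

    On a disconnected input the largest connected component is used (logged).
    ``orientation="standard"`` gives ``(Cp/Cran)/(Lp/Lran)``;
    ``orientation="printed"`` the reciprocal. Raises
    :class:`ComputationError` if the references have zero mean clustering.
    """
    if n_random < 1:
        raise InputError(f"n_random must be >= 1, got {n_random}")
    if orientation not in ("standard", "printed"):
        raise InputError(f"unknown sigma orientation {orientation!r}")
    adj = _adjacency(network)
    comp = connected_components(adj)[0]
    if len(comp) < adj.shape[0]:
        log.info(
            "small_worldness: using largest component (%d of %d nodes)",
            len(comp),
            adj.shape[0],
        )
    sub = adj[np.ix_(comp, comp)]
    if sub.sum() == 0:
        raise ComputationError("small-worldness undefined: no edges")
    cp, lp = _clustering_and_lcc_path_length(sub)
    seeds = np.random.SeedSequence(seed).generate_state(n_random) % (2**31)
    crs = np.empty(n_random)
    lrs = np.empty(n_random)
    for r in range(n_random):
        ref = random_reference(sub, seed=int(seeds[r]), swap_factor=swap_factor)
        crs[r], lrs[r] = _clustering_and_lcc_path_length(ref)
    cran = float(crs.mean())
    lran = float(lrs.mean())
    if cran == 0.0:
        raise ComputationError("small-worldness undefined: reference clustering is 0")
    sigma = (cp / cran) / (lp / lran)
    if orientation == "printed":
        sigma = 1.0 / sigma
    summary = RandomReferenceSummary(n_random=n_random, lran=lran, cran=cran, seed=seed)
    return float(sigma), summary


def compute_metrics(
    network: HemisphereNetwork,
    n_random: int = 100,
    seed: int = 0,
    swap_factor: int = 10,
    orientation: str = "standard",
) -> NetworkMetricSet:
    """Bundle all global measures and per-node profiles for one network."""
    adj = _adjacency(network)
    if adj.sum() == 0:
        raise ComputationError("metrics undefined: network has no edges")
    n = adj.shape[0]
    dist = shortest_paths(adj)
    comps = _components_from_dist(dist)
    note = ""
    if len(comps) > 1:
        note = (
            f"disconnected: Lp and sigma on largest component "
            f"({len(comps[0])} of {n} nodes)"
        )
    comp = comps[0]
    sub_dist = dist[np.ix_(comp, comp)]
    off = ~np.eye(len(comp), dtype=bool)
    lp = float(sub_dist[off].mean())
    all_off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        eglob = float((1.0 / dist[all_off]).mean())
    k, tri = _degrees_and_neighbor_edges(adj)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvals = np.where(k >= 2, 2.0 * tri / (k * (k - 1.0)), 0.0)
    local_eff = _node_local_efficiencies(adj)
    sigma, summary = small_worldness(
        adj, n_random=n_random, seed=seed, swap_factor=swap_factor,
        orientation=orientation,
    )
    profiles = pd.DataFrame(
        {
            "label": network.node_labels,
            "degree": k,
            "neighbor_edges": tri,
            "local_efficiency": local_eff,
            "betweenness": betweenness(adj),
        }
    )
    return NetworkMetricSet(
        lp=lp,
        eglob=eglob,
        cp=float(cvals.mean()),
        elocal=float(local_eff.mean()),
        sigma=sigma,
        node_profiles=profiles,
        random_summary=summary,
        component_note=note,
    )


def extract_roi_betweenness(
    metrics: NetworkMetricSet, atlas: pd.DataFrame, side: str
) -> Mapping[str, float]:
    """Betweenness of the four fronto-limbic ROI nodes of one hemisphere,
    keyed mFOG / STG / amygdala / hippocampus."""
    labels = metrics.node_profiles["label"].to_numpy()
    values = metrics.node_profiles["betweenness"].to_numpy()
    by_label = dict(zip(labels.tolist(), values.tolist()))
    roi_to_label: dict[str, int] = {}
    for row in atlas.itertuples(index=False):
        if row.roi_flag != "none" and row.hemisphere == side:
            roi_to_label[row.roi_flag] = int(row.label_id)
    out = {}
    for roi in ROI_NAMES:
        lab = roi_to_label.get(roi)
        if lab is None or lab not in by_label:
            raise InputError(
                f"ROI {roi!r} missing from the {side} network"
            )
        out[roi] = float(by_label[lab])
    return out
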