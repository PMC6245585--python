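"""Weighted protein-network ingestion, normalization and path structure.

Networks follow the STRING convention: an undirected edge list in which each
protein pair carries an integer "combined score" in 1..999 expressing
confidence in the functional association.  After thresholding (the STRING
curators' recommended cutoff is 700) scores are mapped to raw similarity
weights in (0, 1] and the raw matrix ``W_hat`` is symmetrically normalized,

    W = D^{-1/2} W_hat D^{-1/2},   d_ii = sum_j W_hat_ij,

which preserves symmetry and keeps entries in [0, 1].  All downstream
features are computed on ``W``.
"""

from __future__ import annotations

import gzip
import heapq
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc, shortest_path as _sp

logger = logging.getLogger(__name__)

#: selectable edge-cost transforms for shortest-path computations.  ``W`` holds
#: similarities; the default reads the entries literally as costs, the other
#: modes are provided for sensitivity analysis.
COST_MODES = ("weight_as_cost", "inverse_weight", "one_minus_weight", "hop")

#: tolerance used when deciding whether two path costs tie
TIE_TOL = 1e-12


class NetworkDataError(ValueError):
    """Malformed or inconsistent network input."""


@dataclass
class RawNetwork:
    """Un-normalized symmetric similarity matrix over labelled proteins."""

    node_labels: list[str]
    weights: np.ndarray  # dense symmetric, zero diagonal, entries >= 0

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def validate(self) -> None:
        w = self.weights
        if w.shape != (self.n_nodes, self.n_nodes):
            raise NetworkDataError("weight matrix shape does not match labels")
        if not np.allclose(w, w.T):
            raise NetworkDataError("raw weight matrix is not symmetric")
        if np.any(np.diag(w) != 0):
            raise NetworkDataError("raw weight matrix has nonzero diagonal")
        if np.any(w < 0):
            raise NetworkDataError("raw weights must be non-negative")


@dataclass
class WeightedNetwork:
    """Symmetrically normalized network ``W = D^{-1/2} W_hat D^{-1/2}``.

    ``degree`` stores the diagonal of ``D`` (row sums of the raw matrix),
    which the random-walk features reuse.  Isolated nodes are disallowed:
    every row of ``w`` has at least one nonzero entry.
    """

    node_labels: list[str]
    w: np.ndarray
    degree: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def label_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.node_labels)}

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.w[i] > 0)


@dataclass
class ComponentIndex:
    """Partition of the node set into connected components."""

    component_id: np.ndarray  # int per node
    members: list[np.ndarray]  # member index arrays, one per component

    @property
    def n_components(self) -> int:
        return len(self.members)

    def component_of(self, i: int) -> np.ndarray:
        return self.members[self.component_id[i]]

    def sizes(self) -> list[int]:
        return [len(m) for m in self.members]


@dataclass
class ShortestPathCache:
    """All-pairs weighted shortest-path distances and path counts.

    ``dist[s, t]`` is the minimum total edge cost between ``s`` and ``t``
    (``inf`` across components), ``sigma[s, t]`` the number of distinct
    minimum-cost paths.  Ties in path cost are resolved with an absolute
    tolerance of ``TIE_TOL``.  The number of shortest s-t paths passing
    through an internal node ``i`` is recovered on demand from the identity
    ``sigma_st(i) = sigma_si * sigma_it`` whenever ``d_si + d_it = d_st``.
    """

    dist: np.ndarray
    sigma: np.ndarray
    cost_mode: str

    def sigma_through(self, i: int) -> np.ndarray:
        """Matrix of shortest s-t path counts passing through node ``i``."""
        d, s = self.dist, self.sigma
        with np.errstate(invalid="ignore"):
            on_path = np.abs(d[:, i, None] + d[None, i, :] - d) <= TIE_TOL
        on_path &= np.isfinite(d)
        out = np.where(on_path, np.outer(s[:, i], s[i, :]), 0.0)
        out[i, :] = 0.0
        out[:, i] = 0.0
        np.fill_diagonal(out, 0.0)
        return out


@dataclass
class NetworkStats:
    """Summary statistics in the style of a STRING network description table."""

    n_nodes: int
    average_degree: float
    n_components: int
    component_sizes: list[int]
    diameter: int
    weighted_diameter: float

    def to_dict(self) -> dict:
        return {
            "nodes": self.n_nodes,
            "average_degree": self.average_degree,
            "components": self.n_components,
            "component_size": self.component_sizes,
            "diameter": self.diameter,
            "weighted_diameter": self.weighted_diameter,
        }


# ---------------------------------------------------------------------------
# ingestion


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_string_edges(path, threshold: int = 700) -> RawNetwork:
    """Read a STRING-dialect edge list and threshold on the combined score.

    The file is whitespace/tab separated with three columns: two protein
    identifiers and an integer combined score in 1..999.  An optional header
    line is auto-detected (non-integer score field).  Edges below
    ``threshold`` are dropped, surviving scores are scaled by 1/1000 into raw
    weights, duplicate orientations of the same pair are collapsed
    (conflicting scores are an error), self-loops are dropped with a warning,
    and nodes left without any retained edge are removed.
    """
    if not 1 <= threshold <= 999:
        raise ValueError(f"threshold must be in [1, 999], got {threshold}")
    edges: dict[tuple[str, str], int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise NetworkDataError(f"line {lineno}: expected 3 columns, got {len(parts)}")
            a, b, score_s = parts[0], parts[1], parts[2]
            try:
                score = int(score_s)
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise NetworkDataError(f"line {lineno}: non-integer score {score_s!r}") from None
            if not 1 <= score <= 999:
                raise NetworkDataError(f"line {lineno}: score {score} outside 1..999")
            if a == b:
                logger.warning("line %d: self-loop on %s dropped", lineno, a)
                continue
            key = (a, b) if a < b else (b, a)
            if key in edges:
                if edges[key] != score:
                    raise NetworkDataError(
                        f"line {lineno}: conflicting scores for pair {key}: "
                        f"{edges[key]} vs {score}"
                    )
                continue
            edges[key] = score
    kept = {k: v for k, v in edges.items() if v >= threshold}
    labels = sorted({p for pair in kept for p in pair})
    idx = {lab: i for i, lab in enumerate(labels)}
    w = np.zeros((len(labels), len(labels)))
    for (a, b), score in kept.items():
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = score / 1000.0
    n_dropped = len(edges) - len(kept)
    if n_dropped:
        logger.info("dropped %d edges below threshold %d", n_dropped, threshold)
    return RawNetwork(node_labels=labels, weights=w)


def symmetric_normalize(raw: RawNetwork) -> WeightedNetwork:
    """Apply ``W = D^{-1/2} W_hat D^{-1/2}`` to a raw network.

    Scale-invariant: multiplying all raw weights by a positive constant
    leaves ``W`` unchanged.  Raises on isolated nodes (zero row sums).
    """
    raw.validate()
    d = raw.weights.sum(axis=1)
    if raw.n_nodes and np.any(d == 0):
        bad = [raw.node_labels[i] for i in np.flatnonzero(d == 0)][:5]
        raise NetworkDataError(f"isolated nodes present (zero row sum): {bad} ...")
    if raw.n_nodes == 0:
        return WeightedNetwork(node_labels=[], w=np.zeros((0, 0)), degree=np.zeros(0))
    inv_sqrt = 1.0 / np.sqrt(d)
    # elementwise product of two exactly-symmetric matrices keeps W
    # bit-for-bit symmetric
    w = raw.weights * np.outer(inv_sqrt, inv_sqrt)
    return WeightedNetwork(node_labels=list(raw.node_labels), w=w, degree=d)


# ---------------------------------------------------------------------------
# structure


def connected_components(net: WeightedNetwork) -> ComponentIndex:
    """Undirected connectivity over the nonzero entries of ``W``."""
    n = net.n_nodes
    if n == 0:
        return ComponentIndex(component_id=np.zeros(0, dtype=int), members=[])
    n_comp, labels = _cc(csr_matrix(net.w), directed=False)
    members = [np.flatnonzero(labels == c) for c in range(n_comp)]
    return ComponentIndex(component_id=labels, members=members)


def _edge_costs(net: WeightedNetwork, cost_mode: str) -> np.ndarray:
    if cost_mode not in COST_MODES:
        raise ValueError(f"unknown cost_mode {cost_mode!r}; choose one of {COST_MODES}")
    w = net.w
    cost = np.zeros_like(w)
    nz = w > 0
    if cost_mode == "weight_as_cost":
        cost[nz] = w[nz]
    elif cost_mode == "inverse_weight":
        cost[nz] = 1.0 / w[nz]
    elif cost_mode == "one_minus_weight":
        cost[nz] = 1.0 - w[nz]
    else:  # hop
        cost[nz] = 1.0
    return cost


def _dijkstra_count(indptr, indices, costs, n, source):
    """Single-source Dijkstra with minimum-cost path counting."""
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    dist[source] = 0.0
    sigma[source] = 1.0
    done = np.zeros(n, dtype=bool)
    heap = [(0.0, source)]
    while heap:
        du, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        for k in range(indptr[u], indptr[u + 1]):
            v = indices[k]
            alt = du + costs[k]
            if alt < dist[v] - TIE_TOL:
                dist[v] = alt
                sigma[v] = sigma[u]
                heapq.heappush(heap, (alt, v))
            elif abs(alt - dist[v]) <= TIE_TOL:
                sigma[v] += sigma[u]
    return dist, sigma


def shortest_paths(
    net: WeightedNetwork,
    comps: ComponentIndex | None = None,
    cost_mode: str = "weight_as_cost",
) -> ShortestPathCache:
    """All-pairs shortest-path distances and path counts under ``cost_mode``.

    Edge costs must be strictly positive for the path counts to be finite;
    ``one_minus_weight`` rejects networks containing unit-weight edges.
    """
    cost = _edge_costs(net, cost_mode)
    n = net.n_nodes
    nz = net.w > 0
    if np.any(cost[nz] <= TIE_TOL):
        raise NetworkDataError(
            f"cost_mode {cost_mode!r} produced non-positive edge costs; path counting undefined"
        )
    g = csr_matrix(cost)
    dist = np.zeros((n, n))
    sigma = np.zeros((n, n))
    for s in range(n):
        dist[s], sigma[s] = _dijkstra_count(g.indptr, g.indices, g.data, n, s)
    return ShortestPathCache(dist=dist, sigma=sigma, cost_mode=cost_mode)


def network_stats(
    net: WeightedNetwork,
    comps: ComponentIndex | None = None,
    paths: ShortestPathCache | None = None,
) -> NetworkStats:
    """Node count, average degree, component structure and diameters.

    The (hop) diameter is the number of edges on the longest unweighted
    shortest path; the weighted diameter is the largest finite distance in
    the supplied path cache (computed with its cost mode).
    """
    comps = comps if comps is not None else connected_components(net)
    paths = paths if paths is not None else shortest_paths(net, comps)
    n = net.n_nodes
    avg_degree = float((net.w > 0).sum(axis=1).mean()) if n else 0.0
    hop = _sp(csr_matrix((net.w > 0).astype(float)), method="D", unweighted=True, directed=False)
    finite_hop = hop[np.isfinite(hop)]
    finite_w = paths.dist[np.isfinite(paths.dist)]
    return NetworkStats(
        n_nodes=n,
        average_degree=avg_degree,
        n_components=comps.n_components,
        component_sizes=sorted(comps.sizes(), reverse=True),
        diameter=int(finite_hop.max()) if finite_hop.size else 0,
        weighted_diameter=float(finite_w.max()) if finite_w.size else 0.0,
    )
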