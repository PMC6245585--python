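"""Independent brute-force oracles used to validate the fast implementations.

These deliberately re-derive every quantity from first principles —
exhaustive simple-path enumeration for distances, path counts and
centralities, and direct Monte-Carlo walk simulation for the random-walk
features — so they share no code with the package internals.
"""

from __future__ import annotations

import numpy as np

TOL = 1e-12


def edge_cost(w: np.ndarray, mode: str) -> np.ndarray:
    c = np.zeros_like(w)
    nz = w > 0
    if mode == "weight_as_cost":
        c[nz] = w[nz]
    elif mode == "inverse_weight":
        c[nz] = 1.0 / w[nz]
    elif mode == "one_minus_weight":
        c[nz] = 1.0 - w[nz]
    else:
        c[nz] = 1.0
    return c


def enumerate_shortest(w: np.ndarray, mode: str = "weight_as_cost"):
    """All-pairs distances, path counts and through-counts by enumerating
    every simple path (feasible for n <= 8)."""
    n = len(w)
    cost = edge_cost(w, mode)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    through = np.zeros((n, n, n))  # through[i, s, t]
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = []
            stack = [(s, (s,), 0.0)]
            while stack:
                node, path, c = stack.pop()
                if node == t:
                    paths.append((c, path))
                    continue
                for v in range(n):
                    if w[node, v] > 0 and v not in path:
                        stack.append((v, path + (v,), c + cost[node, v]))
            if not paths:
                continue
            best = min(c for c, _ in paths)
            shortest = [p for c, p in paths if c <= best + TOL]
            dist[s, t] = best
            sigma[s, t] = len(shortest)
            for p in shortest:
                for i in p[1:-1]:
                    through[i, s, t] += 1
    return dist, sigma, through


def brute_centralities(w: np.ndarray, mode: str = "weight_as_cost") -> np.ndarray:
    """Closeness, Lin's index, harmonic and betweenness from the enumerator."""
    n = len(w)
    dist, sigma, through = enumerate_shortest(w, mode)
    out = np.zeros((n, 4))
    for i in range(n):
        comp = [j for j in range(n) if np.isfinite(dist[i, j])]
        s = sum(dist[i, j] for j in comp)
        out[i, 0] = 1.0 / s
        out[i, 1] = len(comp) ** 2 / s
        out[i, 2] = sum(1.0 / dist[i, j] for j in comp if j != i)
        btw = 0.0
        for s_ in range(n):
            for t_ in range(s_ + 1, n):
                if s_ == i or t_ == i or sigma[s_, t_] == 0:
                    continue
                btw += through[i, s_, t_] / sigma[s_, t_]
        out[i, 3] = btw
    return out


def brute_positive_centralities(
    w: np.ndarray, positives: np.ndarray, mode: str = "weight_as_cost"
) -> np.ndarray:
    """Positive closeness / Lin / harmonic from the enumerator."""
    n = len(w)
    dist, _, _ = enumerate_shortest(w, mode)
    pos = set(int(p) for p in positives)
    out = np.zeros((n, 3))
    for i in range(n):
        comp_pos = [j for j in range(n) if np.isfinite(dist[i, j]) and j in pos]
        others = [j for j in comp_pos if j != i]
        if not others:
            continue
        s = sum(dist[i, j] for j in others)
        out[i, 0] = 1.0 / s
        out[i, 1] = len(comp_pos) ** 2 / s
        out[i, 2] = sum(1.0 / dist[i, j] for j in others)
    return out


def simulate_walk_endpoints(
    w: np.ndarray, positives: np.ndarray, walks_per_node: int, seed: int
) -> np.ndarray:
    """Monte-Carlo estimate of the 3Prop features.

    The feature for node ``i`` and walk length ``j`` is
    ``(1/p) * Pr[a j-step walk started at i is at a positive node]`` with
    ``p`` positives, estimated by simulating ``walks_per_node`` walks from
    every start node and recording positive-set occupancy at steps 1-3.
    """
    rng = np.random.default_rng(seed)
    n = len(w)
    p = w / w.sum(axis=1, keepdims=True)
    cum = np.cumsum(p, axis=1)
    pos_mask = np.zeros(n, dtype=bool)
    pos_mask[np.asarray(positives)] = True
    current = np.repeat(np.arange(n), walks_per_node)
    start = current.copy()
    hits = np.zeros((n, 3))
    for step in range(3):
        u = rng.random(len(current))
        nxt = np.empty(len(current), dtype=int)
        for node in range(n):
            m = current == node
            if m.any():
                nxt[m] = np.searchsorted(cum[node], u[m])
        current = nxt
        np.add.at(hits[:, step], start[pos_mask[current]], 1.0)
    return hits / (walks_per_node * pos_mask.sum())


def random_connected_graph(rng: np.random.Generator, n: int, p: float = 0.5) -> np.ndarray:
    """Random symmetric weighted graph with no isolated node (weights in (0,1])."""
    while True:
        mask = np.triu(rng.random((n, n)) < p, k=1)
        w = np.zeros((n, n))
        vals = rng.uniform(0.05, 1.0, size=mask.sum())
        w[mask] = vals
        w = w + w.T
        deg = (w > 0).sum(axis=1)
        if deg.min() >= 1:
            return w
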