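"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths they check: geodesics are enumerated
from a dense distance/path-count matrix, the eigenvector comes from a dense
symmetric eigensolver, PageRank from a dense linear solve, and the contagion
state distribution from exact Markov-chain enumeration over all influence
bitmasks.
"""

from __future__ import annotations

import networkx as nx
import numpy as np


def distances_and_path_counts(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs BFS distances and numbers of geodesics (dense, tiny graphs)."""
    n = len(adj)
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        dist[s, s] = 0.0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(adj[u]):
                    if np.isinf(dist[s, v]):
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
        sigma[s, s] = 1.0
        for v in np.argsort(dist[s]):
            if v == s or np.isinf(dist[s, v]):
                continue
            preds = [u for u in np.flatnonzero(adj[v])
                     if dist[s, u] == dist[s, v] - 1]
            sigma[s, v] = sum(sigma[s, u] for u in preds)
    return dist, sigma


def brute_betweenness(adj: np.ndarray, normalized: bool = True) -> np.ndarray:
    n = len(adj)
    dist, sigma = distances_and_path_counts(adj)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if np.isinf(dist[s, t]):
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    if normalized and n > 2:
        bc /= (n - 1) * (n - 2) / 2
    return bc


def brute_closeness(adj: np.ndarray) -> np.ndarray:
    """Wasserman–Faust closeness: ((r-1)/(n-1)) * ((r-1)/sum d)."""
    n = len(adj)
    dist, _ = distances_and_path_counts(adj)
    out = np.zeros(n)
    for u in range(n):
        reach = np.isfinite(dist[u]) & (np.arange(n) != u)
        r = reach.sum()
        if r == 0:
            continue
        total = dist[u, reach].sum()
        out[u] = (r / (n - 1)) * (r / total) if n > 1 else 0.0
    return out


def brute_eigenvector(adj: np.ndarray) -> np.ndarray:
    """Perron vector of the largest-spectral-radius component, max-normed."""
    g = nx.from_numpy_array(adj)
    best = None
    for comp in sorted(nx.connected_components(g), key=min):
        nodes = sorted(comp)
        sub = adj[np.ix_(nodes, nodes)]
        vals, vecs = np.linalg.eigh(sub)
        radius = vals[-1]
        vec = np.abs(vecs[:, -1])
        if best is None or radius > best[0] + 1e-12:
            best = (radius, nodes, vec)
    _, nodes, vec = best
    out = np.zeros(len(adj))
    out[nodes] = vec / vec.max() if vec.max() > 0 else vec
    return out


def brute_pagerank(adj: np.ndarray, damping: float = 0.85) -> np.ndarray:
    """Dense linear solve of x = d M x + (1-d)/n, M column-stochastic."""
    n = len(adj)
    deg = adj.sum(axis=1)
    m = np.zeros((n, n))
    for v in range(n):
        if deg[v] > 0:
            m[:, v] = adj[:, v] / deg[v]
        else:  # dangling node: uniform teleport
            m[:, v] = 1.0 / n
    x = np.linalg.solve(np.eye(n) - damping * m, np.full(n, (1 - damping) / n))
    return x / x.sum()


def connected_atlas_graphs(min_nodes: int = 3, max_nodes: int = 7):
    """All connected simple graphs with min_nodes..7 nodes (graph atlas)."""
    from networkx.generators.atlas import graph_atlas_g
    for g in graph_atlas_g():
        n = g.number_of_nodes()
        if min_nodes <= n <= max_nodes and n > 0 and nx.is_connected(g):
            yield g


def random_connected_graphs(n_nodes: int, count: int, seed: int):
    """Seeded sample of connected Erdos-Renyi graphs on ``n_nodes`` nodes."""
    rng = np.random.default_rng(seed)
    made = 0
    while made < count:
        p = rng.uniform(0.25, 0.7)
        g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            made += 1
            yield g


# ---------------------------------------------------------------------------
# Exact contagion chain (per-tick reversion; state = influence bitmask)
# ---------------------------------------------------------------------------


def exact_state_distribution(adj: np.ndarray, seed_nodes: set[int],
                             spread: np.ndarray, resistance: np.ndarray,
                             seeds_immune: bool, n_ticks: int) -> dict[int, float]:
    """Distribution over influence bitmasks after ``n_ticks`` synchronous
    ticks under per-tick reversion.  ``spread[u, v]`` is the per-tick
    transmission probability on edge (u, v)."""
    n = len(adj)
    seed_mask = sum(1 << u for u in seed_nodes)
    dist = {seed_mask: 1.0}
    for _ in range(n_ticks):
        nxt: dict[int, float] = {}
        for state, prob in dist.items():
            inf = [(state >> u) & 1 for u in range(n)]
            p_gain = np.zeros(n)
            for u in range(n):
                if inf[u]:
                    continue
                stay = 1.0
                for v in np.flatnonzero(adj[u]):
                    if inf[v]:
                        stay *= 1.0 - spread[u, v]
                p_gain[u] = 1.0 - stay
            # per-node probability of being influenced at the next tick;
            # bits are conditionally independent given the current state
            p_on = np.zeros(n)
            for u in range(n):
                if inf[u]:
                    immune = seeds_immune and (seed_mask >> u) & 1
                    p_on[u] = 1.0 if immune else 1.0 - resistance[u]
                else:
                    p_on[u] = p_gain[u]
            for new_state in range(1 << n):
                p = prob
                for u in range(n):
                    bit = (new_state >> u) & 1
                    p *= p_on[u] if bit else 1.0 - p_on[u]
                    if p == 0.0:
                        break
                if p > 0.0:
                    nxt[new_state] = nxt.get(new_state, 0.0) + p
        dist = nxt
    return dist
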