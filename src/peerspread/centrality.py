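"""Seed selection: four centrality measures plus a random control.

The intervention assigns the top 15% most central agents as the initially
influential ("trained") agents.  Four standard definitions are supported —
shortest-path betweenness, (Wasserman–Faust) closeness, eigenvector centrality
obtained by power iteration and max-normalized to 1, and undirected PageRank
with damping 0.85 (the walker teleports 15% of the time, and the scores sum to
~1 regardless of connectivity) — together with uniform random selection used
as the validation condition.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "CentralityScores",
    "SeedSet",
    "ConvergenceError",
    "betweenness",
    "closeness",
    "eigenvector",
    "pagerank",
    "centrality_scores",
    "select_top_seeds",
    "select_random_seeds",
    "write_scores_csv",
    "MEASURES",
]

MEASURES = ("betweenness", "closeness", "eigenvector", "pagerank")


class ConvergenceError(RuntimeError):
    pass


@dataclass
class CentralityScores:
    measure: str
    scores: dict[int, float]
    meta: dict = field(default_factory=dict)

    def ranked(self) -> list[int]:
        """Node ids from highest to lowest score (ties by lowest id)."""
        return sorted(self.scores, key=lambda u: (-self.scores[u], u))


@dataclass(frozen=True)
class SeedSet:
    nodes: frozenset[int]
    fraction: float
    measure: str

    def __len__(self) -> int:
        return len(self.nodes)


def betweenness(net: nx.Graph, normalized: bool = True) -> CentralityScores:
    """Shortest-path betweenness with fractional credit for tied geodesics."""
    n = net.number_of_nodes()
    if normalized and n < 3:
        raise ValueError("normalized betweenness needs at least 3 nodes")
    scores = nx.betweenness_centrality(net, normalized=normalized)
    return CentralityScores("betweenness", {u: float(s) for u, s in scores.items()},
                            meta={"normalized": normalized})


def closeness(net: nx.Graph) -> CentralityScores:
    """Closeness as (n_reachable-1)/sum(distances), component-size-scaled.

    On disconnected graphs the Wasserman–Faust scaling multiplies by the
    reachable share (r-1)/(n-1); isolated nodes score 0 and are flagged.
    """
    scores = nx.closeness_centrality(net, wf_improved=True)
    isolated = [u for u in net.nodes if net.degree(u) == 0]
    return CentralityScores("closeness", {u: float(s) for u, s in scores.items()},
                            meta={"isolated_nodes": isolated,
                                  "component_size_scaled": True})


def eigenvector(net: nx.Graph, max_iter: int = 50000,
                tol: float = 1e-10) -> CentralityScores:
    """Eigenvector centrality by power iteration, max-normalized to 1.

    Starting from a uniform positive vector, the adjacency operator is applied
    and the iterate L2-normalized each step; convergence is declared when
    successive iterates differ by less than ``tol`` in max-norm.  The final
    scores are rescaled so the maximum is exactly 1.  On a disconnected graph
    the scores concentrate on the component with the largest spectral radius
    (flagged in ``meta``); other components score 0.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    components = sorted(nx.connected_components(net), key=min)
    best = None  # (spectral radius, component nodes, scores)
    for comp in components:
        nodes = sorted(comp)
        n = len(nodes)
        if n == 1:
            radius, x = 0.0, np.ones(1)
        else:
            a = nx.to_scipy_sparse_array(net.subgraph(nodes), nodelist=nodes,
                                         format="csr", dtype=float)
            # iterate on A + I: same eigenvectors, but the spectrum is shifted
            # positive so the Perron gap is strict and bipartite +/-lambda
            # pairs cannot oscillate
            x = np.full(n, 1.0 / np.sqrt(n))
            for _ in range(max_iter):
                y = a @ x + x
                norm = np.linalg.norm(y)
                y = x if norm == 0 else y / norm
                done = np.max(np.abs(y - x)) < tol
                x = y
                if done:
                    break
            else:
                raise ConvergenceError(
                    "power iteration did not converge; raise max_iter or "
                    "loosen tol"
                )
            radius = float(x @ (a @ x))
        if best is None or radius > best[0]:
            best = (radius, nodes, x)
    _, dom_nodes, x = best
    if x.max() > 0:
        x = x / x.max()
    scores = {u: 0.0 for u in net.nodes}
    scores.update(dict(zip(dom_nodes, map(float, x))))
    return CentralityScores("eigenvector", scores,
                            meta={"dominant_component_only": len(components) > 1})


def pagerank(net: nx.Graph, damping: float = 0.85, tol: float = 1e-10,
             max_iter: int = 500) -> CentralityScores:
    """Undirected PageRank (each edge is two directed links); sums to 1."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    try:
        scores = nx.pagerank(net, alpha=damping, tol=tol, max_iter=max_iter)
    except nx.PowerIterationFailedConvergence as exc:  # pragma: no cover
        raise ConvergenceError("PageRank power iteration did not converge") from exc
    return CentralityScores("pagerank", {u: float(s) for u, s in scores.items()},
                            meta={"damping": damping})


def centrality_scores(net: nx.Graph, measure: str, **kwargs) -> CentralityScores:
    """Dispatch by measure name ('betweenness'/'closeness'/'eigenvector'/'pagerank')."""
    funcs = {"betweenness": betweenness, "closeness": closeness,
             "eigenvector": eigenvector, "pagerank": pagerank}
    if measure not in funcs:
        raise ValueError(f"unknown centrality measure {measure!r}")
    return funcs[measure](net, **kwargs)


def select_top_seeds(scores: CentralityScores, fraction: float = 0.15,
                     tiebreak: str = "lowest_id",
                     seed: int | None = None) -> SeedSet:
    """The floor(fraction*n) highest-scoring nodes.

    Ties at the cut are broken deterministically by lowest node id (default)
    or by a seeded random permutation.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    n = len(scores.scores)
    n_seeds = int(np.floor(fraction * n))
    if tiebreak == "lowest_id":
        ranked = scores.ranked()
    elif tiebreak == "random":
        rng = np.random.default_rng(seed)
        jitter = {u: r for u, r in zip(sorted(scores.scores), rng.permutation(n))}
        ranked = sorted(scores.scores, key=lambda u: (-scores.scores[u], jitter[u]))
    else:
        raise ValueError(f"unknown tiebreak {tiebreak!r}")
    return SeedSet(frozenset(ranked[:n_seeds]), fraction, scores.measure)


def select_random_seeds(net: nx.Graph, fraction: float = 0.15,
                        seed: int | None = None) -> SeedSet:
    """Uniform sample without replacement of floor(fraction*n) nodes."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    nodes = np.array(sorted(net.nodes))
    n_seeds = int(np.floor(fraction * len(nodes)))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(nodes, size=n_seeds, replace=False)
    return SeedSet(frozenset(int(u) for u in chosen), fraction, "random")


def write_scores_csv(net: nx.Graph, scores: CentralityScores,
                     seeds: SeedSet, path) -> None:
    ranked = scores.ranked()
    rank = {u: i + 1 for i, u in enumerate(ranked)}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_id", "gender", "measure", "score", "rank", "is_seed"])
        for u in sorted(scores.scores):
            writer.writerow([u, net.nodes[u].get("gender", ""), scores.measure,
                             f"{scores.scores[u]:.10g}", rank[u],
                             int(u in seeds.nodes)])
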