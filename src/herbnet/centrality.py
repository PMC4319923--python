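"""Node centralities on the weighted ingredient network.

Four measures per node: weighted degree (strength), closeness, betweenness
and eigenvector centrality.  For the two shortest-path measures edge
*length* defaults to the reciprocal of the edge weight — a strongly
co-prescribed ingredient pair is "close" — with an ``ignore`` convention
available to treat all edges as unit length.  Closeness is component-local,
(n_c − 1)/Σ d within each connected component; betweenness is unnormalized
Brandes betweenness with fractional credit for tied shortest paths;
eigenvector centrality is the Perron vector of the weight matrix, computed
by shifted power iteration per component and reported with the dominant
component's maximum scaled to 1 and other components scaled down by their
spectral-radius ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .model import ConvergenceError, ValidationError
from .communities import Partition

__all__ = ["compute_centralities", "rank_top_k", "gatekeepers", "RankingTable"]

MEASURES = ("weighted_degree", "closeness", "betweenness", "eigenvector")


def _eigenvector_scores(
    graph: nx.Graph, nodes: list[str], tol: float, max_iter: int
) -> pd.Series:
    index = {n: i for i, n in enumerate(nodes)}
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight="weight", format="csr")
    scores = np.zeros(len(nodes))
    lambdas: list[tuple[float, np.ndarray, list[int]]] = []
    for comp in nx.connected_components(graph):
        idx = sorted(index[n] for n in comp)
        if len(idx) == 1:
            lambdas.append((0.0, np.zeros(1), idx))
            continue
        a = adj[np.ix_(idx, idx)].tocsr()
        # identity shift breaks the period-2 oscillation on bipartite
        # components without changing the leading eigenvector
        v = np.full(len(idx), 1.0 / np.sqrt(len(idx)))
        for _ in range(max_iter):
            nxt = a @ v + v
            norm = np.linalg.norm(nxt)
            if norm == 0:
                break
            nxt /= norm
            if np.abs(nxt - v).max() < tol:
                v = nxt
                break
            v = nxt
        else:
            raise ConvergenceError(
                f"eigenvector power iteration did not converge in {max_iter} "
                "iterations; raise max_iter or loosen tol"
            )
        lam = float(v @ (a @ v))
        lambdas.append((max(lam, 0.0), v, idx))
    lam_max = max((l for l, _, _ in lambdas), default=0.0)
    for lam, v, idx in lambdas:
        if lam_max > 0 and lam > 0 and v.max() > 0:
            scores[idx] = v / v.max() * (lam / lam_max)
    return pd.Series(scores, index=nodes)


def compute_centralities(
    graph: nx.Graph,
    weight_convention: str = "inverse",
    closeness_mode: str = "component",
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Compute the four centralities for every node of a weighted graph.

    ``weight_convention``: ``inverse`` (edge length 1/weight for closeness
    and betweenness) or ``ignore`` (unit lengths).  ``closeness_mode``:
    ``component`` for (n_c − 1)/Σ d within the node's component, or
    ``harmonic`` for Σ 1/d over all other nodes.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("cannot compute centralities on an empty graph")
    if weight_convention not in ("inverse", "ignore"):
        raise ValidationError(f"unknown weight convention {weight_convention!r}")
    if closeness_mode not in ("component", "harmonic"):
        raise ValidationError(f"unknown closeness mode {closeness_mode!r}")
    nodes = sorted(graph.nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    edges = [(pos[u], pos[v]) for u, v in graph.edges]
    weights = np.array([graph[u][v]["weight"] for u, v in graph.edges], dtype=float)
    lengths = (1.0 / weights if weight_convention == "inverse" else
               np.ones_like(weights))
    g = ig.Graph(n=len(nodes), edges=edges)

    strength = pd.Series(
        [float(graph.degree(n, weight="weight")) for n in nodes], index=nodes
    )
    len_arg = list(lengths) if edges else None
    if closeness_mode == "component":
        clo = g.closeness(weights=len_arg, normalized=True) if len(nodes) > 1 else [0.0]
        closeness = pd.Series(clo, index=nodes).fillna(0.0)
    else:
        clo = g.harmonic_centrality(weights=len_arg, normalized=False)
        closeness = pd.Series(clo, index=nodes).fillna(0.0)
    btw = g.betweenness(weights=len_arg) if edges else [0.0] * len(nodes)
    betweenness = pd.Series([float(b) for b in btw], index=nodes)
    eigen = _eigenvector_scores(graph, nodes, tol, max_iter)

    return pd.DataFrame(
        {
            "weighted_degree": strength,
            "closeness": closeness,
            "betweenness": betweenness,
            "eigenvector": eigen,
        }
    )


@dataclass(frozen=True)
class RankingTable:
    """Top-k nodes per centrality plus pairwise top-k set overlaps."""

    k: int
    rankings: dict[str, list[tuple[str, float]]]
    overlap: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"centrality": c, "rank": i + 1, "node": n, "score": s}
            for c, ranked in self.rankings.items()
            for i, (n, s) in enumerate(ranked)
        ]
        return pd.DataFrame(rows, columns=["centrality", "rank", "node", "score"])


def rank_top_k(table: pd.DataFrame, k: int = 50) -> RankingTable:
    """Rank nodes per centrality and cross-compare the top-k sets.

    Descending score order with lexicographic node-id tie-break; the
    overlap between two centralities is |top-k ∩ top-k| / k.  ``k`` larger
    than the node count is clamped with a warning.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    n = len(table)
    if k > n:
        warnings.warn(f"k={k} exceeds node count {n}; clamping", stacklevel=2)
        k = n
    rankings: dict[str, list[tuple[str, float]]] = {}
    for col in table.columns:
        ordered = sorted(table[col].items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        rankings[col] = [(node, float(score)) for node, score in ordered]
    cols = list(table.columns)
    overlap = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            sa = {node for node, _ in rankings[a]}
            sb = {node for node, _ in rankings[b]}
            overlap.loc[a, b] = overlap.loc[b, a] = len(sa & sb) / k
    return RankingTable(k=k, rankings=rankings, overlap=overlap)


def gatekeepers(
    graph: nx.Graph,
    partition: Partition,
    table: pd.DataFrame,
    top_k: int = 10,
) -> list[dict]:
    """High-betweenness nodes whose neighborhoods bridge communities.

    Among the ``top_k`` nodes by betweenness, returns those whose
    neighbors span at least two communities, annotated with the bridged
    community ids, in decreasing betweenness order.
    """
    ranked = sorted(table["betweenness"].items(), key=lambda kv: (-kv[1], kv[0]))
    out: list[dict] = []
    for node, btw in ranked[: min(top_k, len(ranked))]:
        comms = sorted({partition.assignment[nb] for nb in graph.neighbors(node)})
        if len(comms) >= 2:
            out.append(
                {"node": node, "betweenness": float(btw), "communities": comms}
            )
    return out
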