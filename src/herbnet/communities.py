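"""Modularity community detection on weighted graphs.

Communities are found with the two-phase multilevel (Louvain) heuristic:
repeated local moves that greedily improve weighted modularity, followed by
aggregation of communities into super-nodes, iterated to convergence.  The
heuristic is randomized, so :func:`detect_communities` runs several seeded
restarts with shuffled node order and keeps the partition with the highest
modularity, making runs reproducible given a seed.  Modularity itself is
evaluated exactly and independently of the heuristic's bookkeeping by
:func:`modularity`.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Mapping

import igraph as ig
import networkx as nx

from .model import HerbnetError, ValidationError

__all__ = ["Partition", "modularity", "detect_communities", "components"]


@dataclass(frozen=True)
class Partition:
    """A node → community assignment with its modularity score.

    Community ids are contiguous integers from 1, ordered by decreasing
    community size (ties by lexicographically smallest member list).
    """

    assignment: Mapping[str, int]
    n_communities: int
    Q: float

    def communities(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.n_communities)]
        for node, cid in self.assignment.items():
            out[cid - 1].add(node)
        return out

    def community_of(self, node: str) -> int:
        return self.assignment[node]


def _canonical(groups: Iterable[set[str]], graph: nx.Graph, q: float) -> Partition:
    ordered = sorted((g for g in groups if g), key=lambda g: (-len(g), sorted(g)))
    assignment = {n: i + 1 for i, g in enumerate(ordered) for n in sorted(g)}
    return Partition(assignment=assignment, n_communities=len(ordered), Q=q)


def modularity(
    graph: nx.Graph,
    partition: Partition | Mapping[str, int],
    resolution: float = 1.0,
) -> float:
    """Exact weighted Newman–Girvan modularity of a partition.

    Q = (1/2W) Σ_ij [w_ij − γ·s_i s_j / 2W] δ(c_i, c_j) with W the total
    edge weight, s_i the node strength and γ the resolution.  A graph with
    no edges has Q = 0 by convention.
    """
    assignment = partition.assignment if isinstance(partition, Partition) else partition
    missing = [n for n in graph.nodes if n not in assignment]
    if missing:
        raise ValidationError(f"nodes missing from partition: {sorted(missing)[:5]}")
    two_w = 2.0 * graph.size(weight="weight")
    if two_w == 0:
        return 0.0
    internal: dict[int, float] = {}
    strength: dict[int, float] = {}
    for u, v, data in graph.edges(data=True):
        if assignment[u] == assignment[v]:
            internal[assignment[u]] = internal.get(assignment[u], 0.0) + data["weight"]
    for n, s in graph.degree(weight="weight"):
        c = assignment[n]
        strength[c] = strength.get(c, 0.0) + s
    q = 0.0
    for c, s in strength.items():
        q += 2.0 * internal.get(c, 0.0) / two_w - resolution * (s / two_w) ** 2
    return q


def _split_by_component(
    groups: list[set[str]], comp_of: Mapping[str, int]
) -> list[set[str]]:
    out: list[set[str]] = []
    for g in groups:
        parts: dict[int, set[str]] = {}
        for n in g:
            parts.setdefault(comp_of[n], set()).add(n)
        out.extend(parts.values())
    return out


def detect_communities(
    graph: nx.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    restarts: int = 10,
) -> Partition:
    """Louvain-style community detection with seeded restarts.

    Runs ``restarts`` multilevel optimizations, each with a reseeded RNG
    and shuffled node order, and returns the partition with the largest
    exact modularity (at the given resolution); ties are broken by fewer
    communities, then by lexicographic node order.  Isolated nodes become
    singleton communities, and no returned community ever spans two
    connected components.  The reported ``Q`` is the plain (resolution-1)
    modularity of the returned partition.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("cannot detect communities on an empty graph")
    nodes = sorted(graph.nodes)
    comp_of = {
        n: i for i, comp in enumerate(nx.connected_components(graph)) for n in comp
    }
    state = random.getstate()
    best_key: tuple | None = None
    best: list[set[str]] | None = None
    try:
        for t in range(max(1, restarts)):
            rng = random.Random((int(seed) << 16) + t)
            order = list(nodes)
            rng.shuffle(order)
            pos = {n: i for i, n in enumerate(order)}
            g = ig.Graph(
                n=len(order),
                edges=[(pos[u], pos[v]) for u, v in graph.edges],
            )
            weights = [graph[u][v]["weight"] for u, v in graph.edges]
            random.seed((int(seed) << 16) + t)
            clustering = g.community_multilevel(
                weights=weights or None, resolution=resolution
            )
            groups: dict[int, set[str]] = {}
            for i, cid in enumerate(clustering.membership):
                groups.setdefault(cid, set()).add(order[i])
            cand = _split_by_component(list(groups.values()), comp_of)
            q_obj = modularity(graph, _canonical(cand, graph, 0.0), resolution)
            part = _canonical(cand, graph, q_obj)
            key = (
                -round(q_obj, 12),
                part.n_communities,
                tuple(part.assignment[n] for n in nodes),
            )
            if best_key is None or key < best_key:
                best_key, best = key, part.communities()
    finally:
        random.setstate(state)
    assert best is not None

    # never return less than the trivial baselines
    singletons = [{n} for n in nodes]
    comps = [set() for _ in range(len(set(comp_of.values())))]
    for n, c in comp_of.items():
        comps[c].add(n)
    best_q = modularity(graph, _canonical(best, graph, 0.0), resolution)
    for base in (comps, singletons):
        q = modularity(graph, _canonical(base, graph, 0.0), resolution)
        if q > best_q + 1e-12:
            best, best_q = base, q

    return _canonical(best, graph, modularity(graph, _canonical(best, graph, 0.0)))


def components(graph: nx.Graph) -> Partition:
    """Partition of a graph into its connected components."""
    groups = [set(c) for c in nx.connected_components(graph)]
    if not groups:
        return Partition(assignment={}, n_communities=0, Q=0.0)
    q = modularity(graph, _canonical(groups, graph, 0.0))
    return _canonical(groups, graph, q)
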