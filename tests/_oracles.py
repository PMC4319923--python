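"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: explicit pair enumeration, Floyd-
Warshall distances, dense eigendecompositions.  None of it shares code
with the production paths it checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

TOL = 1e-9


def naive_project(herb_graph, catalog):
    """Accumulate union-pair weights by explicit enumeration."""
    acc: dict[tuple[str, str], float] = {}
    for a, b in herb_graph.edges:
        w = herb_graph[a][b]["weight"]
        union = sorted(catalog.herb_to_ingredients[a] | catalog.herb_to_ingredients[b])
        for i, j in itertools.combinations(union, 2):
            acc[(i, j)] = acc.get((i, j), 0) + w
    return acc


def naive_herb_weights(formulae):
    """Count co-occurrences by a double loop over formulae × herb pairs."""
    acc: dict[tuple[str, str], int] = {}
    for f in formulae:
        for a, b in itertools.combinations(sorted(f.herbs), 2):
            acc[(a, b)] = acc.get((a, b), 0) + 1
    return acc


def union_pair_count(m, n, r):
    """C(m+n-r, 2) by materializing the union and counting pairs."""
    set_a = {f"a{i}" for i in range(m - r)} | {f"s{i}" for i in range(r)}
    set_b = {f"b{i}" for i in range(n - r)} | {f"s{i}" for i in range(r)}
    return len(list(itertools.combinations(set_a | set_b, 2)))


def naive_modularity(graph, assignment):
    """Direct double sum over all node pairs."""
    nodes = list(graph.nodes)
    two_w = 2.0 * graph.size(weight="weight")
    if two_w == 0:
        return 0.0
    strength = {n: graph.degree(n, weight="weight") for n in nodes}
    q = 0.0
    for i in nodes:
        for j in nodes:
            if assignment[i] != assignment[j]:
                continue
            w = graph[i][j]["weight"] if graph.has_edge(i, j) else 0.0
            q += w - strength[i] * strength[j] / two_w
    return q / two_w


def _floyd_warshall(nodes, lengths):
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for (i, j), ln in lengths.items():
        d[i, j] = d[j, i] = min(d[i, j], ln)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def naive_centralities(graph, weight_convention="inverse"):
    """All four centralities from first principles (small graphs only).

    Distances by Floyd-Warshall, shortest-path counts by dynamic
    programming over increasing distance, eigenvector by dense
    eigendecomposition per component with spectral-radius scaling.
    """
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    lengths = {}
    for u, v, data in graph.edges(data=True):
        ln = 1.0 / data["weight"] if weight_convention == "inverse" else 1.0
        lengths[(idx[u], idx[v])] = ln
    d = _floyd_warshall(nodes, lengths)

    # shortest-path counts sigma[s, t]
    sigma = np.zeros((n, n))
    for s in range(n):
        order = np.argsort(d[s])
        sigma[s, s] = 1.0
        for t in order:
            if t == s or not np.isfinite(d[s, t]):
                continue
            total = 0.0
            for u_, ln in (
                (u2, l2) for (i2, j2), l2 in lengths.items()
                for u2, v2 in ((i2, j2), (j2, i2)) if v2 == t
            ):
                if abs(d[s, u_] + ln - d[s, t]) < TOL:
                    total += sigma[s, u_]
            sigma[s, t] = total

    strength = np.array([graph.degree(nd, weight="weight") for nd in nodes], float)
    closeness = np.zeros(n)
    for s in range(n):
        reach = [t for t in range(n) if t != s and np.isfinite(d[s, t])]
        if reach:
            closeness[s] = len(reach) / sum(d[s, t] for t in reach)
    betweenness = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if abs(d[s, v] + d[v, t] - d[s, t]) < TOL:
                    betweenness[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]

    import networkx as nx

    adj = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    eig = np.zeros(n)
    comps = []
    for comp in nx.connected_components(graph):
        ids = sorted(idx[c] for c in comp)
        if len(ids) == 1:
            comps.append((0.0, np.zeros(1), ids))
            continue
        vals, vecs = np.linalg.eigh(adj[np.ix_(ids, ids)])
        lam = vals[-1]
        v = np.abs(vecs[:, -1])
        comps.append((max(lam, 0.0), v, ids))
    lam_max = max((l for l, _, _ in comps), default=0.0)
    for lam, v, ids in comps:
        if lam_max > 0 and lam > 0 and v.max() > 0:
            eig[ids] = v / v.max() * (lam / lam_max)

    return {
        nodes[i]: {
            "weighted_degree": strength[i],
            "closeness": closeness[i],
            "betweenness": betweenness[i],
            "eigenvector": eig[i],
        }
        for i in range(n)
    }
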