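"""One-mode projection of the herb network onto the ingredient plane.

Each herb edge {A, B} with weight w is expanded into every unordered pair
of distinct ingredients drawn from the *union* of A's and B's ingredient
sets — intra-herb pairs included — and each such ingredient pair gains w.
A herb pair whose member herbs contain m and n ingredients with r shared
therefore contributes C(m+n-r, 2) ingredient pairs, and the final weight of
an ingredient edge is the sum of w over every herb edge whose union
contains both endpoints.

The production path accumulates all contributions at once through a sparse
union-membership incidence matrix: with U the (ingredient × herb-edge)
0/1 matrix of union membership and w the herb-edge weight vector, the
ingredient weight matrix is U·diag(w)·Uᵀ with its diagonal discarded.
This is algebraically identical to naive pair enumeration but does not
loop over the ~C(m+n-r,2) pairs of each herb edge in Python.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Any

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .model import IngredientCatalog, ValidationError, validate_weighted_graph

__all__ = ["pair_edge_count", "project", "ProjectionReport"]


def pair_edge_count(m: int, n: int, r: int) -> int:
    """Number of ingredient pairs generated by one herb pair.

    ``m`` and ``n`` are the ingredient counts of the two herbs and ``r``
    the number of ingredients they share; the union has m+n-r members, so
    the pair contributes C(m+n-r, 2) = (m+n-r)(m+n-r-1)/2 ingredient edges.
    """
    if m < 1 or n < 1:
        raise ValidationError(f"herb ingredient counts must be >= 1, got m={m}, n={n}")
    if r < 0 or r > min(m, n):
        raise ValidationError(f"shared count r={r} outside [0, min(m, n)={min(m, n)}]")
    return comb(m + n - r, 2)


@dataclass
class ProjectionReport:
    """Bookkeeping of one projection run.

    ``per_pair`` records, for every projected herb edge, the counts
    (m, n, r) and the C(m+n-r, 2) ingredient pairs it generated;
    ``total_contributions`` is Σ w·C(m+n-r, 2), an upper bound on (and
    conservation partner of) the number of distinct ingredient edges.
    """

    n_herb_edges_projected: int = 0
    n_ingredient_edges: int = 0
    max_weight: float = 0.0
    total_contributions: float = 0.0
    per_pair: list[dict[str, Any]] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_herb_edges_projected": self.n_herb_edges_projected,
            "n_ingredient_edges": self.n_ingredient_edges,
            "max_weight": self.max_weight,
            "total_contributions": self.total_contributions,
            "per_pair": self.per_pair,
        }


def project(
    herb_graph: nx.Graph,
    catalog: IngredientCatalog,
    include_isolated_herbs: bool = False,
) -> tuple[nx.Graph, ProjectionReport]:
    """Project a herb co-occurrence graph onto its ingredient plane.

    Returns the weighted ingredient graph and a :class:`ProjectionReport`.
    Vertices are all ingredients of herbs incident to at least one herb
    edge; ingredients of isolated herbs are added as isolated vertices only
    when ``include_isolated_herbs`` is set.  Nodes carry their structural
    type as an attribute.
    """
    validate_weighted_graph(herb_graph)
    connected_herbs = sorted({h for e in herb_graph.edges for h in e})
    missing = [h for h in connected_herbs if h not in catalog.herb_to_ingredients]
    if missing:
        raise ValidationError(
            f"herbs with edges but no catalog entry: {missing[:5]}"
        )

    node_ids = sorted(catalog.ingredients_of(connected_herbs))
    if include_isolated_herbs:
        isolated = [
            h for h in herb_graph.nodes
            if herb_graph.degree(h) == 0 and h in catalog.herb_to_ingredients
        ]
        node_ids = sorted(set(node_ids) | catalog.ingredients_of(isolated))
    index = {iid: i for i, iid in enumerate(node_ids)}

    herb_edges = sorted((min(u, v), max(u, v)) for u, v in herb_graph.edges)
    report = ProjectionReport(n_herb_edges_projected=len(herb_edges))

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    weights = np.zeros(len(herb_edges))
    for j, (a, b) in enumerate(herb_edges):
        w = herb_graph[a][b]["weight"]
        ia = catalog.herb_to_ingredients[a]
        ib = catalog.herb_to_ingredients[b]
        union = ia | ib
        m, n, r = len(ia), len(ib), len(ia & ib)
        report.per_pair.append(
            {"herbs": [a, b], "m": m, "n": n, "r": r,
             "count": pair_edge_count(m, n, r), "weight": w}
        )
        report.total_contributions += w * pair_edge_count(m, n, r)
        rows.append(np.fromiter((index[i] for i in union), dtype=np.int64))
        cols.append(np.full(len(union), j, dtype=np.int64))
        weights[j] = w

    graph = nx.Graph()
    graph.add_nodes_from(node_ids)
    if herb_edges:
        u_mat = sp.csr_matrix(
            (np.ones(sum(len(r_) for r_ in rows)),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(len(node_ids), len(herb_edges)),
        )
        m_mat = sp.triu((u_mat @ sp.diags(weights) @ u_mat.T).tocoo(), k=1).tocoo()
        int_weights = np.all(np.equal(np.mod(m_mat.data, 1), 0))
        for i, j, w in zip(m_mat.row, m_mat.col, m_mat.data):
            graph.add_edge(
                node_ids[i], node_ids[j], weight=int(w) if int_weights else float(w)
            )
    for iid in node_ids:
        graph.nodes[iid]["structural_type"] = catalog.structural_type_of(iid)

    report.n_ingredient_edges = graph.number_of_edges()
    report.max_weight = (
        max((d["weight"] for _, _, d in graph.edges(data=True)), default=0.0)
    )
    return graph, report
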