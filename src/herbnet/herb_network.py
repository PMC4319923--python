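"""Herb co-occurrence network.

Vertices are herbs; the weight of an edge {a, b} counts the formulae in
which a and b are prescribed together.  Herbs are global entities: the same
herb appearing in several formulae is a single vertex, which is how
independent formulae become connected through shared herbs.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx

from .model import FormulaSet, ValidationError

__all__ = ["build_herb_network"]


def build_herb_network(formulae: FormulaSet) -> nx.Graph:
    """Build the weighted herb co-occurrence graph from a formula set.

    Every herb of every formula becomes a vertex (a herb whose formulae
    never pair it with another herb stays isolated); each unordered herb
    pair gets weight = number of formulae containing both.
    """
    if not len(formulae):
        raise ValidationError("cannot build a herb network from an empty formula set")
    g = nx.Graph()
    for f in formulae:
        g.add_nodes_from(f.herbs)
        for a, b in combinations(sorted(f.herbs), 2):
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return g
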