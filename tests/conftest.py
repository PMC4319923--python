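from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from herbnet import (
    Formula,
    FormulaSet,
    Ingredient,
    IngredientCatalog,
    load_core_formulae,
)

GUALOU_HERBS = {
    "Trichosanthis Fructus",
    "Allii Macrostemonis Bulbus",
    "Pinelliae Rhizoma",
}


@pytest.fixture(scope="session")
def core_formulae() -> FormulaSet:
    return load_core_formulae()


def make_catalog(herb_to_ings: dict[str, set[str]],
                 types: dict[str, str] | None = None) -> IngredientCatalog:
    """Small-catalog builder; every ingredient defaults to 'alkaloids'."""
    all_ings = sorted({i for s in herb_to_ings.values() for i in s})
    return IngredientCatalog(
        herb_to_ingredients={h: set(s) for h, s in herb_to_ings.items()},
        ingredients={
            i: Ingredient(cas=i, name=f"name-{i}",
                          structural_type=(types or {}).get(i, "alkaloids"))
            for i in all_ings
        },
    )


@pytest.fixture
def fig1_instance():
    """The worked two-herb-edge projection example: A={h,f,g}, B={h,e},
    D={f,g,j}, herb edges AB (weight x) and AD (weight y)."""
    x, y = 3, 5
    catalog = make_catalog({"A": {"h", "f", "g"}, "B": {"h", "e"},
                            "D": {"f", "g", "j"}})
    herb_graph = nx.Graph()
    herb_graph.add_edge("A", "B", weight=x)
    herb_graph.add_edge("A", "D", weight=y)
    return herb_graph, catalog, x, y


def random_formula_set(rng: np.random.Generator, n_formulae_max=10,
                       n_herbs_max=15) -> FormulaSet:
    herbs = [f"h{i:02d}" for i in range(rng.integers(2, n_herbs_max + 1))]
    n_f = int(rng.integers(1, n_formulae_max + 1))
    formulae = []
    for k in range(n_f):
        size = int(rng.integers(1, len(herbs) + 1))
        chosen = rng.choice(herbs, size=size, replace=False)
        formulae.append(
            Formula(id=f"f{k}", name=f"f{k}", syndrome="s",
                    herbs=tuple(sorted(chosen)))
        )
    return FormulaSet(formulae=tuple(formulae))


def random_weighted_graph(rng: np.random.Generator, n_max=12, p=0.35) -> nx.Graph:
    """Random graph with dyadic weights {1,2,4,8} so that reciprocal path
    lengths add exactly and shortest-path ties are unambiguous."""
    n = int(rng.integers(2, n_max + 1))
    g = nx.Graph()
    g.add_nodes_from(f"n{i:02d}" for i in range(n))
    nodes = sorted(g.nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j],
                           weight=int(2 ** rng.integers(0, 4)))
    return g


def random_projection_instance(rng: np.random.Generator):
    """Random herb graph (≤6 herbs) + catalog (≤8 ingredients per herb,
    shared pool so overlaps occur)."""
    n_herbs = int(rng.integers(2, 7))
    herbs = [f"H{i}" for i in range(n_herbs)]
    pool = [f"i{k:02d}" for k in range(int(rng.integers(8, 20)))]
    h2i = {
        h: set(rng.choice(pool, size=int(rng.integers(1, 9)),
                          replace=False))
        for h in herbs
    }
    g = nx.Graph()
    g.add_nodes_from(herbs)
    for i in range(n_herbs):
        for j in range(i + 1, n_herbs):
            if rng.random() < 0.5:
                g.add_edge(herbs[i], herbs[j], weight=int(rng.integers(1, 5)))
    return g, make_catalog(h2i)
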