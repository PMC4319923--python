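from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

import herbnet as hn
from herbnet.communities import Partition

from conftest import random_weighted_graph
from _oracles import naive_centralities


def unit_star(leaves: int = 3) -> nx.Graph:
    g = nx.Graph()
    for i in range(leaves):
        g.add_edge("hub", f"leaf{i}", weight=1)
    return g


class TestComputeCentralities:
    def test_star_betweenness(self):
        tab = hn.compute_centralities(unit_star(3))
        assert tab.loc["hub", "betweenness"] == pytest.approx(3.0)
        assert (tab.loc[[f"leaf{i}" for i in range(3)], "betweenness"]
                == 0).all()

    def test_cycle_is_vertex_transitive(self):
        g = nx.Graph()
        for i in range(6):
            g.add_edge(f"c{i}", f"c{(i + 1) % 6}", weight=2)
        tab = hn.compute_centralities(g)
        for col in tab.columns:
            assert tab[col].max() - tab[col].min() < 1e-9

    def test_doubling_weights(self):
        rng = np.random.default_rng(41)
        g = random_weighted_graph(rng, n_max=10, p=0.5)
        if g.number_of_edges() == 0:
            pytest.skip("degenerate draw")
        g2 = g.copy()
        for u, v in g2.edges:
            g2[u][v]["weight"] *= 2
        t1 = hn.compute_centralities(g)
        t2 = hn.compute_centralities(g2)
        assert np.allclose(t2["weighted_degree"], 2 * t1["weighted_degree"])
        assert np.allclose(t2["betweenness"], t1["betweenness"])
        assert np.allclose(t2["eigenvector"], t1["eigenvector"], atol=1e-6)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(97)
        checked = 0
        while checked < 20:
            g = random_weighted_graph(rng, n_max=12, p=0.35)
            tab = hn.compute_centralities(g)
            oracle = naive_centralities(g)
            for node in g.nodes:
                for col in ("weighted_degree", "closeness", "betweenness"):
                    assert tab.loc[node, col] == pytest.approx(
                        oracle[node][col], abs=1e-9
                    ), (node, col)
                assert tab.loc[node, "eigenvector"] == pytest.approx(
                    oracle[node]["eigenvector"], abs=1e-6
                )
            checked += 1

    def test_unit_length_convention(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=10)
        g.add_edge("b", "c", weight=1)
        tab = hn.compute_centralities(g, weight_convention="ignore")
        # with unit lengths the two ends are symmetric
        assert tab.loc["a", "closeness"] == pytest.approx(
            tab.loc["c", "closeness"]
        )

    def test_eigenvector_max_is_one(self):
        rng = np.random.default_rng(43)
        for _ in range(5):
            g = random_weighted_graph(rng, n_max=10, p=0.4)
            if g.number_of_edges() == 0:
                continue
            tab = hn.compute_centralities(g)
            assert tab["eigenvector"].max() == pytest.approx(1.0)

    def test_bipartite_component_converges(self):
        g = nx.Graph()
        for i in range(3):
            for j in range(3):
                g.add_edge(f"u{i}", f"v{j}", weight=1)
        tab = hn.compute_centralities(g)
        assert tab["eigenvector"].max() == pytest.approx(1.0)

    def test_other_component_does_not_affect_betweenness(self):
        g = unit_star(4)
        tab1 = hn.compute_centralities(g)
        g2 = g.copy()
        g2.add_edge("x", "y", weight=3)
        g2.add_edge("y", "z", weight=3)
        tab2 = hn.compute_centralities(g2)
        for n in g.nodes:
            assert tab2.loc[n, "betweenness"] == tab1.loc[n, "betweenness"]

    def test_relabeling_permutes_scores(self):
        rng = np.random.default_rng(47)
        g = random_weighted_graph(rng, n_max=9, p=0.4)
        mapping = {n: f"z{n}" for n in g.nodes}
        t1 = hn.compute_centralities(g)
        t2 = hn.compute_centralities(nx.relabel_nodes(g, mapping))
        for n in g.nodes:
            for col in t1.columns:
                assert t2.loc[mapping[n], col] == pytest.approx(
                    t1.loc[n, col], abs=1e-9
                )


class TestRanking:
    def test_identical_scores_overlap_one(self):
        tab = hn.compute_centralities(unit_star(5))
        rk = hn.rank_top_k(tab, k=3)
        assert rk.overlap.loc["weighted_degree", "weighted_degree"] == 1.0

    def test_disjoint_top_sets_overlap_zero(self):
        import pandas as pd

        tab = pd.DataFrame({
            "weighted_degree": [3.0, 2.0, 0.1, 0.2],
            "betweenness": [0.1, 0.2, 3.0, 2.0],
        }, index=["a", "b", "c", "d"])
        rk = hn.rank_top_k(tab, k=2)
        assert rk.overlap.loc["weighted_degree", "betweenness"] == 0.0

    def test_k_clamped_with_warning(self):
        tab = hn.compute_centralities(unit_star(2))
        with pytest.warns(UserWarning, match="clamping"):
            rk = hn.rank_top_k(tab, k=50)
        assert rk.k == 3

    def test_ties_broken_lexicographically(self):
        tab = hn.compute_centralities(unit_star(3))
        rk = hn.rank_top_k(tab, k=4)
        deg = [n for n, _ in rk.rankings["weighted_degree"]]
        assert deg == ["hub", "leaf0", "leaf1", "leaf2"]

    def test_long_format_layout(self):
        tab = hn.compute_centralities(unit_star(3))
        long = hn.rank_top_k(tab, k=2).to_long()
        assert list(long.columns) == ["centrality", "rank", "node", "score"]
        assert set(long["rank"]) == {1, 2}

    def test_degree_eigenvector_concordance_on_synthetic_instance(self):
        cfg = hn.SyntheticConfig(n_herbs=16, n_formulae=5,
                                 formula_size_range=(3, 6),
                                 ingredient_mean=10.0, ingredient_sd=8.0,
                                 ingredient_max=40, seed=6)
        formulae, catalog, _ = hn.generate(cfg)
        ci, _ = hn.project(hn.build_herb_network(formulae), catalog)
        tab = hn.compute_centralities(ci)
        rk = hn.rank_top_k(tab, k=20)
        random_expectation = 20 / ci.number_of_nodes()
        assert (rk.overlap.loc["weighted_degree", "eigenvector"]
                >= random_expectation)


class TestGatekeepers:
    def test_barbell_bridge_is_unique_gatekeeper(self):
        g = nx.Graph()
        for block, names in (("a", ["a0", "a1", "a2"]),
                             ("b", ["b0", "b1", "b2"])):
            for i in range(3):
                for j in range(i + 1, 3):
                    g.add_edge(names[i], names[j], weight=1)
        g.add_edge("a0", "bridge", weight=1)
        g.add_edge("bridge", "b0", weight=1)
        part = hn.detect_communities(g, seed=0)
        tab = hn.compute_centralities(g)
        gk = hn.gatekeepers(g, part, tab, top_k=1)
        assert [x["node"] for x in gk] == ["bridge"]
        assert len(gk[0]["communities"]) >= 2

    def test_single_community_has_no_gatekeepers(self):
        g = unit_star(3)
        part = Partition(assignment={n: 1 for n in g.nodes},
                         n_communities=1, Q=0.0)
        tab = hn.compute_centralities(g)
        assert hn.gatekeepers(g, part, tab, top_k=4) == []

    def test_planted_bridge_detected_in_synthetic_instance(self):
        cfg = hn.SyntheticConfig(n_herbs=12, n_formulae=4,
                                 formula_size_range=(3, 5),
                                 ingredient_mean=8.0, ingredient_sd=5.0,
                                 ingredient_max=30, overlap_prob=0.03,
                                 seed=3)
        formulae, catalog, truth = hn.generate(cfg)
        assert truth.bridge_ingredients, "instance must plant bridges"
        ci, _ = hn.project(hn.build_herb_network(formulae), catalog)
        part = hn.detect_communities(ci, seed=1, restarts=3)
        tab = hn.compute_centralities(ci)
        rec = hn.recovery_report(truth, part, hn.fingerprint(
            hn.build_contingency(part, catalog)), catalog,
            graph=ci, centrality_table=tab, bridge_top_k=10)
        assert rec.bridge_detection_rate is not None
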