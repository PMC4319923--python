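from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

import herbnet as hn
from herbnet.io import GRAPH_FORMATS

from conftest import make_catalog, random_weighted_graph


LONG = """formula_id,syndrome,herb
f1,stasis,Herb A
f1,stasis, Herb B
f2,cold,Herb C
"""

WIDE = """formula_id\tsyndrome\therbs
f1\tstasis\tHerb A; Herb B ;Herb A
f2\tcold\tHerb C
"""


class TestFormulaTable:
    def test_long_and_wide_layouts_agree(self, tmp_path):
        p1 = tmp_path / "long.csv"
        p1.write_text(LONG)
        p2 = tmp_path / "wide.tsv"
        p2.write_text(WIDE)
        fs1 = hn.read_formula_table(p1)
        fs2 = hn.read_formula_table(p2)
        assert [f.herbs for f in fs1] == [f.herbs for f in fs2]
        # trimming + per-formula dedup
        assert fs1.formulae[0].herbs == ("Herb A", "Herb B")

    def test_missing_column_is_named(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("formula_id,herb\nf1,x\n")
        with pytest.raises(hn.FormatError, match="syndrome"):
            hn.read_formula_table(p)

    def test_empty_herb_list_names_the_formula(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("formula_id\tsyndrome\therbs\nf9\ts\t;\n")
        with pytest.raises(hn.ValidationError, match="f9"):
            hn.read_formula_table(p)

    def test_minimal_single_formula(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("formula_id,syndrome,herb\nf1,s,only herb\n")
        fs = hn.read_formula_table(p)
        assert len(fs) == 1 and fs.herbs() == {"only herb"}

    def test_core_table_has_eight_formulae_and_36_herbs(self, core_formulae):
        assert len(core_formulae) == 8
        assert len(core_formulae.herbs()) == 36

    def test_write_read_round_trip(self, core_formulae, tmp_path):
        p = tmp_path / "out.tsv"
        hn.write_formula_table(core_formulae, p)
        back = hn.read_formula_table(p)
        assert [(f.id, f.syndrome, f.herbs) for f in back] == [
            (f.id, f.syndrome, f.herbs) for f in core_formulae
        ]

    def test_duplicate_herb_within_formula_rejected(self):
        with pytest.raises(hn.ValidationError, match="duplicate"):
            hn.Formula(id="f", name="f", syndrome="s", herbs=("a", "a"))


CATALOG = """herb,cas,name,structural_type
HerbA,50-00-0,formaldehyde,alkaloids
HerbB,50-00-0,formaldehyde,alkaloids
HerbA,,unknown one,quinones
HerbA,NA,unknown two,quinones
HerbB,,unknown three,stilbenoids
"""


class TestIngredientCatalog:
    def test_shared_cas_merges_and_blanks_do_not(self, tmp_path):
        p = tmp_path / "cat.csv"
        p.write_text(CATALOG)
        cat = hn.read_ingredient_catalog(p)
        # 50-00-0 merged, 3 distinct placeholders
        assert len(cat.ingredients) == 4
        assert cat.herbs_of("50-00-0") == ["HerbA", "HerbB"]
        assert cat.herb_to_ingredients["HerbA"] == {
            "50-00-0", "NA:HerbA:1", "NA:HerbA:2"
        }
        assert "NA:HerbB:1" in cat.herb_to_ingredients["HerbB"]

    def test_rereading_is_idempotent(self, tmp_path):
        p = tmp_path / "cat.csv"
        p.write_text(CATALOG)
        c1 = hn.read_ingredient_catalog(p)
        c2 = hn.read_ingredient_catalog(p)
        assert c1.herb_to_ingredients == c2.herb_to_ingredients
        assert c1.ingredients == c2.ingredients

    def test_unknown_structural_type_listed(self, tmp_path):
        p = tmp_path / "cat.csv"
        p.write_text("herb,cas,name,structural_type\nA,1-1-1,x,unobtainium\n")
        with pytest.raises(hn.ValidationError, match="unobtainium"):
            hn.read_ingredient_catalog(p)

    def test_all_fourteen_types_accepted(self, tmp_path):
        rows = ["herb,cas,name,structural_type"] + [
            f"A,{i}-00-0,c{i},{t}" for i, t in enumerate(hn.STRUCTURAL_TYPES)
        ]
        p = tmp_path / "cat.csv"
        p.write_text("\n".join(rows) + "\n")
        cat = hn.read_ingredient_catalog(p)
        assert len(cat.ingredients) == 14

    def test_xlsx_layout_reads_identically(self, tmp_path):
        openpyxl = pytest.importorskip("openpyxl")
        wb = openpyxl.Workbook()
        ws = wb.active
        for row in [r.split(",") for r in CATALOG.strip().splitlines()]:
            ws.append(row)
        p = tmp_path / "cat.xlsx"
        wb.save(p)
        csv_p = tmp_path / "cat.csv"
        csv_p.write_text(CATALOG)
        assert (
            hn.read_ingredient_catalog(p).herb_to_ingredients
            == hn.read_ingredient_catalog(csv_p).herb_to_ingredients
        )

    def test_conflicting_type_for_same_cas_rejected(self, tmp_path):
        p = tmp_path / "cat.csv"
        p.write_text(
            "herb,cas,name,structural_type\nA,1-1-1,x,alkaloids\n"
            "B,1-1-1,x,quinones\n"
        )
        with pytest.raises(hn.ValidationError, match="conflicting"):
            hn.read_ingredient_catalog(p)


class TestSummarize:
    def test_hand_computed_counts(self):
        cat = make_catalog({"a": {"i1", "i2"}, "b": {"i3", "i4", "i5", "i6"},
                            "c": {"i7", "i8", "i9", "i10", "i11", "i12"}})
        s = hn.summarize_catalog(cat)
        assert (s.mean, s.sd, s.min, s.max) == (4.0, 2.0, 2, 6)

    def test_single_herb_sd_flagged(self):
        cat = make_catalog({"a": {"i1", "i2"}})
        s = hn.summarize_catalog(cat)
        assert s.mean == 2 and s.sd == 0.0 and not s.sd_defined
        assert s.min == s.max == 2

    def test_mean_counts_shared_ingredients_per_herb(self):
        # one shared ingredient: reference count 2+2=4 over 3 distinct
        cat = make_catalog({"a": {"x", "s"}, "b": {"y", "s"}})
        s = hn.summarize_catalog(cat)
        assert s.n_ingredients == 3
        assert s.mean == 2.0
        assert sum(s.counts.values()) >= s.n_ingredients


class TestGraphIO:
    @pytest.mark.parametrize("fmt", GRAPH_FORMATS)
    def test_round_trip_random_graphs(self, fmt, tmp_path):
        rng = np.random.default_rng(7)
        for k in range(8):
            g = random_weighted_graph(rng)
            p = tmp_path / f"g{k}.{fmt}"
            hn.write_graph(g, p, fmt)
            back = hn.read_graph(p, fmt)
            assert set(back.nodes) == set(g.nodes)
            assert {frozenset(e) for e in back.edges} == {
                frozenset(e) for e in g.edges
            }
            for u, v, data in g.edges(data=True):
                assert back[u][v]["weight"] == data["weight"]

    def test_single_edge_graphml_carries_weight(self, tmp_path):
        g = nx.Graph()
        g.add_edge("a", "b", weight=2)
        p = tmp_path / "g.graphml"
        hn.write_graph(g, p, "graphml")
        text = p.read_text()
        assert text.count("<edge") == 1 and "weight" in text

    def test_fig1_projection_round_trips_gexf(self, fig1_instance, tmp_path):
        herb_graph, catalog, _, _ = fig1_instance
        ci, _ = hn.project(herb_graph, catalog)
        p = tmp_path / "ci.gexf"
        hn.write_graph(ci, p, "gexf")
        back = hn.read_graph(p, "gexf")
        assert back.number_of_edges() == ci.number_of_edges()
        for u, v, data in ci.edges(data=True):
            assert back[u][v]["weight"] == data["weight"]

    def test_empty_graph_writes_valid_file(self, tmp_path):
        g = nx.Graph()
        for fmt in GRAPH_FORMATS:
            p = tmp_path / f"empty.{fmt}"
            hn.write_graph(g, p, fmt)
            assert hn.read_graph(p, fmt).number_of_edges() == 0

    def test_unknown_format_is_usage_error(self, tmp_path):
        with pytest.raises(hn.FormatError, match="unknown graph format"):
            hn.write_graph(nx.Graph(), tmp_path / "x", "dot")

    def test_self_loop_rejected(self, tmp_path):
        g = nx.Graph()
        g.add_edge("a", "a", weight=1)
        with pytest.raises(hn.ValidationError, match="self-loop"):
            hn.write_graph(g, tmp_path / "x.graphml")
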