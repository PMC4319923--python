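"""Readers and writers for formula tables, ingredient catalogs and graphs.

Tabular inputs are UTF-8 delimited text (comma or tab, auto-detected from
the header line) with a header row; the catalog reader also accepts XLSX
with the same column layout.  Graphs are written as GraphML, GEXF or a
three-column weighted edge list so that external network tools can load
them directly.
"""

from __future__ import annotations

import csv
import importlib.resources
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .model import (
    STRUCTURAL_TYPES,
    Formula,
    FormulaSet,
    FormatError,
    Ingredient,
    IngredientCatalog,
    ValidationError,
    validate_weighted_graph,
)

__all__ = [
    "read_formula_table",
    "write_formula_table",
    "read_ingredient_catalog",
    "write_ingredient_catalog",
    "write_graph",
    "read_graph",
    "load_core_formulae",
    "GRAPH_FORMATS",
]

GRAPH_FORMATS = ("graphml", "gexf", "edgelist")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path, dtype=str)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_formula_table(path: str | Path) -> FormulaSet:
    """Read a formula table in long or wide layout.

    Long layout: one row per (formula, herb) with columns ``formula_id``,
    ``syndrome``, ``herb`` (optional ``name``).  Wide layout: one row per
    formula with a ``herbs`` column holding semicolon-separated herb names.
    Herb names are whitespace-trimmed and deduplicated per formula,
    preserving first-occurrence order.
    """
    df = _read_table(path)
    cols = set(df.columns)
    required = {"formula_id", "syndrome"}
    missing = sorted(required - cols)
    if missing:
        raise FormatError(f"formula table is missing column(s): {missing}")
    if "herb" in cols:
        wide = False
    elif "herbs" in cols:
        wide = True
    else:
        raise FormatError("formula table is missing column(s): ['herb' or 'herbs']")

    formulae: list[Formula] = []
    seen: dict[str, dict] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        fid = str(row["formula_id"]).strip()
        if fid not in seen:
            seen[fid] = {
                "name": str(row.get("name", fid) or fid).strip(),
                "syndrome": str(row["syndrome"]).strip(),
                "herbs": [],
            }
            order.append(fid)
        if wide:
            herbs = [h.strip() for h in str(row["herbs"]).split(";")]
        else:
            herbs = [str(row["herb"]).strip()]
        for h in herbs:
            if h and h not in seen[fid]["herbs"]:
                seen[fid]["herbs"].append(h)
    for fid in order:
        rec = seen[fid]
        if not rec["herbs"]:
            raise ValidationError(f"formula {fid!r} has an empty herb list")
        formulae.append(
            Formula(id=fid, name=rec["name"], syndrome=rec["syndrome"],
                    herbs=tuple(rec["herbs"]))
        )
    return FormulaSet(formulae=tuple(formulae))


def write_formula_table(formulae: FormulaSet, path: str | Path) -> None:
    """Write a formula set as a long-layout TSV."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["formula_id", "name", "syndrome", "herb"])
        for f in formulae:
            for h in f.herbs:
                w.writerow([f.id, f.name, f.syndrome, h])


def read_ingredient_catalog(
    path: str | Path,
    structural_types: Sequence[str] = STRUCTURAL_TYPES,
) -> IngredientCatalog:
    """Read a herb → ingredient catalog.

    Expected columns: ``herb``, ``cas``, ``name``, ``structural_type``.
    A blank or NA CAS receives the deterministic herb-scoped placeholder
    ``NA:<herb>:<k>`` (k-th blank row of that herb, in file order); such
    rows are never merged across herbs.  Rows sharing a real CAS number are
    merged into one ingredient referenced by every listing herb.
    """
    df = _read_table(path)
    missing = sorted({"herb", "cas", "name", "structural_type"} - set(df.columns))
    if missing:
        raise FormatError(f"ingredient catalog is missing column(s): {missing}")

    allowed = set(structural_types)
    bad = sorted(
        {t for t in (s.strip() for s in df["structural_type"]) if t not in allowed}
    )
    if bad:
        raise ValidationError(
            f"unknown structural type(s): {bad}; expected one of {sorted(allowed)}"
        )

    herb_to_ingredients: dict[str, set[str]] = {}
    ingredients: dict[str, Ingredient] = {}
    na_counter: dict[str, int] = {}
    for _, row in df.iterrows():
        herb = str(row["herb"]).strip()
        cas = str(row["cas"]).strip()
        name = str(row["name"]).strip()
        stype = str(row["structural_type"]).strip()
        if cas in ("", "NA", "nan", "None"):
            na_counter[herb] = na_counter.get(herb, 0) + 1
            cas = f"NA:{herb}:{na_counter[herb]}"
        if cas in ingredients:
            prev = ingredients[cas]
            if prev.structural_type != stype:
                raise ValidationError(
                    f"ingredient {cas!r} listed with conflicting structural types "
                    f"{prev.structural_type!r} and {stype!r}"
                )
            if prev.name != name:
                warnings.warn(
                    f"ingredient {cas!r} listed under names {prev.name!r} and "
                    f"{name!r}; keeping the first", stacklevel=2,
                )
        else:
            ingredients[cas] = Ingredient(cas=cas, name=name, structural_type=stype)
        herb_to_ingredients.setdefault(herb, set()).add(cas)
    if not herb_to_ingredients:
        raise ValidationError("ingredient catalog is empty")
    return IngredientCatalog(
        herb_to_ingredients=herb_to_ingredients, ingredients=ingredients
    )


def write_ingredient_catalog(catalog: IngredientCatalog, path: str | Path) -> None:
    """Write a catalog as a long-layout TSV (one row per herb × ingredient)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["herb", "cas", "name", "structural_type"])
        for herb in sorted(catalog.herb_to_ingredients):
            for iid in sorted(catalog.herb_to_ingredients[herb]):
                ing = catalog.ingredients[iid]
                w.writerow([herb, ing.cas, ing.name, ing.structural_type])


def _coerce_weight(text: str) -> float | int:
    try:
        return int(text)
    except ValueError:
        return float(text)


def write_graph(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Write a weighted graph as GraphML, GEXF or a weighted edge list.

    All three outputs round-trip through :func:`read_graph`: vertex set,
    edge set and weights are preserved exactly (weights are written in
    decimal text).  Node attributes (community id, centralities, structural
    type) are serialized by the GraphML/GEXF writers when present; the edge
    list keeps isolated vertices as rows with an empty target column.
    """
    validate_weighted_graph(graph)
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "gexf":
        nx.write_gexf(graph, path)
    elif fmt == "edgelist":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["source", "target", "weight"])
            for u, v, data in graph.edges(data=True):
                w.writerow([u, v, repr(data["weight"])])
            for n in graph.nodes:
                if graph.degree(n) == 0:
                    w.writerow([n, "", ""])
    else:
        raise FormatError(f"unknown graph format {fmt!r}; expected one of {GRAPH_FORMATS}")


def read_graph(path: str | Path, fmt: str = "graphml") -> nx.Graph:
    """Read a graph written by :func:`write_graph`."""
    fmt = fmt.lower()
    if fmt == "graphml":
        g = nx.read_graphml(path)
    elif fmt == "gexf":
        g = nx.read_gexf(path)
        for _, data in g.nodes(data=True):
            data.pop("label", None)
    elif fmt == "edgelist":
        g = nx.Graph()
        with open(path, encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            if header[:2] != ["source", "target"]:
                raise FormatError(f"not a weighted edge list: header {header!r}")
            for row in reader:
                if not row or not row[0]:
                    continue
                if len(row) < 3 or row[1] == "":
                    g.add_node(row[0])
                else:
                    g.add_edge(row[0], row[1], weight=_coerce_weight(row[2]))
    else:
        raise FormatError(f"unknown graph format {fmt!r}; expected one of {GRAPH_FORMATS}")
    return g


def load_core_formulae() -> FormulaSet:
    """The packaged core-formula table: 8 formulae for the 8 basic
    coronary-heart-disease syndromes, spanning 36 herbs."""
    ref = importlib.resources.files("herbnet") / "data" / "core_formulae.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_formula_table(p)
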