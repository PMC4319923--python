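"""End-to-end orchestration: data → networks → communities → reports.

A run reads (or generates) a formula table and ingredient catalog, builds
the herb co-occurrence network, projects it onto the ingredient plane,
detects modularity communities, tests the community × structural-type
association, computes centralities, and writes every artifact plus a
single JSON manifest of headline numbers.  Given the same inputs and seed
the manifest is byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import association as assoc
from . import centrality as cent
from . import communities as comm
from . import io as hio
from . import synthetic as syn
from .herb_network import build_herb_network
from .model import HerbnetError, ValidationError, summarize_catalog
from .projection import project

__all__ = ["PipelineConfig", "run"]

log = logging.getLogger("herbnet")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of (``formulae_path`` + ``catalog_path``) or ``synthetic``
    must be provided.
    """

    outdir: str | Path = "herbnet-run"
    formulae_path: str | Path | None = None
    catalog_path: str | Path | None = None
    synthetic: syn.SyntheticConfig | None = None
    resolution: float = 1.0
    seed: int = 1
    restarts: int = 10
    weight_convention: str = "inverse"
    top_k: int = 50
    include_isolated_herbs: bool = False
    graph_formats: tuple[str, ...] = ("graphml", "edgelist")

    def validate(self) -> None:
        paths_given = self.formulae_path is not None and self.catalog_path is not None
        if paths_given == (self.synthetic is not None):
            raise ValidationError(
                "provide either both input paths or a synthetic config, not both"
            )
        if self.formulae_path is not None and self.catalog_path is None:
            raise ValidationError("catalog path is missing")
        for p in (self.formulae_path, self.catalog_path):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input file not found: {p}")
        for f in self.graph_formats:
            if f not in hio.GRAPH_FORMATS:
                raise ValidationError(f"unknown graph format {f!r}")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as e:
                raise HerbnetError(f"stage {name!r} failed: {e}") from e
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _write_json(path: Path, obj: Any) -> None:
    path.write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )


def run(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full pipeline and return the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"outputs": {}}

    def save_graph(graph, stem: str) -> None:
        for fmt in config.graph_formats:
            ext = {"graphml": ".graphml", "gexf": ".gexf", "edgelist": ".tsv"}[fmt]
            p = outdir / f"{stem}{ext}"
            hio.write_graph(graph, p, fmt)
            manifest["outputs"][f"{stem}_{fmt}"] = p.name

    @_stage("load")
    def load():
        truth = None
        if config.synthetic is not None:
            formulae, catalog, truth = syn.generate(config.synthetic,
                                                    seed=config.seed)
            hio.write_formula_table(formulae, outdir / "formulae.tsv")
            hio.write_ingredient_catalog(catalog, outdir / "catalog.tsv")
            _write_json(outdir / "ground_truth.json", truth.to_dict())
            manifest["outputs"].update(
                formulae="formulae.tsv", catalog="catalog.tsv",
                ground_truth="ground_truth.json",
            )
        else:
            formulae = hio.read_formula_table(config.formulae_path)
            catalog = hio.read_ingredient_catalog(config.catalog_path)
        missing = formulae.herbs() - catalog.herbs
        if missing:
            raise ValidationError(
                f"herbs in formulae but absent from catalog: {sorted(missing)[:5]}"
            )
        extra = catalog.herbs - formulae.herbs()
        if extra:
            warnings.warn(
                f"catalog lists herbs absent from the formula set: "
                f"{sorted(extra)[:5]}", stacklevel=2,
            )
        return formulae, catalog, truth

    formulae, catalog, truth = load()
    summary = summarize_catalog(catalog)
    manifest["dataset"] = {
        "n_formulae": len(formulae),
        "n_herbs": len(formulae.herbs()),
        "n_ingredients": summary.n_ingredients,
        "ingredients_per_herb": {
            "mean": round(summary.mean, 3), "sd": round(summary.sd, 3),
            "min": summary.min, "max": summary.max,
        },
    }
    _write_json(outdir / "dataset_summary.json", manifest["dataset"])
    manifest["outputs"]["dataset_summary"] = "dataset_summary.json"

    @_stage("herb_network")
    def herb_net():
        g = build_herb_network(formulae)
        save_graph(g, "herb_network")
        return g

    herb_graph = herb_net()
    herb_parts = comm.components(herb_graph)
    manifest["herb_network"] = {
        "n_herbs": herb_graph.number_of_nodes(),
        "n_edges": herb_graph.number_of_edges(),
        "n_components": herb_parts.n_communities,
        "total_weight": float(herb_graph.size(weight="weight")),
    }

    @_stage("projection")
    def proj():
        g, report = project(
            herb_graph, catalog,
            include_isolated_herbs=config.include_isolated_herbs,
        )
        save_graph(g, "ingredient_network")
        _write_json(outdir / "projection_report.json", report.to_dict())
        manifest["outputs"]["projection_report"] = "projection_report.json"
        return g, report

    ci_graph, proj_report = proj()
    manifest["ingredient_network"] = {
        "n_ingredients": ci_graph.number_of_nodes(),
        "n_edges": ci_graph.number_of_edges(),
        "n_components": comm.components(ci_graph).n_communities,
        "max_weight": proj_report.max_weight,
    }

    @_stage("communities")
    def communities():
        part = comm.detect_communities(
            ci_graph, resolution=config.resolution, seed=config.seed,
            restarts=config.restarts,
        )
        with open(outdir / "partition.tsv", "w", encoding="utf-8") as fh:
            fh.write("node\tcommunity\n")
            for node in sorted(part.assignment):
                fh.write(f"{node}\t{part.assignment[node]}\n")
        manifest["outputs"]["partition"] = "partition.tsv"
        return part

    partition = communities()
    sizes = [len(c) for c in partition.communities()]
    manifest["communities"] = {
        "n_communities": partition.n_communities,
        "modularity": round(partition.Q, 6),
        "sizes": sizes,
    }

    @_stage("association")
    def association():
        table = assoc.build_contingency(partition, catalog)
        result = assoc.chi_square(table)
        fp = assoc.fingerprint(table)
        reps = assoc.representative_herbs(partition, catalog)
        table.table.to_csv(outdir / "contingency.tsv", sep="\t")
        fp.percentages.round(4).to_csv(outdir / "fingerprint.tsv", sep="\t")
        _write_json(outdir / "association.json", {
            "chi2": round(result.chi2, 3), "df": result.df,
            "p_value": result.p_value, "N": result.N,
            "low_expected_fraction": round(result.low_expected_fraction, 4),
        })
        manifest["outputs"].update(
            contingency="contingency.tsv", fingerprint="fingerprint.tsv",
            association="association.json",
        )
        return table, result, fp, reps

    table, result, fp, reps = association()
    manifest["association"] = {
        "chi2": round(result.chi2, 3),
        "df": result.df,
        "p_value": result.p_value,
        "N": result.N,
    }
    manifest["fingerprint"] = {
        "dominant_types": {str(c): d for c, d in fp.dominant.items()},
        "overall_shares": {
            t: round(v, 1) for t, v in fp.overall_shares.items() if v > 0
        },
        "representative_herbs": {
            str(c): [{"herb": h, "coverage": round(cv, 3)} for h, cv in lst]
            for c, lst in reps.items()
        },
    }

    @_stage("centrality")
    def centrality():
        tab = cent.compute_centralities(
            ci_graph, weight_convention=config.weight_convention
        )
        ranking = cent.rank_top_k(tab, k=config.top_k)
        gk = cent.gatekeepers(ci_graph, partition, tab, top_k=config.top_k)
        tab.round(8).to_csv(outdir / "centralities.tsv", sep="\t",
                            index_label="node")
        ranking.to_long().to_csv(outdir / "rankings.tsv", sep="\t", index=False)
        _write_json(outdir / "gatekeepers.json", gk)
        manifest["outputs"].update(
            centralities="centralities.tsv", rankings="rankings.tsv",
            gatekeepers="gatekeepers.json",
        )
        return tab, ranking, gk

    cent_table, ranking, gk = centrality()
    manifest["centrality"] = {
        "top_k": ranking.k,
        "overlap": {
            a: {b: round(float(ranking.overlap.loc[a, b]), 3)
                for b in ranking.overlap.columns}
            for a in ranking.overlap.index
        },
        "n_gatekeepers": len(gk),
    }

    if truth is not None:
        rec = syn.recovery_report(
            truth, partition, fp, catalog, graph=ci_graph,
            centrality_table=cent_table,
        )
        manifest["recovery"] = rec.to_dict()

    # annotate and re-write the ingredient graph with analysis attributes
    for node in ci_graph.nodes:
        ci_graph.nodes[node]["community"] = partition.assignment[node]
        for col in cent_table.columns:
            ci_graph.nodes[node][col] = float(cent_table.loc[node, col])
    save_graph(ci_graph, "ingredient_network_annotated")

    _write_json(outdir / "manifest.json", manifest)
    return manifest
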