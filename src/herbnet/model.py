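"""Domain model for multi-herb formulae and their chemical-ingredient catalogs.

The two primary inputs of the pipeline are

* a *formula table*: each formula (a prescribed combination of medicinal
  herbs, mapped to one diagnostic syndrome) lists its member herbs;
* an *ingredient catalog*: for each herb, the chemical ingredients it is
  reported to contain, each keyed by a CAS registry number (or a
  deterministic placeholder when none is known) and labelled with one of a
  small set of coarse structural types (flavonoids, volatile oils, ...).

Graphs built from these objects are plain :class:`networkx.Graph` instances
with positive ``weight`` edge attributes; :func:`validate_weighted_graph`
checks the conventions the rest of the package relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "STRUCTURAL_TYPES",
    "Formula",
    "FormulaSet",
    "Ingredient",
    "IngredientCatalog",
    "DatasetSummary",
    "HerbnetError",
    "FormatError",
    "ValidationError",
    "ConvergenceError",
    "validate_weighted_graph",
    "summarize_catalog",
]

#: Canonical list of the 14 primary chemical structural types used to
#: classify herbal ingredients.  Catalog readers validate against this list
#: unless a custom one is supplied.
STRUCTURAL_TYPES: tuple[str, ...] = (
    "alkaloids",
    "amino acid",
    "fatty acid",
    "flavonoids and its glycosides",
    "glycosides",
    "phenylpropanoids and its derivates",
    "protein and enzyme",
    "quinones",
    "saccharides and its derivates",
    "steroids and its glycosides",
    "stilbenoids",
    "terpenoids and its derivates",
    "triterpenoids and its glycosides",
    "volatile oils",
)


class HerbnetError(Exception):
    """Base class for package errors."""


class FormatError(HerbnetError):
    """An input file does not have the expected layout."""


class ValidationError(HerbnetError):
    """Input data violates a model invariant."""


class ConvergenceError(HerbnetError):
    """An iterative numerical routine failed to converge."""


@dataclass(frozen=True)
class Formula:
    """One formula: an ordered, duplicate-free set of member herbs."""

    id: str
    name: str
    syndrome: str
    herbs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.herbs:
            raise ValidationError(f"formula {self.id!r} has an empty herb list")
        if len(set(self.herbs)) != len(self.herbs):
            dupes = sorted({h for h in self.herbs if list(self.herbs).count(h) > 1})
            raise ValidationError(
                f"formula {self.id!r} lists duplicate herbs: {dupes}"
            )


@dataclass(frozen=True)
class FormulaSet:
    """A collection of formulae sharing one herb namespace."""

    formulae: tuple[Formula, ...]

    def __post_init__(self) -> None:
        ids = [f.id for f in self.formulae]
        if len(set(ids)) != len(ids):
            raise ValidationError("formula ids are not unique")
        if not self.herbs():
            raise ValidationError("formula set contains no herbs")

    def herbs(self) -> set[str]:
        """Union of herbs over all member formulae."""
        out: set[str] = set()
        for f in self.formulae:
            out.update(f.herbs)
        return out

    def __len__(self) -> int:
        return len(self.formulae)

    def __iter__(self):
        return iter(self.formulae)


@dataclass(frozen=True)
class Ingredient:
    """A chemical ingredient, identified by CAS number or placeholder id."""

    cas: str
    name: str
    structural_type: str


@dataclass
class IngredientCatalog:
    """Herb → ingredient mapping with a global ingredient registry.

    ``herb_to_ingredients`` maps a herb id to the set of ingredient ids it
    contains; ``ingredients`` maps ingredient id to the :class:`Ingredient`
    record.  Ingredients shared by several herbs appear once in
    ``ingredients`` and are referenced from each herb's set.
    """

    herb_to_ingredients: dict[str, set[str]]
    ingredients: dict[str, Ingredient]

    def __post_init__(self) -> None:
        referenced: set[str] = set()
        for herb, ings in self.herb_to_ingredients.items():
            if not ings:
                raise ValidationError(f"herb {herb!r} has no ingredients")
            referenced.update(ings)
        unknown = referenced - self.ingredients.keys()
        if unknown:
            raise ValidationError(
                f"herbs reference unregistered ingredients: {sorted(unknown)[:5]}"
            )
        orphans = self.ingredients.keys() - referenced
        if orphans:
            raise ValidationError(
                f"ingredients referenced by no herb: {sorted(orphans)[:5]}"
            )

    @property
    def herbs(self) -> set[str]:
        return set(self.herb_to_ingredients)

    def ingredients_of(self, herbs: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for h in herbs:
            out.update(self.herb_to_ingredients[h])
        return out

    def structural_type_of(self, ingredient_id: str) -> str:
        return self.ingredients[ingredient_id].structural_type

    def herbs_of(self, ingredient_id: str) -> list[str]:
        return sorted(
            h for h, ings in self.herb_to_ingredients.items() if ingredient_id in ings
        )


@dataclass(frozen=True)
class DatasetSummary:
    """Summary statistics over per-herb ingredient reference counts.

    ``mean``/``sd`` are computed over the number of ingredients each herb
    references; shared ingredients therefore count once per referencing
    herb, while ``n_ingredients`` deduplicates across herbs.  ``sd`` uses
    the sample (n-1) convention; for a single herb it is reported as 0 with
    ``sd_defined`` False.
    """

    n_herbs: int
    n_ingredients: int
    counts: Mapping[str, int] = field(repr=False)
    mean: float = 0.0
    sd: float = 0.0
    min: int = 0
    max: int = 0
    sd_defined: bool = True


def summarize_catalog(catalog: IngredientCatalog) -> DatasetSummary:
    """Compute per-herb ingredient-count statistics for a catalog."""
    counts = {h: len(ings) for h, ings in catalog.herb_to_ingredients.items()}
    if not counts:
        raise ValidationError("empty catalog")
    values = list(counts.values())
    n = len(values)
    mean = sum(values) / n
    if n > 1:
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
        sd_defined = True
    else:
        sd, sd_defined = 0.0, False
    return DatasetSummary(
        n_herbs=n,
        n_ingredients=len(catalog.ingredients),
        counts=counts,
        mean=mean,
        sd=sd,
        min=min(values),
        max=max(values),
        sd_defined=sd_defined,
    )


def validate_weighted_graph(graph: nx.Graph) -> None:
    """Check the package's weighted-graph conventions.

    Undirected simple graph, no self-loops, every edge carries a positive
    numeric ``weight``.
    """
    if graph.is_directed() or graph.is_multigraph():
        raise ValidationError("expected a simple undirected graph")
    for u, v, data in graph.edges(data=True):
        if u == v:
            raise ValidationError(f"self-loop at {u!r}")
        w = data.get("weight")
        if w is None or not w > 0:
            raise ValidationError(f"edge ({u!r}, {v!r}) has non-positive weight {w!r}")
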