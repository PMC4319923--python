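"""Community × structural-type association and chemical fingerprints.

Cross-tabulates network communities against the structural types of their
member ingredients, tests the association with a plain Pearson chi-square
(no continuity correction — the tables are large), and derives per-
community *fingerprints*: the percentage distribution of structural types
within each community, its dominant type(s), and the representative herbs
covering most of its members.

Because many cells of a community × type table can be sparse, a
permutation (Monte-Carlo) p-value that shuffles type labels across
ingredients while keeping both margins fixed is available alongside the
asymptotic chi-square p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import IngredientCatalog, STRUCTURAL_TYPES, ValidationError
from .communities import Partition

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "Fingerprint",
    "build_contingency",
    "chi_square",
    "null_chi_square_samples",
    "monte_carlo_pvalue",
    "fingerprint",
    "representative_herbs",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Integer counts of ingredients per (community, structural type)."""

    table: pd.DataFrame

    @property
    def N(self) -> int:
        return int(self.table.to_numpy().sum())


@dataclass(frozen=True)
class AssociationResult:
    chi2: float
    df: int
    p_value: float
    N: int
    expected: pd.DataFrame = field(repr=False)
    low_expected_fraction: float = 0.0


@dataclass(frozen=True)
class Fingerprint:
    """Row-percentage view of a contingency table.

    ``percentages`` rows sum to 100; ``dominant`` lists the argmax type(s)
    of each community; ``overall_shares`` is the column-total percentage of
    each structural type across all classified ingredients.
    """

    percentages: pd.DataFrame
    dominant: dict[int, list[str]]
    overall_shares: pd.Series


def build_contingency(
    partition: Partition,
    catalog: IngredientCatalog,
    structural_types: Sequence[str] = STRUCTURAL_TYPES,
) -> ContingencyTable:
    """Count partition members per (community, structural type).

    Every node of the partition must be a cataloged ingredient with a
    structural type; columns follow the supplied type order, keeping only
    types that occur plus preserving the full configured list.
    """
    untyped = sorted(n for n in partition.assignment if n not in catalog.ingredients)
    if untyped:
        raise ValidationError(f"nodes without structural type: {untyped[:10]}")
    cids = sorted(set(partition.assignment.values()))
    seen_types = {catalog.structural_type_of(n) for n in partition.assignment}
    cols = list(structural_types) + sorted(seen_types - set(structural_types))
    table = pd.DataFrame(0, index=cids, columns=cols, dtype=int)
    for node, cid in partition.assignment.items():
        table.loc[cid, catalog.structural_type_of(node)] += 1
    return ContingencyTable(table=table)


def _nonzero(table: pd.DataFrame) -> pd.DataFrame:
    t = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    return t


def chi_square(table: ContingencyTable) -> AssociationResult:
    """Pearson chi-square test of community × type independence.

    All-zero rows and columns are dropped before computing df; expected
    counts are row_total × col_total / N, the statistic is Σ (O−E)²/E and
    the p-value comes from the upper tail of the χ²(df) distribution.  The
    fraction of cells with expected count < 5 is reported as a validity
    caveat (the asymptotic p-value degrades when it is large).
    """
    obs = _nonzero(table.table)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValidationError(
            f"degenerate contingency table of shape {obs.shape}; need >= 2x2"
        )
    chi2, p, dof, expected = stats.chi2_contingency(obs.to_numpy(), correction=False)
    exp_df = pd.DataFrame(expected, index=obs.index, columns=obs.columns)
    return AssociationResult(
        chi2=float(chi2),
        df=int(dof),
        p_value=float(p),
        N=int(obs.to_numpy().sum()),
        expected=exp_df,
        low_expected_fraction=float((expected < 5).mean()),
    )


def null_chi_square_samples(
    table: ContingencyTable, n_reps: int, seed: int = 0
) -> np.ndarray:
    """Sample the permutation null of the chi-square statistic.

    Type labels are shuffled across ingredients with both margins held
    fixed (equivalent to permuting the type column of the ingredient
    table), and the Pearson statistic is recomputed for each replicate.
    """
    obs = _nonzero(table.table).to_numpy()
    row_tot = obs.sum(axis=1)
    col_tot = obs.sum(axis=0)
    n = obs.sum()
    expected = np.outer(row_tot, col_tot) / n
    type_vec = np.repeat(np.arange(len(col_tot)), col_tot)
    row_starts = np.concatenate([[0], np.cumsum(row_tot)])
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    n_cols = len(col_tot)
    for k in range(n_reps):
        perm = rng.permutation(type_vec)
        t = np.vstack([
            np.bincount(perm[row_starts[i]:row_starts[i + 1]], minlength=n_cols)
            for i in range(len(row_tot))
        ])
        out[k] = ((t - expected) ** 2 / expected).sum()
    return out


def monte_carlo_pvalue(
    table: ContingencyTable, n_reps: int = 999, seed: int = 0
) -> float:
    """Permutation p-value of the chi-square statistic (add-one rule)."""
    obs_stat = chi_square(table).chi2
    samples = null_chi_square_samples(table, n_reps, seed)
    return float((1 + (samples >= obs_stat - 1e-9).sum()) / (n_reps + 1))


def fingerprint(table: ContingencyTable) -> Fingerprint:
    """Per-community structural-type percentages and dominant types."""
    t = table.table
    row_tot = t.sum(axis=1)
    pct = t.div(row_tot.replace(0, np.nan), axis=0) * 100.0
    pct = pct.fillna(0.0)
    dominant: dict[int, list[str]] = {}
    for cid, row in pct.iterrows():
        if row.sum() == 0:
            dominant[int(cid)] = []
            continue
        best = row.max()
        dominant[int(cid)] = [t_ for t_, v in row.items() if v == best]
    overall = t.sum(axis=0) / table.N * 100.0
    return Fingerprint(percentages=pct, dominant=dominant, overall_shares=overall)


def representative_herbs(
    partition: Partition,
    catalog: IngredientCatalog,
    threshold: float = 0.5,
    top_k: int = 2,
    mode: str = "individual",
) -> dict[int, list[tuple[str, float]]]:
    """Representative herbs per community, with coverage fractions.

    A herb's coverage of a community is the fraction of community members
    among its ingredients.  In ``individual`` mode (default) the top
    ``top_k`` herbs whose individual coverage exceeds ``threshold`` are
    returned, falling back to the ``top_k`` best-covering herbs when none
    passes.  In ``cumulative`` mode herbs are added in decreasing coverage
    order until their summed coverage reaches ``threshold`` (at most
    ``top_k``).
    """
    if mode not in ("individual", "cumulative"):
        raise ValidationError(f"unknown coverage mode {mode!r}")
    members: dict[int, set[str]] = {}
    for node, cid in partition.assignment.items():
        members.setdefault(cid, set()).add(node)
    out: dict[int, list[tuple[str, float]]] = {}
    for cid in sorted(members):
        grp = members[cid]
        cov = []
        for herb, ings in catalog.herb_to_ingredients.items():
            c = len(grp & ings) / len(grp)
            if c > 0:
                cov.append((herb, c))
        cov.sort(key=lambda hc: (-hc[1], hc[0]))
        if mode == "individual":
            passing = [(h, c) for h, c in cov if c > threshold][:top_k]
            out[cid] = passing if passing else cov[:top_k]
        else:
            acc: list[tuple[str, float]] = []
            total = 0.0
            for h, c in cov[:top_k]:
                acc.append((h, c))
                total += c
                if total >= threshold:
                    break
            out[cid] = acc
    return out
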