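# Methods

## Data model

A **formula** is an ordered, duplicate-free set of herbs attached to a
syndrome label; a **catalog** maps each herb to the set of chemical
ingredients it contains.  Ingredients are global entities keyed by CAS
registry number: rows of a catalog file sharing a CAS id are merged into
one ingredient referenced by every listing herb.  A blank CAS receives the
herb-scoped placeholder `NA:<herb>:<k>` and is *never* merged across
herbs — without an identifier, cross-herb identity is unknowable, and a
false merge would fabricate network edges.  Each ingredient carries one of
14 coarse structural types (alkaloids, amino acid, fatty acid, flavonoids
and its glycosides, glycosides, phenylpropanoids and its derivates,
protein and enzyme, quinones, saccharides and its derivates, steroids and
its glycosides, stilbenoids, terpenoids and its derivates, triterpenoids
and its glycosides, volatile oils); the list is configurable, the reader
validates against it.

Per-herb ingredient statistics (`summarize_catalog`) count *references*:
an ingredient shared by two herbs counts once for each, so the mean per
herb can exceed `n_ingredients / n_herbs` (which deduplicates).  The SD
uses the sample (n−1) convention, matching spreadsheet and statistics-
package defaults; a one-herb catalog reports SD 0 with `sd_defined=False`.
Herb names are matched exactly after whitespace trimming — no fuzzy
matching, to avoid silent mis-joins.

## Herb network and projection

`G_TCM` weights count co-prescription: for every formula, every unordered
herb pair gains 1.  Duplicate herbs within a formula are impossible by the
model invariant, so a pair can gain at most 1 per formula.

The projection treats all ingredients of two connected herbs as mutually
interacting: herb edge {A, B} with weight *w* adds *w* to every unordered
pair of distinct ingredients in `ingredients(A) ∪ ingredients(B)`.
Intra-herb pairs are therefore created whenever the herb has at least one
edge; a herb with no edges contributes nothing (its ingredients are
excluded from the graph by default, included as isolated vertices behind
`include_isolated_herbs` — this only matters for degenerate inputs, since
every herb of the packaged formula table has edges).  A pair with counts
(m, n, r shared) generates C(m+n−r, 2) pairs; shared ingredients are
counted once in the union.

The implementation never loops over those pairs in Python: with `U` the
sparse ingredient × herb-edge union-membership matrix and `w` the weight
vector, the ingredient weight matrix is `U · diag(w) · Uᵀ` with the
diagonal discarded.  This is algebraically identical to naive enumeration
(the test suite checks exact equality against an explicit-enumeration
oracle) and keeps the largest realistic case — a herb pair of 248 + 200
ingredients generating ~10⁵ pairs — in sparse BLAS.  The conservation law
Σ edge weights = Σ_pairs w·C(m+n−r, 2) is reported per run in the
projection report and asserted in tests.

## Community detection

Communities maximize weighted Newman–Girvan modularity with an optional
resolution γ.  The optimizer is the two-phase multilevel (Louvain)
heuristic as implemented in igraph; determinism is imposed from outside
the heuristic: each of `restarts` (default 10) runs reseeds the RNG and
shuffles node order, every candidate partition is scored with the
package's own exact modularity evaluator, and the best (ties → fewer
communities → lexicographic node order) is returned.  Two safeguards make
the output well-behaved on all inputs: any community spanning several
connected components is split (splitting across components always
increases Q), and the result is never worse than the components partition
or the all-singletons partition.  Community labels are re-indexed from 1
by decreasing size.  A graph with no edges has Q = 0 by convention and
yields singleton communities.  The number of communities is data-dependent
output, never a constraint.

## Association and fingerprints

The contingency table counts ingredients per (community, structural type).
The test is a plain Pearson chi-square — no Yates correction, no exact
test; all-zero rows and columns are dropped before df = (R−1)(C−1), since
empty communities or types are partition artifacts.  Expected counts are
`row·col/N`; the p-value is the upper tail of χ²(df).  Because community ×
type tables are often sparse, the fraction of cells with expected count
below 5 is reported as a validity caveat, and a permutation alternative
(`monte_carlo_pvalue`) shuffles type labels across ingredients with both
margins fixed; under independence its p-value is uniform by construction,
which the acceptance suite exploits for null calibration (the permutation
null's exact mean is df·N/(N−1)).

Fingerprints are row percentages (each community sums to 100%); the
dominant type is the row argmax, with ties reported as lists.
Representative herbs rank herbs by the fraction of community members they
contain; the default mode returns up to two herbs whose *individual*
coverage exceeds 50%, falling back to the two best-covering herbs —
coverage is computed over all community members, not any "active" subset.

## Centralities

* **Weighted degree** — node strength, Σ incident weights.
* **Closeness / betweenness** — shortest-path measures with edge length
  1/weight by default (a strong combination is a short tie); the
  `ignore` convention (unit lengths) is available because visualization
  tools of the study's era differ in whether path metrics use weights.
  Closeness is component-local, (n_c − 1)/Σ d (harmonic closeness behind a
  flag); betweenness is unnormalized Brandes betweenness with fractional
  credit for tied shortest paths — rankings are scale-invariant so
  normalization would not change top-k output.
* **Eigenvector** — Perron vector of the weight matrix, computed per
  connected component by power iteration on `A + I` (the identity shift
  breaks the period-2 oscillation of bipartite components without changing
  eigenvectors), tolerance 1e−8, max 1000 iterations, raising a
  convergence error with an override hint otherwise.  The dominant
  component (largest spectral radius λ) is scaled to max 1; other
  components are scaled by λ_c/λ_max, so scores remain comparable and the
  global max is 1 whenever the graph has an edge.

Path computations run through igraph's C implementations; the test suite
checks them (and the eigenvector scores) against an independent
Floyd–Warshall / path-counting / dense-eigendecomposition oracle on random
graphs of ≤ 12 nodes, using dyadic weights so shortest-path ties are
floating-point-exact.

`rank_top_k` sorts descending with lexicographic tie-break and reports
|top-k ∩ top-k|/k for every centrality pair.  `gatekeepers` returns the
top-betweenness nodes whose neighbors span ≥ 2 communities.

## Synthetic data generator

The generator emulates a curated formula/catalog instance at the scale of
the packaged study sample; its defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_formulae`, `formula_size_range` | 8, (3, 13) | formulae and herbs per formula |
| `n_herbs` | 36 | herb universe |
| `reuse_power` | 1.5 | preferential-attachment exponent: a few herbs recur across formulae |
| `ingredient_mean`, `ingredient_sd` | 44.78, 59.4 | target log-normal moments of per-herb counts |
| `ingredient_min`, `ingredient_max` | 2, 248 | truncation bounds (resampling) |
| `n_types` | 14 | structural types |
| `type_concentration` α | 0.1 | Dirichlet concentration: α→0 gives one-type herbs, α→∞ uniform types |
| `overlap_prob` | 0.01 | per-slot probability of reusing an ingredient from another herb |
| `include_isolated_formula` | True | one 3-herb formula whose herbs and ingredients never touch the rest |

Per-herb counts are rounded log-normal draws with (μ, σ) solved from the
target mean/SD, resampled into [2, 248]; truncating the heavy upper tail
lowers the realized mean by roughly 10% relative to the untruncated
target, which the calibration test bounds at 15% over 100 seeds.  Each
herb draws a dominant type uniformly, then type probabilities from
Dirichlet(α·1 + e_dom), so α is a single dial from planted association to
null.  Cross-herb sharing draws uniformly from previously generated
non-isolated herbs' ingredients; shared ingredients are recorded as
planted "bridges".  The emitted ground truth (dominant types, isolated
formula, bridges) drives `recovery_report`: dominant-type match fraction,
exact recovery of the isolated component, and bridge detection among
top-betweenness nodes.

What the generator does **not** emulate: real chemistry (ids and names
are synthetic, types are drawn, not assigned by structure), correlated
type profiles between botanically related herbs, and the long-range
co-occurrence structure of a larger formula corpus.  Passing recovery
tests therefore demonstrate that the pipeline detects the *kind* of
structure the generator plants, not that any particular real catalog
carries it.

## Determinism and problem sizes

Every stochastic step (generation, community restarts, permutation nulls)
is driven by an explicit seed; pipeline reruns with identical config and
seed produce byte-identical manifests (timings go to the log, never into
outputs).  Unit and property tests run on scaled-down instances (≤ 20
herbs, ~8–20 ingredients per herb, graphs of ≤ 30 nodes for oracle
comparisons); the acceptance script runs the full 36-herb, study-scale
configuration, which completes in well under a minute.

## Known limitations

* The chi-square p-value is asymptotic; with many sparse cells prefer the
  permutation p-value (both are exposed).
* Modularity optimization is heuristic: seeded restarts make it
  reproducible, not provably optimal, and community boundaries on dense
  projections can vary between seeds even when component-level facts and
  association-level statistics are stable.
* Exact reproduction of a study's community boundaries requires its exact
  catalog and tool conventions; this package promises component-level
  facts, conservation laws and association statistics instead.
* Formula dosage is deliberately ignored, and structural types are opaque
  categorical labels (no SMILES/InChI parsing).
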