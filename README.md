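# herbnet

Network analysis of multi-herb formulae and their chemical ingredients.

Traditional Chinese medicine treats disease with *formulae* — fixed
combinations of medicinal herbs, one formula per diagnostic syndrome.  Each
herb contributes dozens to hundreds of chemical ingredients, so the
prescription habits encoded in a set of formulae induce a large network of
ingredient co-occurrence.  `herbnet` builds and analyses that network for
any formula table and herb → ingredient catalog:

1. **Herb co-occurrence network** `G_TCM`: herbs are vertices; the weight
   of edge {v_i, v_j} counts the formulae prescribing both herbs.
2. **One-mode projection** `G_CI`: each herb edge {A, B} of weight *w* is
   expanded into every unordered pair of distinct ingredients in the
   *union* of A's and B's ingredient sets (intra-herb pairs included); a
   herb pair with *m* and *n* ingredients sharing *r* contributes
   C(m+n−r, 2) ingredient pairs, and weights accumulate over herb edges.
3. **Community detection**: weighted-modularity optimization
   (multilevel/Louvain heuristic with seeded restarts), with an exact
   evaluator of Q = (1/2W) Σ_ij [w_ij − s_i s_j/2W] δ(c_i, c_j).
4. **Structural-type association**: communities × the 14 coarse chemical
   structural types (alkaloids, flavonoids, volatile oils, ...) are
   cross-tabulated and tested with a Pearson chi-square; per-community
   *fingerprints* (type percentage profiles), dominant types and
   representative herbs are derived.
5. **Centralities**: weighted degree, closeness, betweenness and
   eigenvector centrality per ingredient, top-k ranking tables,
   cross-centrality concordance and community-bridging "gatekeepers".

The package ships the eight core coronary-heart-disease formulae (36
herbs) as its reference formula table, and a synthetic catalog generator
that emulates a curated ingredient catalog (right-skewed per-herb counts,
herb-specific type bias, rare cross-herb sharing, one isolated formula)
with planted ground truth for recovery testing.

## Worked example

```python
import numpy as np
import herbnet as hn

formulae = hn.load_core_formulae()                      # 8 formulae, 36 herbs
herb_net = hn.build_herb_network(formulae)

catalog, truth = hn.generate_catalog(                   # synthetic catalog
    sorted(formulae.herbs()), hn.SyntheticConfig(), np.random.default_rng(1),
    isolated_herbs=("Allii Macrostemonis Bulbus", "Pinelliae Rhizoma",
                    "Trichosanthis Fructus"),
)
ingredient_net, report = hn.project(herb_net, catalog)
partition = hn.detect_communities(ingredient_net, seed=1)
result = hn.chi_square(hn.build_contingency(partition, catalog))
```

Output of the above (printing the intermediate objects):

```
8 formulae, 36 herbs
herb network: 169 edges; Persicae Semen + Carthami Flos co-prescribed in 2 formulae
catalog: 1142 ingredients, 31.97 +/- 36.08 per herb (min 2, max 176)
ingredient network: 1142 nodes, 206194 edges
7 communities, Q = 0.616
chi-square = 1565.9, df = 78, p = 1.7e-275
community 1 dominant type: terpenoids and its derivates (23%)
```

The herb network splits into two components: the three herbs of the
phlegm-stasis formula (Gualou Xiebai Banxia Decoction) are used in no
other formula, so their ingredients form an isolated component of the
ingredient network — the synthetic catalog preserves this by never sharing
ingredients across that boundary.  The tiny chi-square p-value reflects
the planted herb-level type bias: communities inherit the type profile of
their dominant herbs.

## Command line

```sh
herbnet generate --seed 1 --out data/                 # synthetic dataset
herbnet build    --formulae data/formulae.tsv --catalog data/catalog.tsv \
                 --out nets/
herbnet analyze  --formulae data/formulae.tsv --catalog data/catalog.tsv \
                 --resolution 1.0 --seed 1 --restarts 10 \
                 --weight-convention inverse --top-k 50 --out run/
herbnet report   --run run/
```

`analyze` writes GraphML/edge-list graphs, the partition, contingency,
fingerprint, centrality and ranking tables, and a `manifest.json` of
headline numbers; reruns with the same inputs and seed produce a
byte-identical manifest.

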