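# pathclass

Functional classification of protein regulatory pathways from their
topology, chemistry and annotation.

A regulatory pathway — a set of proteins with directed regulatory
relations — is modelled as a digraph *G* = (*V*, *E*) whose vertices are
proteins and whose arcs are weighted by the cosine similarity of the
endpoints' binary GO annotation vectors. Each pathway is encoded as a
fixed-layout feature vector with three blocks:

* **Graph block (88 features).** Size and density |E|/|V|²; mean /
  variance / median / max of in- and out-degree; arc-weight statistics
  with and without missing (zero-weight) edges; arc-count change rates
  across weight cutoffs 0.1–0.8; neighborhood degree correlation;
  directed clustering (density of neighborhood-induced subgraphs);
  normalized neighborhood-overlap statistics T₁–T₄; the three largest
  singular values of the adjacency matrix; and GO-similarity local
  density L(w) = 2|E(G(w))|/(l(l−1)) of each vertex's in/out
  neighborhood across cutoffs 0–0.9.
* **Physicochemical block (264 features).** Each protein sequence is
  recoded into property pseudo-sequences (hydrophobicity, van der Waals
  volume, polarity, polarizability, secondary structure, solvent
  accessibility) and summarized by composition / transition /
  distribution (CTD) descriptors plus amino-acid composition — 132
  protein descriptors, z-scored across the corpus, then aggregated per
  pathway as mean and max.
* **Functional block (one feature per GO term).** The enrichment score
  of pathway *i* on term *j* is −log₁₀ P(X ≥ k) for
  X ~ Hypergeom(N, M_j, n_i): the upper-tail probability of seeing at
  least k term-annotated proteins in a pathway of n given M_j annotated
  among N background proteins. With the canonical 5218-term universe
  the full vector has 88 + 264 + 5218 = 5570 dimensions.

Features are discretized (μ±σ, three states) and ranked by mRMR —
greedily maximizing I(f; class) minus the mean mutual information with
already-selected features — alongside the relevance-only MaxRel list.
Classification is nearest neighbor under cosine distance
d(x, y) = 1 − x·y/(‖x‖‖y‖), evaluated by the jackknife (leave-one-out)
test, and incremental feature selection (IFS) sweeps nested prefixes of
the ranked list to find the most accurate feature subset.

## Worked example

The built-in generator produces a labeled benchmark in exactly the
formats the loaders read (edge-list TSV, FASTA, annotation TSV, label
TSV): six functional classes, twenty pathways each, with class-specific
signature GO terms planted at carry probability 0.9 against a 0.05
background, and mildly class-biased residue composition.

```python
from pathclass import (SyntheticSpec, generate, filter_benchmark,
                       build_table, PathwayClassModel)

ds = generate(SyntheticSpec(seed=42))
pathways = filter_benchmark(ds.pathways, ds.proteins)   # the benchmark rules
table = build_table(pathways, ds.proteins, ds.universe)
print(f"{len(table.pathway_ids)} pathways x {table.n_features} features")
results = PathwayClassModel.from_feature_table(table).fit(depth=15)
print(results.summary())
```

prints

```
120 pathways x 552 features
Pathway classification — incremental feature selection
==========================================================
pathways:            120
classes:             6 (Cellular Processes, Environmental Information Processing, Genetic Information Processing, Human Diseases, Metabolism, Organismal Systems)
features available:  552
IFS depth:           15
best classifier:     NNA
best subset size:    10
jackknife accuracy:  0.9750
----------------------------------------------------------
top features:
   1. GO:0000016.enrich
   2. GO:0000001.enrich
   3. GO:0000010.enrich
   4. GO:0000022.enrich
   5. mean.aac.K
   6. mean.aac.G
   7. GO:0000023.enrich
   8. GO:0000017.enrich
   9. GO:0000006.enrich
  10. GO:0000012.enrich
```

120 of 120 generated pathways survive filtering; the table has
88 + 264 + 200 columns for the 200-term universe. Ten features —
mostly enrichment scores of planted signature terms, plus two
composition aggregates — classify 97.5 % of pathways correctly under
leave-one-out. `results.confusion_matrix()`, `results.jackknife_report()`
and `results.plot_ifs()` give the per-class breakdown and the IFS curve.

The same pipeline runs from the shell on KGML or edge-list inputs:

```sh
pathclass synth --seed 42 --out data/
pathclass features --edges data/pathways.tsv --fasta data/proteins.fasta \
    --annotations data/annotations.tsv --labels data/labels.tsv --out table.tsv
pathclass rank --table table.tsv --depth 50 --out-prefix ranked
pathclass ifs --table table.tsv --depth 15 --out curve.tsv
```

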