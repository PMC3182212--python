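# Methods

## Data model and benchmark filtering

A pathway is a simple digraph of proteins: duplicate arcs collapse,
self-loops are allowed, arc subtypes (activation vs inhibition) are
discarded because the feature set uses unlabeled arcs only. KGML input
maps gene-type entries to vertices and relations to arcs; compound
entries and group entries are dropped (relations touching them are
skipped with a warning, and the drop count is logged). Sequences are
sanitized to the 20 standard residues — the non-standard letters B, J,
O, U, X, Z are deleted rather than remapped, since every property
alphabet below is defined only on the standard residues.

Benchmark filtering removes, per pathway, every protein lacking either
a GO annotation or a usable sequence, together with its incident arcs,
and then excludes pathways left with fewer than three proteins. The
order of surviving pathways is preserved so downstream output is
reproducible.

## Arc weights

Each protein is a binary vector over the fixed, ordered term list of
the annotation universe; an arc's weight is the cosine of its endpoint
vectors, in [0, 1]. A zero-norm vector (possible only before
filtering) gets weight 0 by convention. Terms are used exactly as
annotated — no ancestor propagation through the ontology DAG is
applied, and no information-content similarity is involved; the weight
is pure annotation overlap. Whether the universe is restricted to one
GO namespace is left to the supplied term list.

## Graph feature conventions

The 88 graph features follow fixed conventions wherever the verbal
definitions leave room:

* **Variance** is always the population variance (so single-element
  sets are well-defined with variance 0); the median of an even-length
  list is the mean of the two central values; statistics of empty sets
  are 0, never NaN.
* **Cutoff comparisons are strict** (weight > c), uniformly across the
  topology-change and local-density groups.
* **Neighborhoods exclude the vertex itself**: a self-loop counts in
  |E|, in the density denominator |V|², and in the adjacency matrix,
  but does not make a vertex its own neighbor and does not contribute
  to degrees.
* **Degree correlation** scores a neighbor by its total degree
  (in + out); the directional reading (in-degree of in-neighbors,
  out-degree of out-neighbors) is available via
  `neighbor_degree="directional"`.
* **Topological overlaps**: T₁ and T₂ normalize by the in-degree n₁,
  T₃ by the out-degree n₂. For T₄ (out-out overlap) the default
  denominator is n₂, by symmetry with T₃; `t4_denominator="in"`
  selects the alternative. Terms with a zero divisor are 0, and the
  mean runs over all ordered pairs j ≠ i.
* **Topology change** is normalized by the arc count at the lower
  cutoff of each consecutive pair, guarded by max(·, 1) — a "change
  rate" relative to the graph it shrinks from.

Singular values come from the 0/1 adjacency matrix (top three,
zero-padded). The whole block is cross-checked in the test suite
against an independent loop-based enumeration on random digraphs.

## Physicochemical descriptors

The four Dubchak-style CTD alphabets (hydrophobicity, normalized van
der Waals volume, polarity, polarizability) are fixed three-class
residue tables held in `physchem.py` and swappable via
`PropertyAlphabet`. Composition is a class percentage; transition
between classes a and b counts adjacent positions carrying {a, b} in
either order, as a percentage of L−1 (0 when L = 1); distribution
reports the sequence position (as % of L) of the 1st occurrence, the
ceil(q·m)-th occurrence for q ∈ {0.25, 0.5, 0.75}, and the last
occurrence of each class, with five zeros for an absent class.

Secondary structure and solvent accessibility are, in the original
setting, per-residue *predictions* from external programs. This
package does not wrap a predictor: the defaults are deterministic
residue-class coders — a Chou–Fasman-style conformational-preference
table (helix formers AELMQKRH, strand formers VIYCWFT, coil formers
GNPSD) and the sign of the Kyte–Doolittle hydropathy (A, C, F, I, L,
M, V buried) — and precomputed coded strings can be supplied per
protein wherever higher-fidelity structure information exists. The
descriptor pipeline downstream of the coded string is identical either
way.

Descriptors are z-scored column-wise with the population standard
deviation; constant columns map to 0. Standardization statistics are
computed over **all proteins of the loaded corpus** and frozen before
pathway aggregation (per-pathway scaling would destroy the mean/max
contrast between pathways); they can be persisted to TSV so held-out
pathways are standardized identically. Aggregation is the mean and the
max over the pathway's proteins: 132 × 2 = 264 features.

## Enrichment scores

Scores are the upper-tail (over-representation) hypergeometric
probability, −log₁₀ P(X ≥ k), with k counting distinct pathway
proteins per term. The tail is evaluated with scipy's hypergeometric
survival function and verified against exact rational tail sums in the
tests; scores are capped at 300 so the block stays finite when the
tail underflows double precision. No multiple-testing correction is
applied — scores are features, not inferences. The background size N
defaults to the number of distinct annotated proteins in the loaded
annotation set and can be overridden in configuration where a fixed
proteome-wide background is wanted.

## Feature ranking

Continuous features are discretized into three states at μ ± σ
(population σ, per column over the full table), the convention of the
original mRMR program for continuous data. Mutual information is the
plug-in estimate in bits. The mRMR list uses the MID ("difference")
scheme; MIQ is not implemented. Ranking depth defaults to 500 —
enough for any IFS sweep while avoiding the O(N²·rows) cost of
ranking all features — and ties break deterministically toward the
lower column index. The MaxRel list (relevance only) always covers
every feature.

## Classification and evaluation

The native classifier is the cosine-distance nearest neighbor rule;
distance ties break toward the lower training-row index. Feature
columns enter the distance as-is (the physicochemical block is already
standardized; graph and enrichment features keep their native scales).
The jackknife (leave-one-out) accuracy is used throughout because it
is unique and deterministic for a given table. IFS evaluates every
prefix of the mRMR list up to the requested depth; the best report is
the maximal accuracy, with ties resolved toward the smaller subset.
SVM or Bayesian classifiers can be swept alongside through the
fit/predict contract (`SklearnAdapter`); they are deliberately not
re-implemented here.

## Synthetic benchmark generator

The generator emulates a labeled multi-class pathway benchmark: each
class owns disjoint signature GO terms; every protein carries each
universe term with probability p_bg except its own class's signature
terms, carried with p_sig — so p_sig = p_bg with zero residue bias is
an exact null. Sequences are drawn i.i.d. from a residue distribution
mixing the uniform with a 4-residue class profile at weight
`residue_bias`; topology is Erdős–Rényi over distinct ordered pairs.

Defaults are the bench conditions used by the tests and the acceptance
script: 6 classes × 20 pathways, 3–25 proteins per pathway, a 200-term
universe with 5 signature terms per class, p_sig = 0.9, p_bg = 0.05,
arc density 0.15, sequence lengths 50–300, residue bias 0.05. Pathway
sizes and sequence lengths reflect typical filtered regulatory
pathways; the residue bias is deliberately mild so that the planted GO
signature remains the primary class signal and composition a secondary
one — the intended regime for the recovery checks (with a strong
compositional bias the physicochemical block dominates the ranking
instead). The 200-term universe keeps the bench table at
88 + 264 + 200 = 552 columns, small enough for the whole
generate→filter→features→rank→IFS chain to run in seconds while
exercising every code path at full fidelity; the feature-layout checks
separately build a table over the full 5218-term universe.

What the generator does **not** emulate: realistic KEGG degree
distributions or motif structure, shared proteins across pathways,
ontology DAG structure among terms, or sequence order/domain
structure. Passing the recovery tests therefore demonstrates that the
pipeline recovers the kind of signal it is built to detect under its
own assumptions — not that any particular accuracy carries over to a
real pathway database snapshot.

## Numerical and degenerate-input choices

Empty neighbor sets, edgeless graphs, single-residue sequences,
absent classes and constant columns all produce defined zeros rather
than NaN; the feature table refuses non-finite cells, naming the
pathway and feature. Feature order is fixed by construction, never by
hash iteration, and rebuilding a table from the same inputs is
bit-identical. Serialization uses 17-significant-digit decimal, which
round-trips IEEE doubles exactly.

## Known limitations

* The six-class benchmark of the original study (146 human KEGG
  pathways against a 2009 database snapshot) is not reproducible
  offline; the package substitutes property checks on generated data
  with known ground truth.
* Plug-in mutual information on ~100 samples is positively biased;
  rankings are comparative, so the bias largely cancels, but absolute
  relevance scores should not be over-read.
* The nearest-neighbor rule has no rejection option: every query gets
  a class.
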