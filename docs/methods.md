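# Methods

## Problem

Supervised protein-function prediction needs negative examples, but GO-style
annotation databases record only what a protein *does*. Treating every
unannotated protein as negative is unsafe: some of them are positives that
simply have not been characterized yet. `netnegsel` implements a
network-based analysis of this problem. Given a weighted protein-interaction
network and two temporal releases of an annotation table, it (i) extracts 17
per-protein features, (ii) measures which features discriminate the
*unreliable* negatives — proteins unannotated in the older release that
acquire the annotation in the newer one, the class written `C_np` — (iii)
evaluates the features for ordinary per-term function prediction, and (iv)
uses them to select "reliable negative" sets under a budget, scoring the
selection by false negatives (selected proteins that were in `C_np`).

## Network model

The input is a STRING-dialect edge list with integer confidence scores in
1..999. Edges below a threshold (default 700, the conventional
high-confidence cutoff) are dropped, surviving scores are scaled by 1/1000,
isolated nodes are removed, and the raw matrix `Ŵ` is normalized

    W = D^{-1/2} Ŵ D^{-1/2},    d_ii = Σ_j Ŵ_ij .

The normalization is scale invariant, so the 1/1000 scaling is a convention
without downstream effect. Shortest paths treat the entries of `W` as edge
costs by default (`weight_as_cost`); `inverse_weight`, `one_minus_weight`
and `hop` are selectable for sensitivity analyses. Path counts (`σ_st`, and
through-counts recovered as `σ_si·σ_it` on the shortest-path condition) use
an absolute tie tolerance of 1e-12 on path costs; `one_minus_weight` is
rejected when unit-weight edges would create zero-cost edges. The summary
statistics report the hop diameter (edges on the longest unweighted shortest
path) and separately the weighted diameter under the configured cost mode.

## The 17 features

Term-unaware: f1/f2 mean and sample variance of a node's incident weights
(variance defined as 0 for a single neighbor), f3 weighted degree, f4 a
weighted local clustering coefficient — total weight of closed triples over
total weight of all triples centered at the node, which reduces exactly to
the unweighted local clustering coefficient when all weights are equal — and
the geometric centralities f6 closeness, f7 Lin's index (closeness times
squared component size, correcting the small-component bias), f8 harmonic
centrality, f9 betweenness. f5 counts a protein's other old-release
annotations (multifunctionality), excluding the term under study to avoid
leaking the label.

Term-aware, computed from the *older* release only: f10 total edge weight to
annotated neighbors (a guilt-by-association score) and f11 its mean; f12–f14
the closeness/Lin/harmonic variants restricted to annotated proteins in the
node's component (the node itself is excluded from the distance sums when it
is annotated, and the empty-set value is 0); f15–f17 the 3Prop random-walk
features `p^j = P^j y`, `j = 1,2,3`, with `P` the row-stochastic
normalization of `W` and `y` uniform over the term's annotated proteins.
`P^j y` is computed by repeated operator application, never by materializing
matrix powers. Note that `(P^j y)_i` equals `1/p` times the probability that
a j-step walk *from i* occupies the positive set; the Monte-Carlo oracle in
the test suite simulates exactly that quantity.

Every feature column is finally normalized to sum to one across proteins
(all-zero columns are left zero with a warning), making ranges comparable
between features of very different magnitudes.

## Feature relevance (CART + SFFS)

For each term with at least 20 `C_np` proteins, the instances are the
old-release non-positives, labelled by `C_np` membership. The wrapper is
sequential floating forward selection around a CART tree (unlimited depth,
minimum leaf size 2): features are added greedily while the inner 3-fold
cross-validated F1 strictly improves (tolerance 1e-12), with conditional
removals while removal strictly improves; F1 is the criterion throughout
because the positives are scarce. The protocol is a triple loop: a
label-stratified split into three non-overlapping subsets, a 3-fold outer CV
inside each subset, and the wrapper's inner 3-fold CV on each outer-training
portion. Every selection event increments per-feature counters; the output
is the proportion of events in which each feature was selected, pooled over
terms. Stratified splitters shrink their fold count to the minority-class
count and skip the event below two; all splits are seeded.

## Function prediction

Per term, labels are the older release's annotations. Two families are
evaluated under a stratified 3-fold outer / 3-fold inner nested CV with F1
for both tuning and scoring: a linear SVM with class weights `(1, (n−p)/p)`
for the `p` positives, tuning `C ∈ {0.01, 0.1, 1, 10, 100}`, and a random
forest tuning `mtry` over `{⌈√d⌉/2, ⌈√d⌉, 2⌈√d⌉, d/2}` clipped to `[1, d]`.
The forest default is 500 trees; the shipped experiments use 50–200 trees, a
problem-size choice recorded below. The ablation repeats the experiment on
f1–f14 removing one feature at a time (the walk features are not ablated).

## Negative selection

For each term a model is trained on the full older release and the
non-positives are ranked by ascending positive-class score — the SVM
decision value, or the forest's *out-of-bag* positive-class probability.
Out-of-bag scoring matters because the candidates are training points:
in-sample forest probabilities just reproduce the training labels. The
ranking forest additionally uses `min_samples_leaf = 10`; fully grown trees
put a large fraction of the pool at probability exactly 0, turning the
bottom of the ranking into an arbitrary tie, whereas moderate leaves give
graded class-frequency estimates. Score ties are broken by protein
identifier for determinism. The first `⌊x·n/100⌋` candidates (never fewer
than one, capped at the pool) are selected for
`x ∈ {1, 5, 10, 15, 20, 25, 30}`, and the false negatives `|selected ∩
C_np|` are averaged across terms. Seven feature configurations are compared:
f15–f17, f1–f14 and f1–f17 each in full, top-5-by-frequency, and
above-mean-frequency variants (top-q ties broken by canonical feature order;
the mean rule is strict). Every cell carries the random-selection
expectation `budget · |C_np ∩ candidates|/|candidates|` as its baseline.

## Synthetic data

The generator emulates the study conditions end to end. Networks are
planted-partition graphs: communities with within/between edge probabilities
(optionally trailing communities kept as separate components, mimicking the
one-large-plus-satellites shape of thresholded interaction networks), edge
scores `threshold + round((999 − threshold)·Beta(2,2))`, and isolated nodes
re-wired into their community. Annotations: per term, old positives are
sampled inside a home community (or grown greedily-assortatively across
communities), plus uniform noise positives at a configurable rate; each
non-positive then converts to a newer-release positive with probability
`sigmoid(α + β·z_i)`, where `z` is the standardized guilt-by-association
score (f10 by default; a per-degree variant and a study-intensity variant
are available as hooks) and `α` is calibrated by bisection so the expected
`|C_np|` hits a target. `β` is the planted effect size in per-SD log-odds:
`β = 0` makes conversions provably independent of the network, large `β`
concentrates them at high f10. Optional background terms (old-release-only,
sampled by a log-normal study-intensity variable) give f5 a realistic spread
without adding conversion structure. Everything is reproducible bit-for-bit
from (config, seed).

Canned fixtures: `tiny` (n=30, 2 terms, full-pipeline smoke runs; its `C_np`
filter is 5 because only ~25 candidates exist per term), `relevance` (n=150,
55 terms, β=3, satellite components, assortative positives) and its `null`
twin (β=0, otherwise identical), `afp` (n=100, 3 terms, dense
between-community wiring so distance features are flat and the positive
neighborhood is the separating signal), and `negsel` (n=160, 8 terms, β
graded over {2, 3, 4}, 20 background terms).

What the generator does not emulate: scale-free degree distributions, GO
term co-occurrence and hierarchy, annotation-evidence heterogeneity, and
identifier-mapping noise. Passing tests therefore show that the pipeline
recovers planted effects of the stated form at desk scale, not that the
paper-scale biological findings replicate.

## Numerical and design choices

* Path-count ties: exact accumulation with 1e-12 cost tolerance.
* Duplicate input edges: identical rows deduplicated; conflicting scores are
  an error; self-loops dropped with a warning.
* Revoked annotations (present old, absent new) are kept as old-release
  positives and never enter a negative pool — the conservative choice for a
  study of negatives.
* Term universe: intersection of the two releases' term sets.
* SFFS ties among candidate features are broken by canonical feature order;
  the strict-improvement stopping rule guarantees the returned criterion is
  at least the best single feature's and that duplicated columns are never
  both selected.
* F1 is defined as 0 when a classifier predicts no positives.
* The per-term SVM class weight uses the closed form `(1, (n−p)/p)`; the
  forest is left unweighted.
* Experiment problem sizes (fixture dimensions above, forests of 50–200
  trees, 55-term relevance runs) were chosen so the full suite and the
  acceptance script run comfortably on one CPU; the protocol itself (triple
  loop, nested CV, budget grid) is never reduced.

## Known limitations

* Wrapper selection frequencies under a label-independence null are not
  exchangeable across features: strongly rank-correlated features (the six
  distance-based centralities) share selection mass and land systematically
  below the pool mean, while uncorrelated high-granularity features land
  above it. The null-uniformity check in the acceptance suite documents this
  honestly rather than asserting a property the estimator does not have.
* Under a conversion model that is logistic in a single monotone score, a
  linear ranker is structurally near-optimal, so the forest's advantage in
  negative selection emerges only when representations include the walk
  features whose interactions the linear model cannot exploit; the
  acceptance check compares the selectors on the full 17-feature
  representation for that reason.
* Betweenness is O(n³) via the cached path counts — fine at fixture scale,
  not intended for proteome-scale networks.
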