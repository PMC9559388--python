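# Methods

`mutclass` implements a pan-tumor-type classification analysis over
somatic mutation profiles: each sample is its set of mutated genes plus
a class label, and the pipeline turns those sets into features, screens
and ranks the features, selects a compact predictive prefix, and
extracts human-readable decision rules. This note documents the models,
the defaults and their rationale, the synthetic study design, and the
numerical choices.

## Feature encodings

**Enrichment features.** For a sample with mutated-gene set `G_p` and an
annotation term with gene set `G_t`, over a universe of `N` genes, let
`n = |G_p|`, `M = |G_t|`, `m = |G_p ∩ G_t|`. The feature value is

    score(p, t) = −log10  Σ_{k=m}^{min(n,M)}  C(M,k) C(N−M, n−k) / C(N,n),

the upper tail of the hypergeometric distribution: how surprising it is
that the sample's mutations hit the term at least `m` times. One column
per catalog term. The universe is an explicit input (`N = |universe|`);
genes outside it are dropped from both `n` and `m`, which keeps the
statistic self-contained rather than depending on an external gene
dictionary release. `m = 0` scores exactly 0 (tail probability 1), and
scores are capped at 300 (p ≈ 1e−300) so downstream learners stay
finite.

*Numerics.* The tail is never formed in linear space. Log-binomials come
from `lgamma`; small tails use a suffix log-sum-exp over the pmf; tails
near 1 are computed as `log1p(−head)` from the complementary head mass,
which preserves *relative* accuracy of the log as the tail approaches 1
(a plain log-sum-exp loses ~7 digits there). Against exact integer
enumeration over every admissible `(N ≤ 60, M, n, m)` the worst relative
error is ~2e−13.

**Text features.** Each sample's gene set becomes one "sentence" (gene
symbols as words, order randomized by a seeded shuffle — a mutation set
has no natural order, and a fixed lexicographic order would create
spurious window artifacts). Skip-gram with negative sampling (5 noise
words, unigram^0.75 noise distribution, linearly decaying learning rate
from 0.025) is trained on the corpus; a sample's feature vector is the
arithmetic mean of its genes' vectors. Default dimension 256.

The trainer is an in-package, JIT-compiled per-pair SGD loop (the
classic word2vec update). A token's exported embedding is the **sum of
its input and output vectors**: two genes that always co-occur predict
each other, which aligns input-with-output vectors; summing makes that
relation visible as input-space cosine similarity, which the mean-pooled
sample features rely on.

**Network features.** A weighted gene-interaction graph (edge weights =
interaction confidence in (0,1]) is explored by second-order biased
random walks: from node `v` with predecessor `t`, the step to `x` has
probability ∝ `α(t,x)·w(v,x)` with `α = 1/p` for backtracking, 1 for
nodes adjacent to `t`, `1/q` otherwise; the first step is weight-
proportional. Defaults `p = q = 1` (a first-order weighted walk, for
which a fast path is used), walk length 80, 10 walks per node. Walks are
skip-gram sentences; sample vectors are mean node vectors over the
sample's embedded genes (genes absent from the graph are skipped; a
sample with none gets a zero vector and a warning). Default dimension
500.

## Screening

Shadow-feature screening: each iteration appends an independently
permuted copy of every candidate column, fits a 200-tree random forest
on `[originals | shadows]`, and credits a hit to each feature whose
importance exceeds the **maximum** shadow importance. After each
iteration a feature's hit count is tested against Binomial(t, 1/2) with
Bonferroni correction over the still-undecided features (α = 0.05
default): significantly many hits → accepted, significantly few →
rejected, survivors at the cap (default 100 iterations) → tentative.
Rejected features are dropped from later fits. Tentative features are
excluded downstream by default. Constant columns are auto-rejected with
a warning.

## Ranking

Four complementary rankers produce ordered lists of the screened
features:

* **lasso** — one-vs-rest L1 regressions on standardized features
  against class indicators; score = max |coefficient| over classes.
  Default `alpha = 0.01`: with unit-variance features and 0/1 targets,
  `alpha = 1.0` (the common library default for generic regression)
  drives every coefficient to exactly zero, making the ranking vacuous.
* **mrmr** — greedy maximum-relevance-minimum-redundancy, difference
  form: features are discretized to 3 states at mean ± sd; the first
  pick maximizes I(f; y), thereafter `I(f; y) − mean_{s∈S} I(f; s)`.
  Ties break by input order.
* **mcfs** — Monte-Carlo feature selection: `c = 20` stratified
  resamplings × `s = 100` random projections of `⌈0.05·d⌉` features,
  each training an entropy decision tree. A feature's relative
  importance accumulates, over every node splitting on it,
  `wAcc^u · IG(node) · (n_node/n_tree)^v` with `u = v = 1` and `wAcc`
  the tree's class-balanced accuracy on the held-out part. RI = 0
  features are dropped from the list (recorded in metadata).
* **gbdt** — a 100-tree LightGBM ensemble (31 leaves, learning rate
  0.1); score = number of splits using the feature, not gain.

## Incremental feature selection

Prefixes of a ranked list (step 5 by default, final prefix = full list)
are each evaluated by stratified 10-fold cross-validation. Within each
fold the *training part only* is rebalanced by SMOTE — every minority
class is upsampled to the majority count with synthetic points
`x + u·(x_nn − x)`, `u ~ U(0,1)`, `x_nn` one of the k = 5 nearest
same-class neighbors — and a classifier is fit (decision tree, 100-tree
random forest, or RBF-kernel SVM with C = 1, all with fixed reference
defaults). Metrics are pooled over the out-of-fold predictions rather
than averaged per fold: with classes of a few dozen samples, per-fold
F1 estimates are noisy and pooling is the stabler choice.

Per-class precision/recall/F1 use the 0/0 → 0 convention. The weighted
F1 (class-support-weighted mean of per-class F1) is the selection
objective, appropriate under class imbalance. The multiclass Matthews
correlation coefficient is computed in covariance form over one-hot
true/predicted matrices, `cov(X,Y)/√(cov(X,X)·cov(Y,Y))` with the
covariance summed over class columns; this equals the standard
confusion-matrix closed form (verified to 1e−12 on random confusions).

The **optimal** prefix is the smallest one attaining the maximum
weighted F1 (parsimony as the tie-break). The **feasible** prefix is the
smallest one within δ = 0.05 of that maximum — an explicit surrogate for
the informal "high performance with fewer features" model choice, which
otherwise follows no closed rule.

## Rules and reports

A decision tree fit on all samples restricted to the optimal features is
unrolled into one IF-THEN rule per leaf; redundant thresholds on a
feature collapse to the tightest interval, the rule's class is the leaf
majority, support is the leaf's training count and purity its majority
fraction. Rule-based prediction replays the tree exactly (asserted on
training data and fresh draws). Companion reports compute exact
membership tiers of the per-method feature sets (core = features in all
sets) and the breakdown of any feature list by type
(enrichment/text/network).

## Synthetic study design

The generator plants a recoverable ground truth: each class has driver
term(s) whose genes receive a `signal_fraction` share of that class's
mutation draws, the rest falling uniformly on the universe. Per-sample
burden is negative-binomial (mean 60, dispersion 2, floored at 3
mutations) — heterogeneous, like tumor mutation burden. Class sizes are
imbalanced by default (160/60/140/80/100/60). The interaction graph
connects within-term gene pairs with probability 0.1 and background
pairs with 0.002, weights Beta(2,2) rescaled to (0.15, 0.999], so graph
communities align with annotation terms.

Reference desk-scale conditions (the defaults, used by the test-suite
and the acceptance script): 2,000 genes, 150 terms (sizes 10–200), 6
classes, 600 samples, `signal_fraction = 0.5`, text and network
embeddings at 32 dimensions with shortened walks (length 40, 5 per
node). A full pipeline run takes a few minutes on one CPU.
`drivers_per_class = 1`: with disjoint driver assignment the recovery
question ("are the planted terms ranked on top?") stays sharp, and a
small driver set is the only regime in which a top-decile rank for the
*median* driver is even geometrically possible once composite features
enter the candidate set.

What the generator does **not** emulate: trinucleotide mutational
signatures, gene length and copy-number biases, inter-class driver
sharing, and annotation-graph structure (terms are sampled
independently, not nested). Passing recovery tests therefore shows the
machinery is sound under the planted model, not that real cohorts would
yield comparable accuracy.

### A structural note on driver ranks

In a K-class problem a planted driver term is a *one-class indicator*;
its label information is bounded by H(1/K) (≈ 0.45 nats at K = 6),
whereas an embedding dimension — a composite encoder of all classes at
once — can carry up to log 3 ≈ 1.1 nats after 3-state discretization.
On the reference cohort every one of the 32 text dimensions measures
above the one-class ceiling, so information-based rankers (mRMR, MCFS)
necessarily place all drivers below the text block; coefficient- and
split-based rankers (lasso, GBDT) favor single-class discriminators
more and rank drivers near, but not inside, the top decile. The
corresponding end-to-end assertion in the test-suite documents this
tension and is expected to fail on the mRMR/MCFS side under the
reference conditions; the classification-performance assertion (weighted
F1 ≥ 0.85) passes with a wide margin.

## Known limitations

* The skip-gram trainer is single-threaded and processes pairs in a
  fixed seeded order; it trades throughput for bit-for-bit
  reproducibility.
* SMOTE interpolates in the raw feature space; with mixed feature
  scales the k-NN geometry is dominated by the widest features.
  Enrichment scores (0–300) and embedding coordinates (≈ ±2) co-exist
  in the pipeline, which matches the source method's behavior but is a
  known caveat of SMOTE generally.
* Boruta-style screening inherits random-forest importance biases
  (continuous features with many split points are slightly favored).
* `evaluate_prefix` refits from scratch for every prefix; IFS cost is
  linear in the number of grid points times the CV cost.
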