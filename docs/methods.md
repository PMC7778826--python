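# Methods

## Problem setting

`psnstack` classifies tabular clinical records with a rare binary outcome —
the motivating case is predicting clinical pregnancy per intrauterine
insemination (IUI) treatment cycle from couple-level features — and ranks the
features by their contribution to that prediction.  The method has three
stages: (1) standard preprocessing of a mixed-type table into a dense numeric
matrix in [0, 1]; (2) per-record *patient-similarity complex networks* from
which 17 centrality-contrast features are engineered; (3) a two-layer stacked
ensemble with diversity-selected members and validation-accuracy-weighted
voting.

## Patient-similarity networks

For a record x to be classified, three weighted undirected graphs are built
over the preprocessed training records:

* **CN1** — x plus all training records;
* **CN2** — x plus the positive-labelled training records;
* **CN3** — x plus the negative-labelled training records.

Nodes i, j are joined when their Euclidean distance d(i, j) (over the feature
columns only; the label is never used) is strictly below a threshold
τ = τ_factor × (mean pairwise distance).  τ is computed once from CN1 and
shared by CN2/CN3, so the class networks are edge-subsets of CN1 restricted
to same-class pairs plus query edges; lowering τ_factor provably sparsifies
the graph.  The default τ_factor is 0.7.  Edge weights are
w(i, j) = d(i, j) / max pairwise distance, i.e. normalized **dissimilarities**
in [0, 1].  When x is itself a training record, its labelled copy is removed
from all three node sets so its own label cannot leak into its features.

Weights-as-dissimilarities drives the metric conventions:

* path-based statistics (closeness, betweenness, minimum shortest-path
  length) use w as edge length;
* count-based statistics (degree, clustering coefficient, two-hop neighbour
  count, eigenvector centrality) use the binary adjacency;
* weighted degree sums the literal w of adjacent edges.

An alternative reading — inverting w into a similarity before path
computations — is defensible; the literal-dissimilarity reading is
implemented because it requires no extra transform, and the choice is
localized in `psnstack.network`.

Degenerate conventions: an isolated node has degree, weighted degree,
closeness, betweenness, eigenvector, clustering and two-hop count 0 and an
infinite minimum shortest-path length (a sentinel resolved during feature
engineering); clustering of a degree-<2 node is 0; duplicate records form
zero-weight edges, and a node whose reachable path lengths sum to zero takes
the maximum finite closeness in its network.  Eigenvector centrality is the
principal eigenvector of the binary adjacency of the node's connected
component, obtained by power iteration on A + I (same eigenvector, but
convergent on bipartite components) to tolerance 1e-10, L2-normalized.

Networks larger than `size_limit` (default 2000 nodes) are partitioned by
Louvain modularity on the binary adjacency (distances are not affinities, so
the weighted modularity would invert the intended structure), and a node's
metrics are computed on its community's induced subgraph.  Below the limit
the whole network is one community, so metrics equal whole-network metrics.

## The 17 engineered features

With m_k(x) the query's statistic in CN_k and n_k(x) its max-normalized
version (statistic divided by the maximum over that network's nodes):

* F1–F6 = (m_2 − m_3) / m_1 for degree, weighted degree, closeness,
  eigenvector, betweenness, clustering;
* F7 = minimum shortest-path length ratio CN2/CN3, with ∞/∞ → 1 and
  finite/∞ → 0;
* F8 = two-hop neighbour count ratio CN2/CN3;
* F9–F12 = plain CN2/CN3 ratios of degree, closeness, eigenvector,
  betweenness;
* F13–F17 = (n_2 − n_3) / max(n_2, n_3) for degree, closeness, eigenvector,
  betweenness, clustering.

All divisions pass through `safe_ratio`: 0/0 → 0, x/0 → ±cap, and every
quotient is clamped to magnitude ≤ cap (default 10).  F13–F17 are bounded in
[−1, 1] by construction and need no cap.  The driving hypothesis is that a
record is denser among training records of its own class, so positives push
F1–F6 positive and the ratios above 1.  Swapping the class labels negates the
contrast features and inverts the ratios, which is regression-tested.

Two under-determined readings were fixed as follows: F7's "shortest path
from the node" is the distance to the *nearest* other reachable node of that
network; "normalized" in F13–F17 is per-network max-scaling.

## Stacked ensemble

Six learner families are available in both layers: logistic regression, SVM,
decision tree, random forest, AdaBoost, LightGBM.  Fitting proceeds as:

1. a stratified 20% validation split is held out;
2. the remaining training portion is balanced by duplicating minority
   records uniformly at random (oversampling is confined to learner fitting —
   validation and test folds are never resampled);
3. candidates (one per hyperparameter-grid cell per family) are fitted and
   ranked by validation accuracy, then greedily admitted while their
   |Q-statistic| with every already-admitted member stays ≤ Q_max
   (default 0.9).  Q is Yule's association of two classifiers' correctness
   patterns: Q = (N11·N00 − N01·N10)/(N11·N00 + N01·N10), with a zero
   denominator resolved to 1 for identical patterns and 0 otherwise;
4. the admitted layer-1 members' positive-class scores form the meta-feature
   matrix (a hard-label mode exists for strict runs; scores are the default
   because they preserve ranking information);
5. layer 2 is selected the same way on meta-features;
6. each layer-2 member's vote weight is its validation accuracy, and the
   model score is the weighted mean of layer-2 scores; aggregate ≥ 0.5 means
   positive (the tie goes to positive — arbitrary but fixed).

SVMs expose a [0, 1] score through a logistic squashing of the decision
margin rather than refitting with probability calibration; this keeps fits
deterministic and fast at the cost of uncalibrated (but rank-preserving)
scores.

The analytic companion: M independent voters of error ε < 0.5 aggregated by
majority vote err at the binomial upper tail P(X ≥ (M+1)/2), X ~ Bin(M, ε),
computed in exact rational arithmetic (`majority_vote_error`; M must be odd).
Stacking a second layer of M2 voters whose individual errors are at most the
first layer's error ε_L1 yields ε_L2 ≤ tail(M2, ε_L1), hence the ordering
ε_L2 ≤ ε_L1 ≤ ε.  For the worked configuration M = 25, ε = 0.35 the tail is
≈ 0.0604.

## Evaluation

Accuracy, sensitivity and specificity follow their standard confusion-matrix
definitions.  The F-score is deliberately nonstandard here: the harmonic mean
of **sensitivity and specificity** (not precision/recall), matching the
modelled protocol; it is regression-tested against that formula.  AUC uses
the rank-sum concordance formulation with ties counting one half.

**A-Test structural risk.** For each K = 2..K_max (K_max ≤ minority-class
size): split into K stratified folds; balance each fold by oversampling its
within-fold minority; train the pipeline on K−1 balanced folds and record the
misclassification percentage on the held-out balanced fold; Γ_K averages over
folds and Γ^ averages Γ_K over K (0–100 scale; 0 = perfectly stable,
50 = chance on balanced data).  The exact balancing recipe of the original
procedure is not published; within-fold random oversampling was chosen as the
smallest seeded change that makes every fold class-balanced.

**MDA importance.** Baseline accuracy is the stratified K-fold (default 5)
cross-validated accuracy with all features; each feature is removed in turn
and the pipeline retrained on the same fold assignment; the drop in
percentage points, averaged over repetitions with distinct seeds (default
10 at desk scale; the full protocol would use 50), is the feature's score.
Noise features are centred at 0 and may go slightly negative.

**Partial dependence.** The mean model score as one feature is forced to each
grid value with all other features at observed values.

## Synthetic cohorts

Real IUI registries are private, so `psnstack.cohort` generates cohorts with
the registry's statistical skeleton, which is what the test suite and the
acceptance script run on:

* couples contribute 1–7 cycles with probabilities (0.72, 0.22, 0.05,
  0.005, 0.003, 0.001, 0.001) — ~72%/22%/5%/<1% for 1/2/3/>3 cycles;
* the default feature census is 86 numeric / 152 binary / 51 nominal /
  7 binominal.  "Binominal" is generated as a two-level nominal feature
  distinct from the 0/1 binary block, which keeps the census reproducible
  while the term's exact meaning stays open;
* numeric features are standard normal (unit-scale, min–max-scalable),
  binary features Bernoulli(0.3), nominal levels mildly skewed categorical;
* the outcome is Bernoulli with logit(p) = α + u_couple + Σ β_j x_j over a
  configurable informative set; α is calibrated by root finding so the
  marginal positive rate hits the target (default 14.4%); u_couple is a
  couple-level random intercept (sd 0.1 by default) tying repeated cycles
  together, because cycles of one couple are not independent;
* missingness is injected completely at random per feature; the outcome is
  never masked.

What the generator does **not** emulate: realistic marginal distributions or
clinical covariance among features, informative missingness, or
cycle-ordering effects.  Passing tests therefore demonstrate the machinery —
preprocessing, network contrast features, stacking, importance recovery —
under controlled conditions, not clinical performance on real registries.

## Problem sizes and numerical choices

Feature engineering is O(n²) per record (three networks with all-node
betweenness for normalization), so the test suite and the acceptance script
run the end-to-end pipeline on cohorts of ~150–600 records with 3–5 folds,
sizes at which every stage completes in seconds to a few minutes on one CPU.
Other fixed choices: strict ">" in the 20% missing-rate drop; correlation
filter defaults 0.01 (outcome floor) and 0.95 (pairwise ceiling), both
configurable since the protocol only says "very low"/"very high"; dummy
reference level = most frequent level (stable under resampling); constant
columns min–max-scale to 0; Pearson correlation of a constant vector is
defined as 0 with a warning; ratio cap 10; exact-0.5 votes are positive.
Record aggregation (couple × cycle → one row) is assumed done upstream.

## Known limitations

* The all-node betweenness needed for max-normalization dominates runtime;
  very large cohorts rely on community partitioning to stay tractable, which
  makes metrics depend on the partition.
* The dissimilarity-vs-similarity reading of edge weights in path metrics is
  a genuine fork; only the literal reading is implemented.
* MDA on dummy-encoded tables scores indicator columns separately rather
  than whole nominal features.
* Scores are not calibrated probabilities; thresholds other than 0.5 are the
  caller's responsibility.
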