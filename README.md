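# psnstack

Patient-similarity-network feature engineering and stacked-ensemble
classification for tabular clinical cohorts with rare binary outcomes.

The motivating problem is predicting the outcome of an intrauterine
insemination (IUI) treatment cycle — clinical pregnancy or not, positive in
roughly one cycle in seven — from a couple's demographic, clinical and semen
features, and ranking those features by predictive value.  Single classifiers
do poorly here because the two classes overlap heavily; `psnstack`
implements a geometry-driven alternative for any dataset with this shape:
records × mixed-type features, a binary outcome, optional group (couple)
identifiers linking repeated records.

## Method

For each record *x* three weighted undirected *complex networks* are built
over the preprocessed training records: **CN1** (x + all records), **CN2**
(x + positives), **CN3** (x + negatives).  Records i, j are joined when their
Euclidean distance is below τ = 0.7 × mean pairwise distance (shared by all
three networks), with edge weight d(i,j)/max d.  The intuition: a record sits
denser among training records of its own class, so its centrality in CN2
versus CN3 carries label information even when no hyperplane does.  Seventeen
features contrast the query node's statistics between the class networks,
e.g.

    F1 = (degree in CN2 − degree in CN3) / degree in CN1
    F7 = min shortest-path length in CN2 / min shortest-path length in CN3
    F13 = (normalized degree in CN2 − normalized degree in CN3) / max(·,·)

over degree, weighted degree, closeness, eigenvector centrality,
betweenness, clustering coefficient and two-hop counts.  These features —
alone or concatenated with the originals — feed a **two-layer stacked
ensemble**: candidate classifiers (logistic regression, SVM, decision tree,
random forest, AdaBoost, LightGBM over small grids) are ranked by validation
accuracy and greedily admitted under a Q-statistic diversity ceiling; layer-1
scores become meta-features for layer 2; layer-2 votes are weighted by
validation accuracy.  For M independent voters of error ε < 0.5 the majority
vote errs at the binomial tail P(X ≥ (M+1)/2), X ~ Bin(M, ε) — ≈ 0.0604 for
M = 25, ε = 0.35 — and a second stacked layer can only tighten that bound,
which is the analytic motivation for stacking.

Evaluation utilities include accuracy/sensitivity/specificity, the
protocol's F-score (harmonic mean of sensitivity and *specificity*), ROC and
precision-recall curves, leave-one-feature-out mean-decrease-in-accuracy
(MDA) importance, partial dependence, and the A-Test structural-risk sweep
(misclassification percentage under balanced K-fold validation, K = 2..K_max,
averaged into a 0–100 instability score Γ̂).

Real IUI registries are private, so `psnstack.cohort` generates synthetic
cohorts with the registry's skeleton (couples contributing 1–7 cycles,
86/152/51/7 numeric/binary/nominal/binominal features, ~14.4% positive rate,
configurable informative effects and missingness); every stage is tested
against it.  See `docs/methods.md` for the full model description and
conventions.

## Worked example

```python
import numpy as np
from psnstack import CohortConfig, generate_cohort, SimilarityEnsembleModel

config = CohortConfig(
    n_couples=120, n_numeric=8, n_binary=4, n_nominal=2, n_binominal=1,
    informative_features={0: 1.5, 1: -1.5}, base_rate=0.3, seed=42,
)
table, truth = generate_cohort(config)          # 156 records, 42 positives

train = table.subset_rows(np.arange(0, 120))
test = table.subset_rows(np.arange(120, table.n_records))

model = SimilarityEnsembleModel(train, feature_set="both")
results = model.fit(seed=0)
print(results.summary())
report = results.evaluate(test)
print(f"test accuracy {report.accuracy:.3f}  sensitivity {report.sensitivity:.3f}  "
      f"specificity {report.specificity:.3f}  AUC {report.auc:.3f}")
```

prints

```
Similarity-network stacked ensemble
====================================================
records (after preprocessing): 120
retained feature columns:      16
feature set mode:              both
tau factor:                    0.7
seed:                          0
----------------------------------------------------
layer 1 members (1):
  lightgbm               val acc 0.958  {'n_estimators': 60, 'num_leaves': 31}
layer 2 members (1), vote weight = val acc:
  logistic_regression    weight  0.958  {'C': 0.1}
====================================================
test accuracy 0.861  sensitivity 0.800  specificity 0.885  AUC 0.954
```

The preprocessing (missing-rate drops, imputation, dummy coding, min–max
scaling, correlation filtering) kept 16 columns; one LightGBM dominated the
diversity-selected first layer on this small cohort, and the held-out AUC of
0.95 reflects the two strong planted effects.  Where the class structure is
*geometric* rather than linear the engineered features matter most: on an
XOR-blob cohort a logistic-regression-only stack scores AUC 0.57 on the raw
coordinates but 1.00 on the 17 network features.

A command-line front end mirrors the library:

```sh
psnstack simulate --n-couples 300 --seed 1 --out cohort.csv
psnstack fit --config experiment.yaml --output-dir run1/
psnstack rank-features --config experiment.yaml --out ranking.tsv
psnstack a-test --config experiment.yaml --k-max 5
```

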