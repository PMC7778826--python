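"""Classification metrics, structural-risk A-Test, and feature importance.

The metric conventions follow the modelled protocol, including one
deliberately nonstandard definition: the F-score here is the harmonic mean of
*sensitivity and specificity* (not of precision and recall):

    F = 2 * sens * spec / (sens + spec).

The A-Test measures structural risk: for every K = 2..K_max the data is split
into K stratified folds, each fold is balanced by oversampling its minority
class, the pipeline is trained on K-1 folds and its misclassification
percentage on the held-out balanced fold is averaged over folds (Gamma_K);
the mean of Gamma_K over K is the instability score Gamma_hat on a 0-100
scale.  Mean-decrease-in-accuracy (MDA) importance retrains the pipeline
with one feature removed at a time and records the held-out accuracy drop in
percentage points.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve as _sk_pr_curve
from sklearn.metrics import roc_auc_score

from .preprocess import stratified_kfold
from .table import FeatureTable


@dataclass
class EvaluationReport:
    """Confusion counts and the derived scalar metrics."""

    TP: int
    TN: int
    FP: int
    FN: int
    accuracy: float
    sensitivity: float
    specificity: float
    f_score: float
    auc: float | None = None
    pr_curve: list[tuple[float, float]] | None = None

    @property
    def N(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def to_dict(self) -> dict:
        d = {
            "TP": self.TP,
            "TN": self.TN,
            "FP": self.FP,
            "FN": self.FN,
            "N": self.N,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f_score": self.f_score,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class ATestResult:
    """Misclassification percentages Gamma_K per fold count and their mean."""

    gamma_K: dict[int, float]
    K_max: int
    gamma_hat: float

    def minimum(self) -> float:
        return min(self.gamma_K.values())


@dataclass
class MDARanking:
    """Leave-one-feature-out accuracy drops, sorted descending."""

    mda: dict[str, float]  # feature -> mean drop in percentage points
    per_repetition: dict[str, list[float]] = field(default_factory=dict)
    repetitions: int = 1
    seeds: list[int] = field(default_factory=list)

    @property
    def ranking(self) -> list[str]:
        return sorted(self.mda, key=lambda f: -self.mda[f])

    def to_tsv(self, path: str | Path) -> None:
        lines = ["feature\tmda"]
        lines += [f"{f}\t{self.mda[f]:.6g}" for f in self.ranking]
        Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------


def f_score(sensitivity: float, specificity: float) -> float:
    """Harmonic mean of sensitivity and specificity (protocol convention)."""
    if sensitivity + specificity == 0:
        return 0.0
    return 2.0 * sensitivity * specificity / (sensitivity + specificity)


def confusion_metrics(y_true, y_pred, scores=None) -> EvaluationReport:
    """Confusion counts and accuracy / sensitivity / specificity / F-score."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred length mismatch")
    TP = int(np.sum((t == 1) & (p == 1)))
    TN = int(np.sum((t == 0) & (p == 0)))
    FP = int(np.sum((t == 0) & (p == 1)))
    FN = int(np.sum((t == 1) & (p == 0)))
    N = len(t)
    acc = (TP + TN) / N if N else 0.0

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (empty class); returning 0", stacklevel=3)
            return 0.0
        return num / den

    sens = _ratio(TP, TP + FN, "sensitivity")
    spec = _ratio(TN, TN + FP, "specificity")
    auc = None
    if scores is not None and len(np.unique(t)) == 2:
        auc = roc_auc(t, scores)
    return EvaluationReport(
        TP=TP,
        TN=TN,
        FP=FP,
        FN=FN,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        f_score=f_score(sens, spec),
        auc=auc,
    )


def roc_auc(y_true, scores) -> float:
    """AUC by the concordance (rank-sum) formulation; ties count one half."""
    t = np.asarray(y_true, dtype=int)
    if len(np.unique(t)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(t, np.asarray(scores, dtype=float)))


def precision_recall_points(y_true, scores) -> list[tuple[float, float]]:
    """(precision, recall) per distinct score threshold, recall decreasing."""
    t = np.asarray(y_true, dtype=int)
    if len(np.unique(t)) < 2:
        raise ValueError("precision-recall curve needs both classes present")
    precision, recall, _ = _sk_pr_curve(t, np.asarray(scores, dtype=float))
    return list(zip(precision.tolist(), recall.tolist()))


# ----------------------------------------------------------------------
# A-Test structural risk

#: contract: pipeline.fit(X, y) then pipeline.predict(X) -> labels
Pipeline = object
PipelineFactory = Callable[[], Pipeline]


def a_test(
    pipeline_factory: PipelineFactory,
    table: FeatureTable,
    K_max: int,
    seed: int = 0,
) -> ATestResult:
    """Structural-risk sweep over K = 2..K_max balanced folds."""
    y = table.outcome.to_numpy()
    counts = np.unique(y, return_counts=True)[1]
    minority = int(counts.min())
    if not (2 <= K_max <= minority):
        raise ValueError(
            f"K_max must lie in [2, minority size {minority}], got {K_max}"
        )
    X = table.matrix()
    rng = np.random.default_rng(seed)
    gamma: dict[int, float] = {}
    for K in range(2, K_max + 1):
        assignment = stratified_kfold(y, K, seed=int(rng.integers(2**31 - 1)))
        fold_rows = [
            _balance_rows(np.flatnonzero(assignment == k), y, rng) for k in range(K)
        ]
        errors = []
        for k in range(K):
            train_rows = np.concatenate([fold_rows[j] for j in range(K) if j != k])
            test_rows = fold_rows[k]
            pipe = pipeline_factory()
            pipe.fit(X[train_rows], y[train_rows])
            pred = np.asarray(pipe.predict(X[test_rows]), dtype=int)
            errors.append(100.0 * float(np.mean(pred != y[test_rows])))
        gamma[K] = float(np.mean(errors))
    gamma_hat = float(np.mean(list(gamma.values())))  # = sum / (K_max - 1)
    return ATestResult(gamma_K=gamma, K_max=K_max, gamma_hat=gamma_hat)


def _balance_rows(rows: np.ndarray, y: np.ndarray, rng) -> np.ndarray:
    """Oversample the within-fold minority so the fold has equal class counts."""
    fold_y = y[rows]
    classes, counts = np.unique(fold_y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("a fold lost one class entirely; lower K")
    minority = classes[np.argmin(counts)]
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return rows
    extra = rng.choice(rows[fold_y == minority], size=deficit, replace=True)
    return np.concatenate([rows, extra])


# ----------------------------------------------------------------------
# MDA feature importance


def mda_ranking(
    pipeline_factory: PipelineFactory,
    table: FeatureTable,
    repetitions: int = 10,
    seed: int = 0,
    K: int = 5,
) -> MDARanking:
    """Leave-one-feature-out mean decrease in accuracy, in percentage points.

    Per repetition: stratified K-fold accuracy with all features is the
    baseline; each feature is then removed, the pipeline retrained, and the
    accuracy drop recorded.  Repetitions use distinct seeds and are averaged.
    """
    features = table.feature_names
    if len(features) < 2:
        raise ValueError("MDA needs at least two features")
    if repetitions < 1:
        raise ValueError("repetitions must be at least 1")
    y = table.outcome.to_numpy()
    X = table.matrix()
    seeds = [seed + 7919 * r for r in range(repetitions)]
    drops: dict[str, list[float]] = {f: [] for f in features}
    for rep_seed in seeds:
        assignment = stratified_kfold(y, K, seed=rep_seed)
        baseline = _cv_accuracy(pipeline_factory, X, y, assignment, K)
        for j, f in enumerate(features):
            X_wo = np.delete(X, j, axis=1)
            acc = _cv_accuracy(pipeline_factory, X_wo, y, assignment, K)
            drops[f].append(100.0 * (baseline - acc))
    mda = {f: float(np.mean(v)) for f, v in drops.items()}
    return MDARanking(mda=mda, per_repetition=drops, repetitions=repetitions, seeds=seeds)


def _cv_accuracy(factory, X, y, assignment, K) -> float:
    accs = []
    for k in range(K):
        train = assignment != k
        test = ~train
        pipe = factory()
        pipe.fit(X[train], y[train])
        pred = np.asarray(pipe.predict(X[test]), dtype=int)
        accs.append(float(np.mean(pred == y[test])))
    return float(np.mean(accs))


# ----------------------------------------------------------------------


def partial_dependence(model, table: FeatureTable, feature: str, grid) -> np.ndarray:
    """Mean predicted score as ``feature`` is forced to each grid value."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if feature not in table.data.columns:
        raise ValueError(f"feature {feature!r} not in table")
    X = table.data.copy()
    out = np.empty(len(grid))
    for i, v in enumerate(grid):
        X[feature] = v
        out[i] = float(np.mean(model.predict_score(X.to_numpy(dtype=float))))
    return out
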