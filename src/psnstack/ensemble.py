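"""Two-layer stacked ensemble with diversity-aware member selection.

Layer 1 fits a pool of candidate classifiers (logistic regression, SVM,
decision tree, random forest, AdaBoost, LightGBM across small hyperparameter
grids) on the balanced training portion; candidates are ranked by validation
accuracy and greedily admitted unless their Q-statistic association with an
already-admitted member exceeds a diversity ceiling.  The admitted learners'
positive-class scores become meta-features for layer 2, whose members are
selected the same way; layer-2 scores are aggregated by voting weighted by
each member's validation accuracy.

The module also carries the analytic error-rate results for independent
majority voters: the layer error is the binomial upper tail
P(X >= (M+1)/2), X ~ Binomial(M, eps), evaluated in exact rational
arithmetic, and stacking a second layer can only tighten that bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from lightgbm import LGBMClassifier

FAMILIES = (
    "logistic_regression",
    "svm",
    "decision_tree",
    "random_forest",
    "adaboost",
    "lightgbm",
)


class BaseLearner:
    """A classifier family + hyperparameters exposing fit / predict / score.

    ``score`` returns the positive-class score in [0, 1] (predicted
    probability; for SVMs a logistic squashing of the decision margin).
    """

    def __init__(self, family: str, hyperparameters: dict | None = None, seed: int = 0):
        if family not in FAMILIES:
            raise ValueError(f"unknown learner family {family!r}")
        self.family = family
        self.hyperparameters = dict(hyperparameters or {})
        self.seed = seed
        self._est = _make_estimator(family, self.hyperparameters, seed)
        self.fitted = False

    def fit(self, X, y) -> "BaseLearner":
        self._est.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        self.fitted = True
        return self

    def predict(self, X) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return np.asarray(self._est.predict(np.asarray(X, dtype=float)), dtype=int)

    def score(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            if hasattr(self._est, "predict_proba"):
                proba = self._est.predict_proba(X)
                pos = list(self._est.classes_).index(1)
                return proba[:, pos]
            # margin-based classifiers: squash the signed distance to [0, 1]
            margin = self._est.decision_function(X)
            return expit(margin)

    def accuracy(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=int)))

    def clone_unfitted(self) -> "BaseLearner":
        return BaseLearner(self.family, self.hyperparameters, self.seed)

    def __repr__(self) -> str:
        return f"BaseLearner({self.family}, {self.hyperparameters})"


def _make_estimator(family: str, params: dict, seed: int):
    if family == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if family == "svm":
        return SVC(random_state=seed, **params)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **{"n_estimators": 100, **params})
    if family == "adaboost":
        return AdaBoostClassifier(random_state=seed, **{"n_estimators": 50, **params})
    if family == "lightgbm":
        defaults = {"n_estimators": 60, "verbose": -1, "min_child_samples": 5}
        return LGBMClassifier(random_state=seed, **{**defaults, **params})
    raise ValueError(family)


#: small default hyperparameter grids per family (grid-search candidates)
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "logistic_regression": [{"C": 0.1}, {"C": 1.0}],
    "svm": [{"kernel": "rbf", "C": 1.0}, {"kernel": "linear", "C": 1.0}],
    "decision_tree": [{"max_depth": 4}, {"max_depth": None}],
    "random_forest": [{"n_estimators": 100, "max_depth": None}],
    "adaboost": [{"n_estimators": 50}],
    "lightgbm": [{"n_estimators": 60, "num_leaves": 31}],
}


@dataclass
class StackedConfig:
    """Knobs of the stacked ensemble."""

    layer1_families: tuple[str, ...] = FAMILIES
    layer2_families: tuple[str, ...] = FAMILIES
    grids: dict[str, list[dict]] = field(default_factory=lambda: {k: [dict(g) for g in v] for k, v in DEFAULT_GRIDS.items()})
    q_max: float = 0.9
    validation_fraction: float = 0.20
    #: "score" feeds layer 2 the positive-class scores; "label" the hard labels
    meta_mode: str = "score"
    oversample: bool = True

    def __post_init__(self) -> None:
        if self.meta_mode not in ("score", "label"):
            raise ValueError("meta_mode must be 'score' or 'label'")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must lie in (0, 1)")


# ----------------------------------------------------------------------
# diversity and selection


def q_statistic(pred_a, pred_b, truth) -> float:
    """Yule's Q on two classifiers' correctness patterns; near +-1 = low diversity.

    Convention for a zero denominator: 1 if the correctness patterns are
    identical, else 0.
    """
    a = np.asarray(pred_a)
    b = np.asarray(pred_b)
    t = np.asarray(truth)
    if not (len(a) == len(b) == len(t)):
        raise ValueError("prediction/truth length mismatch")
    ca = a == t
    cb = b == t
    n11 = int(np.sum(ca & cb))
    n00 = int(np.sum(~ca & ~cb))
    n01 = int(np.sum(~ca & cb))
    n10 = int(np.sum(ca & ~cb))
    den = n11 * n00 + n01 * n10
    if den == 0:
        return 1.0 if np.array_equal(ca, cb) else 0.0
    return (n11 * n00 - n01 * n10) / den


def select_learners(
    candidates: Sequence[BaseLearner],
    X_val,
    y_val,
    q_max: float = 0.9,
) -> list[BaseLearner]:
    """Accuracy-ranked greedy selection with a Q-statistic diversity ceiling.

    Candidates are visited in decreasing validation accuracy; one is admitted
    unless |Q| with some already-admitted learner exceeds ``q_max``.  At least
    one learner (the most accurate) is always admitted.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    y_val = np.asarray(y_val, dtype=int)
    scored = sorted(
        ((c.accuracy(X_val, y_val), -i, c) for i, c in enumerate(candidates)),
        reverse=True,
    )
    chosen: list[BaseLearner] = []
    chosen_preds: list[np.ndarray] = []
    for _, _, cand in scored:
        pred = cand.predict(X_val)
        if not chosen:
            chosen.append(cand)
            chosen_preds.append(pred)
            continue
        if all(abs(q_statistic(pred, p, y_val)) <= q_max for p in chosen_preds):
            chosen.append(cand)
            chosen_preds.append(pred)
    return chosen


def tune_hyperparameters(
    family: str,
    grid: Sequence[dict],
    X_train,
    y_train,
    X_val,
    y_val,
    seed: int = 0,
) -> dict:
    """Exhaustive grid search on validation accuracy; ties break to grid order."""
    if not grid:
        raise ValueError("empty hyperparameter grid")
    best_params, best_acc = None, -1.0
    for params in grid:
        learner = BaseLearner(family, params, seed).fit(X_train, y_train)
        acc = learner.accuracy(X_val, y_val)
        if acc > best_acc:
            best_params, best_acc = dict(params), acc
    return best_params


# ----------------------------------------------------------------------
# the stacked model


@dataclass
class StackedModel:
    """Fitted two-layer stack: members, meta map and vote weights."""

    layer1: list[BaseLearner]
    layer2: list[BaseLearner]
    vote_weights: np.ndarray
    meta_mode: str
    seed: int
    validation_accuracy: dict[str, float] = field(default_factory=dict)

    def meta_features(self, X) -> np.ndarray:
        """Layer-1 outputs, one column per admitted layer-1 learner."""
        if self.meta_mode == "label":
            cols = [l.predict(X).astype(float) for l in self.layer1]
        else:
            cols = [l.score(X) for l in self.layer1]
        return np.column_stack(cols)

    def predict_score(self, X) -> np.ndarray:
        meta = self.meta_features(X)
        layer2_scores = np.column_stack([l.score(meta) for l in self.layer2])
        return np.array(
            [weighted_vote(row, self.vote_weights)[1] for row in layer2_scores]
        )

    def predict(self, X) -> np.ndarray:
        return (self.predict_score(X) >= 0.5).astype(int)


def weighted_vote(scores, weights) -> tuple[int, float]:
    """Accuracy-weighted mean of member scores; aggregate >= 0.5 -> positive."""
    s = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s.shape != w.shape:
        raise ValueError("scores and weights must have equal length")
    total = w.sum()
    if total <= 0:
        raise ValueError("vote weights must sum to a positive value")
    aggregate = float((w * s).sum() / total)
    return (1 if aggregate >= 0.5 else 0), aggregate


def _candidate_pool(families, grids, seed) -> list[BaseLearner]:
    pool = []
    for family in families:
        for params in grids.get(family, [{}]):
            pool.append(BaseLearner(family, params, seed))
    return pool


def fit_stacked(
    X,
    y,
    config: StackedConfig | None = None,
    seed: int = 0,
) -> StackedModel:
    """Fit the two-layer stack.

    Steps: stratified 20% validation holdout; oversample the remaining
    training portion to balance; fit and diversity-select layer 1; build the
    meta-feature matrix from layer-1 outputs; fit and select layer 2 on
    meta-features; weight layer-2 votes by validation accuracy.
    """
    config = config or StackedConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError("validation split would empty a class")

    X_tr, X_val, y_tr, y_val = train_test_split(
        X,
        y,
        test_size=config.validation_fraction,
        stratify=y,
        random_state=seed,
    )
    if config.oversample:
        X_tr, y_tr = _oversample_xy(X_tr, y_tr, seed)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        layer1_pool = [
            c.fit(X_tr, y_tr)
            for c in _candidate_pool(config.layer1_families, config.grids, seed)
        ]
        layer1 = select_learners(layer1_pool, X_val, y_val, config.q_max)

        def meta(learners, Xm):
            if config.meta_mode == "label":
                return np.column_stack([l.predict(Xm).astype(float) for l in learners])
            return np.column_stack([l.score(Xm) for l in learners])

        M_tr = meta(layer1, X_tr)
        M_val = meta(layer1, X_val)

        layer2_pool = [
            c.fit(M_tr, y_tr)
            for c in _candidate_pool(config.layer2_families, config.grids, seed)
        ]
        layer2 = select_learners(layer2_pool, M_val, y_val, config.q_max)

    weights = np.array([l.accuracy(M_val, y_val) for l in layer2])
    if weights.sum() <= 0:
        weights = np.ones_like(weights)  # degenerate validation: fall back to plain vote
    val_acc = {
        f"layer1_{i}_{l.family}": l.accuracy(X_val, y_val) for i, l in enumerate(layer1)
    }
    val_acc.update(
        {f"layer2_{i}_{l.family}": float(w) for i, (l, w) in enumerate(zip(layer2, weights))}
    )
    return StackedModel(
        layer1=layer1,
        layer2=layer2,
        vote_weights=weights,
        meta_mode=config.meta_mode,
        seed=seed,
        validation_accuracy=val_acc,
    )


def _oversample_xy(X: np.ndarray, y: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    classes, counts = np.unique(y, return_counts=True)
    minority = classes[np.argmin(counts)]
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return X, y
    rng = np.random.default_rng(seed)
    extra = rng.choice(np.flatnonzero(y == minority), size=deficit, replace=True)
    return np.vstack([X, X[extra]]), np.concatenate([y, y[extra]])


# ----------------------------------------------------------------------
# analytic majority-vote error rates


def majority_vote_error(M: int, eps: float) -> float:
    """Error of a majority vote of M independent voters each erring at rate eps.

    P(X >= (M+1)/2) with X ~ Binomial(M, eps), summed exactly in rational
    arithmetic.  M must be odd so the majority is unambiguous.
    """
    if M < 1:
        raise ValueError("M must be at least 1")
    if M % 2 == 0:
        raise ValueError("M must be odd (even M makes the majority ambiguous)")
    if not (0.0 <= eps <= 1.0):
        raise ValueError("eps must lie in [0, 1]")
    p = Fraction(eps).limit_denominator(10**12)
    q = 1 - p
    total = Fraction(0)
    for i in range((M + 1) // 2, M + 1):
        total += comb(M, i) * p**i * q ** (M - i)
    return float(total)


@dataclass
class EnsembleErrorParams:
    """Inputs/outputs of the two-layer analytic error computation."""

    M: int
    eps: float
    M2: int
    eps_b2: float
    eps_L1: float | None = None
    eps_L2: float | None = None


def stacked_error_bound(params: EnsembleErrorParams) -> EnsembleErrorParams:
    """Layer error rates and the second-layer bound.

    eps_L1 = majority_vote_error(M, eps); eps_L2 = majority_vote_error(M2,
    eps_b2), bounded above by majority_vote_error(M2, eps_L1) whenever
    eps_b2 <= eps_L1.  A violated premise is warned about, not fatal.
    """
    eps_L1 = majority_vote_error(params.M, params.eps)
    if params.eps_b2 > eps_L1:
        warnings.warn(
            f"premise violated: eps_b2={params.eps_b2} > eps_L1={eps_L1:.6f}",
            stacklevel=2,
        )
    eps_L2 = majority_vote_error(params.M2, params.eps_b2)
    bound = majority_vote_error(params.M2, eps_L1)
    params.eps_L1 = eps_L1
    params.eps_L2 = eps_L2
    if params.eps_b2 <= eps_L1:
        assert eps_L2 <= bound + 1e-15
    return params
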