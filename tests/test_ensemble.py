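import math

import numpy as np
import pytest
from scipy.stats import binom

from psnstack.ensemble import (
    BaseLearner,
    EnsembleErrorParams,
    StackedConfig,
    fit_stacked,
    majority_vote_error,
    q_statistic,
    select_learners,
    stacked_error_bound,
    tune_hyperparameters,
    weighted_vote,
)


class FixedLearner(BaseLearner):
    """Test double: returns predetermined predictions on the validation set."""

    def __init__(self, preds):
        self._preds = np.asarray(preds, dtype=int)
        self.family = "decision_tree"
        self.hyperparameters = {}
        self.seed = 0
        self.fitted = True

    def predict(self, X):
        return self._preds

    def score(self, X):
        return self._preds.astype(float)


class TestQStatistic:
    def test_identical_predictions_give_one(self):
        p = [1, 0, 1, 1]
        assert q_statistic(p, p, [1, 1, 0, 1]) == 1.0

    def test_direct_formula_evaluation(self):
        # N11=5, N00=3, N01=1, N10=1 -> (15-1)/(15+1) = 0.875
        truth = [1] * 10
        a = [1] * 5 + [0] * 3 + [0] + [1]
        b = [1] * 5 + [0] * 3 + [1] + [0]
        assert q_statistic(a, b, truth) == pytest.approx(0.875)

    def test_balanced_counts_give_zero(self):
        truth = [1] * 8
        a = [1, 1, 0, 0, 0, 0, 1, 1]
        b = [1, 1, 0, 0, 1, 1, 0, 0]
        # N11=2, N00=2, N01=2, N10=2
        assert q_statistic(a, b, truth) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            q_statistic([1, 0], [1], [1, 0])


class TestSelectLearners:
    def test_identical_learners_admit_exactly_one(self):
        y = np.array([1, 0, 1, 0, 1, 1])
        a = FixedLearner([1, 0, 1, 0, 0, 1])
        b = FixedLearner([1, 0, 1, 0, 0, 1])
        chosen = select_learners([a, b], np.zeros((6, 1)), y, q_max=0.9)
        assert len(chosen) == 1

    def test_qmax_one_admits_all_in_accuracy_order(self):
        y = np.array([1, 0, 1, 0])
        good = FixedLearner([1, 0, 1, 0])
        ok = FixedLearner([1, 0, 1, 1])
        bad = FixedLearner([0, 1, 0, 1])
        chosen = select_learners([bad, ok, good], np.zeros((4, 1)), y, q_max=1.0)
        assert chosen == [good, ok, bad]

    def test_greedy_walkthrough_on_frozen_fixture(self):
        """Hand-walked: best admitted; second conflicts (|Q|=1); third diverse."""
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        best = FixedLearner([1, 1, 1, 1, 0, 0, 1, 1])    # acc 6/8
        twin = FixedLearner([1, 1, 1, 1, 0, 0, 1, 1])    # same pattern -> Q = 1
        divers = FixedLearner([1, 1, 1, 0, 1, 0, 0, 1])  # acc 5/8, Q = 1/3 with best
        assert q_statistic(best.predict(None), divers.predict(None), y) == pytest.approx(1 / 3)
        chosen = select_learners([best, twin, divers], np.zeros((8, 1)), y, q_max=0.9)
        assert chosen == [best, divers]

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_learners([], np.zeros((2, 1)), [0, 1])


class TestTuneHyperparameters:
    def test_singleton_grid_returned(self):
        X = np.array([[0.0], [1.0], [0.1], [0.9]])
        y = np.array([0, 1, 0, 1])
        best = tune_hyperparameters("decision_tree", [{"max_depth": 2}], X, y, X, y)
        assert best == {"max_depth": 2}

    def test_grid_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.random((80, 2))
        y = (X[:, 0] + 0.3 * rng.standard_normal(80) > 0.5).astype(int)
        X_val, y_val = X[:30], y[:30]
        grid = [{"max_depth": 1}, {"max_depth": 2}, {"max_depth": 3}, {"max_depth": 8}]
        best = tune_hyperparameters("decision_tree", grid, X, y, X_val, y_val)
        accs = []
        for g in grid:
            l = BaseLearner("decision_tree", g).fit(X, y)
            accs.append(l.accuracy(X_val, y_val))
        assert best == grid[int(np.argmax(accs))]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tune_hyperparameters("svm", [], None, None, None, None)


class TestWeightedVote:
    def test_unanimous_positive(self):
        label, agg = weighted_vote([1.0, 1.0, 1.0], [0.2, 0.5, 0.9])
        assert label == 1 and agg == 1.0

    def test_weighted_mean_example(self):
        label, agg = weighted_vote([0.0, 1.0], [0.9, 0.3])
        assert agg == pytest.approx(0.25)
        assert label == 0

    def test_equal_weights_reduce_to_plain_mean(self):
        scores = [0.2, 0.4, 0.9]
        _, agg = weighted_vote(scores, [1.0, 1.0, 1.0])
        assert agg == pytest.approx(np.mean(scores))

    def test_exact_half_breaks_positive(self):
        label, agg = weighted_vote([0.5], [1.0])
        assert agg == 0.5 and label == 1

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_vote([0.5, 0.5], [0.0, 0.0])


def _small_config():
    return StackedConfig(
        layer1_families=("logistic_regression", "decision_tree", "random_forest"),
        layer2_families=("logistic_regression", "decision_tree"),
        grids={
            "logistic_regression": [{"C": 1.0}],
            "decision_tree": [{"max_depth": 4}],
            "random_forest": [{"n_estimators": 40}],
        },
    )


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(5)
    X = np.vstack([rng.normal(-2, 0.3, (60, 2)), rng.normal(2, 0.3, (60, 2))])
    y = np.array([0] * 60 + [1] * 60)
    return X, y


class TestFitStacked:
    def test_separable_fixture_training_accuracy_one(self, separable):
        X, y = separable
        model = fit_stacked(X, y, _small_config(), seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_meta_feature_width_equals_admitted_layer1(self, separable):
        X, y = separable
        model = fit_stacked(X, y, _small_config(), seed=0)
        assert model.meta_features(X).shape == (len(X), len(model.layer1))

    def test_seed_determinism(self, separable):
        X, y = separable
        m1 = fit_stacked(X, y, _small_config(), seed=3)
        m2 = fit_stacked(X, y, _small_config(), seed=3)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))
        np.testing.assert_allclose(m1.predict_score(X), m2.predict_score(X))

    def test_predict_is_thresholded_score_and_permutation_equivariant(self, separable):
        X, y = separable
        model = fit_stacked(X, y, _small_config(), seed=1)
        scores = model.predict_score(X)
        np.testing.assert_array_equal(model.predict(X), (scores >= 0.5).astype(int))
        perm = np.random.default_rng(0).permutation(len(X))
        np.testing.assert_allclose(model.predict_score(X[perm]), scores[perm])

    def test_manual_forward_pass_on_frozen_model(self, separable):
        X, y = separable
        model = fit_stacked(X, y, _small_config(), seed=2)
        X3 = X[:3]
        meta = np.column_stack([l.score(X3) for l in model.layer1])
        l2 = np.column_stack([l.score(meta) for l in model.layer2])
        w = model.vote_weights
        expected = (l2 * w).sum(axis=1) / w.sum()
        np.testing.assert_allclose(model.predict_score(X3), expected, atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_stacked(np.zeros((10, 2)), np.ones(10), _small_config())

    def test_label_meta_mode_runs(self, separable):
        X, y = separable
        config = _small_config()
        config.meta_mode = "label"
        model = fit_stacked(X, y, config, seed=0)
        assert set(np.unique(model.meta_features(X))) <= {0.0, 1.0}


class TestStackVersusMajorityVote:
    def test_second_layer_not_worse_than_plain_majority_of_layer1(self):
        """The learned second layer should match or beat unweighted majority
        voting of the layer-1 members on held-out data (small tolerance)."""
        rng = np.random.default_rng(21)
        corners = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        which = rng.integers(0, 4, 600)
        X = corners[which] + rng.normal(0, 0.2, (600, 2))
        y = np.array([0, 0, 1, 1])[which]
        model = fit_stacked(X[:400], y[:400], _small_config(), seed=0)
        X_test, y_test = X[400:], y[400:]
        stacked_acc = float(np.mean(model.predict(X_test) == y_test))
        votes = np.column_stack([l.predict(X_test) for l in model.layer1])
        majority = (votes.mean(axis=1) >= 0.5).astype(int)
        majority_acc = float(np.mean(majority == y_test))
        assert stacked_acc >= majority_acc - 0.02


class TestMajorityVoteError:
    def test_single_voter_is_identity(self):
        assert majority_vote_error(1, 0.35) == pytest.approx(0.35)

    def test_symmetric_at_half(self):
        assert majority_vote_error(25, 0.5) == pytest.approx(0.5)

    def test_matches_brute_force_binomial_sum(self):
        expected = sum(
            math.comb(25, i) * 0.35**i * 0.65 ** (25 - i) for i in range(13, 26)
        )
        assert majority_vote_error(25, 0.35) == pytest.approx(expected, rel=1e-12)
        # the classic textbook tail value for this configuration (~0.06)
        assert majority_vote_error(25, 0.35) == pytest.approx(0.0604, abs=5e-5)

    def test_strictly_decreasing_in_m_increasing_in_eps(self):
        errs = [majority_vote_error(M, 0.3) for M in (1, 3, 5, 7, 9, 25)]
        assert all(a > b for a, b in zip(errs, errs[1:]))
        errs_eps = [majority_vote_error(9, e) for e in (0.1, 0.2, 0.3, 0.4, 0.49)]
        assert all(a < b for a, b in zip(errs_eps, errs_eps[1:]))

    def test_monte_carlo_voters_within_three_standard_errors(self):
        M, eps, trials = 5, 0.3, 100_000
        rng = np.random.default_rng(123)
        wrong = (rng.random((trials, M)) < eps).sum(axis=1)
        empirical = float(np.mean(wrong >= (M + 1) // 2))
        analytic = majority_vote_error(M, eps)
        se = math.sqrt(analytic * (1 - analytic) / trials)
        assert abs(empirical - analytic) < 3 * se

    def test_even_m_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            majority_vote_error(4, 0.3)


class TestStackedErrorBound:
    def test_bound_attained_when_eps_b2_equals_eps_l1(self):
        p = EnsembleErrorParams(M=9, eps=0.3, M2=5, eps_b2=majority_vote_error(9, 0.3))
        out = stacked_error_bound(p)
        assert out.eps_L2 == pytest.approx(majority_vote_error(5, out.eps_L1))

    def test_zero_second_layer_error(self):
        out = stacked_error_bound(EnsembleErrorParams(M=9, eps=0.3, M2=5, eps_b2=0.0))
        assert out.eps_L2 == 0.0

    def test_error_ordering_chain(self):
        """eps_L2 << eps_L1 << eps for 25 voters at 0.35 stacked into 5."""
        eps = 0.35
        eps_L1 = majority_vote_error(25, eps)
        out = stacked_error_bound(
            EnsembleErrorParams(M=25, eps=eps, M2=5, eps_b2=eps_L1)
        )
        assert out.eps_L2 < eps_L1 < eps

    def test_premise_violation_warns(self):
        with pytest.warns(UserWarning, match="premise"):
            stacked_error_bound(EnsembleErrorParams(M=9, eps=0.3, M2=5, eps_b2=0.4))
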