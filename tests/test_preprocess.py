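import numpy as np
import pandas as pd
import pytest

from psnstack.preprocess import (
    PreprocessPipeline,
    drop_high_missing,
    dummy_encode,
    filter_irrelevant,
    impute,
    minmax_normalize,
    noop_detector,
    oversample_minority,
    pearson_corr,
    remove_outliers,
    stratified_kfold,
)
from psnstack.table import FeatureTable


def make_table(data: dict, outcome, types=None):
    df = pd.DataFrame(data)
    return FeatureTable(
        data=df,
        outcome=pd.Series(outcome),
        feature_types=types or {},
    )


class TestDropHighMissing:
    def test_feature_above_threshold_dropped_exactly_at_threshold_kept(self):
        t = make_table(
            {
                "a": [1.0, np.nan, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20],
                "b": [np.nan] * 5 + list(range(15)),  # 25% missing -> dropped
            },
            [0, 1] * 10,
            {"a": "numeric", "b": "numeric"},
        )
        # a: 1/20 = 5% missing (kept); b: 25% (dropped)
        out, report = drop_high_missing(t, threshold=0.20)
        assert out.feature_names == ["a"]
        assert "b" in report.dropped_features_missing
        # exactly 20% missing is retained (strict inequality)
        t2 = make_table(
            {"c": [np.nan, 1.0, 2.0, 3.0, 4.0]}, [0, 1, 0, 1, 0], {"c": "numeric"}
        )
        out2, _ = drop_high_missing(t2, threshold=0.20)
        assert out2.feature_names == ["c"]

    def test_fully_observed_table_unchanged(self):
        t = make_table({"a": [1.0, 2.0, 3.0]}, [0, 1, 0], {"a": "numeric"})
        out, report = drop_high_missing(t)
        pd.testing.assert_frame_equal(out.data, t.data)
        assert not report.dropped_features_missing

    def test_all_features_removed_is_an_error_naming_the_threshold(self):
        t = make_table({"a": [np.nan, np.nan, 1.0]}, [0, 1, 0], {"a": "numeric"})
        with pytest.raises(ValueError, match="20%"):
            drop_high_missing(t, threshold=0.20)

    def test_records_above_threshold_dropped_order_preserved(self):
        t = make_table(
            {
                "a": [1.0, np.nan, 3.0, 4.0],
                "b": [1.0, np.nan, 3.0, 4.0],
                "c": [1.0, 1.0, 3.0, 4.0],
            },
            [0, 1, 0, 1],
            {"a": "numeric", "b": "numeric", "c": "numeric"},
        )
        out, report = drop_high_missing(t, threshold=0.5)
        assert 1 in report.dropped_records_missing
        assert out.data["a"].tolist() == [1.0, 3.0, 4.0]


class TestImpute:
    def test_numeric_missing_gets_column_mean(self):
        t = make_table({"a": [1.0, 2.0, np.nan, 3.0]}, [0, 1, 0, 1], {"a": "numeric"})
        out = impute(t)
        assert out.data["a"].tolist() == [1.0, 2.0, 2.0, 3.0]

    def test_categorical_missing_gets_mode(self):
        t = make_table(
            {"a": ["a", "a", "b", None]}, [0, 1, 0, 1], {"a": "nominal"}
        )
        out = impute(t)
        assert out.data["a"].tolist() == ["a", "a", "b", "a"]

    def test_mode_tie_breaks_to_lexicographically_smallest(self):
        t = make_table(
            {"a": ["b", "a", None, None]}, [0, 1, 0, 1], {"a": "nominal"}
        )
        out = impute(t)
        assert out.data["a"].tolist() == ["b", "a", "a", "a"]

    def test_all_missing_column_rejected(self):
        t = make_table({"a": [np.nan, np.nan]}, [0, 1], {"a": "numeric"})
        with pytest.raises(ValueError, match="entirely missing"):
            impute(t)


class TestDummyEncode:
    def test_four_level_nominal_becomes_three_indicators(self):
        t = make_table(
            {"a": ["w", "x", "y", "z", "w"]}, [0, 1, 0, 1, 0], {"a": "nominal"}
        )
        out, report = dummy_encode(t)
        assert len(out.feature_names) == 3
        assert report.reference_levels["a"] == "w"  # most frequent dropped

    def test_numeric_binary_passes_through_single_column(self):
        t = make_table({"a": [0.0, 1.0, 0.0]}, [0, 1, 0], {"a": "binary"})
        out, _ = dummy_encode(t)
        assert out.feature_names == ["a"]
        assert out.data["a"].tolist() == [0.0, 1.0, 0.0]

    def test_unseen_level_at_transform_encodes_as_reference_with_warning(self):
        train = make_table({"a": ["x", "y", "x"]}, [0, 1, 0], {"a": "nominal"})
        _, report = dummy_encode(train)
        new = make_table({"a": ["z", "y"]}, [0, 1], {"a": "nominal"})
        with pytest.warns(UserWarning, match="unseen"):
            out, _ = dummy_encode(
                new,
                encoding_map=report.encoding_map,
                reference_levels=report.reference_levels,
            )
        assert out.data.iloc[0].tolist() == [0.0]  # all-zero indicators


class TestMinMaxNormalize:
    def test_basic_scaling(self):
        t = make_table({"a": [2.0, 4.0, 6.0]}, [0, 1, 0], {"a": "numeric"})
        out, report = minmax_normalize(t)
        assert out.data["a"].tolist() == [0.0, 0.5, 1.0]
        assert report.scaling_params["a"] == (2.0, 6.0)

    def test_constant_column_maps_to_zero(self):
        t = make_table({"a": [3.0, 3.0, 3.0]}, [0, 1, 0], {"a": "numeric"})
        out, _ = minmax_normalize(t)
        assert out.data["a"].tolist() == [0.0, 0.0, 0.0]

    def test_unit_interval_column_unchanged_and_transform_clips(self):
        t = make_table({"a": [0.0, 0.25, 1.0]}, [0, 1, 0], {"a": "numeric"})
        out, report = minmax_normalize(t)
        assert out.data["a"].tolist() == [0.0, 0.25, 1.0]
        new = make_table({"a": [-1.0, 2.0]}, [0, 1], {"a": "numeric"})
        clipped, _ = minmax_normalize(new, scaling_params=report.scaling_params)
        assert clipped.data["a"].tolist() == [0.0, 1.0]


class TestPearsonCorr:
    def test_perfect_positive_and_negative(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert pearson_corr(x, x) == pytest.approx(1.0)
        assert pearson_corr(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_matches_direct_formula_evaluation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        # brute-force evaluation of the correlation definition
        mx, my = x.mean(), y.mean()
        expected = np.sum((x - mx) * (y - my)) / (
            np.sqrt(np.sum((x - mx) ** 2)) * np.sqrt(np.sum((y - my) ** 2))
        )
        assert pearson_corr(x, y) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.8)

    def test_constant_vector_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) == 0.0


class TestFilterIrrelevant:
    def test_pure_noise_feature_dropped_at_default_threshold(self):
        rng = np.random.default_rng(12)
        n = 5000
        y = rng.integers(0, 2, n)
        signal = y + 0.5 * rng.standard_normal(n)
        noise = rng.standard_normal(n)
        t = make_table(
            {"signal": signal, "noise": noise},
            y,
            {"signal": "numeric", "noise": "numeric"},
        )
        assert abs(pearson_corr(noise, y)) < 0.01
        out, report = filter_irrelevant(t)
        assert out.feature_names == ["signal"]
        assert report.dropped_features_correlation["noise"]["rule"] == "low_outcome_correlation"

    def test_exact_duplicate_columns_keep_exactly_one(self):
        rng = np.random.default_rng(3)
        x = rng.random(200)
        y = (x > 0.5).astype(int)
        t = make_table({"a": x, "b": x.copy()}, y, {"a": "numeric", "b": "numeric"})
        out, _ = filter_irrelevant(t)
        assert len(out.feature_names) == 1

    def test_extreme_thresholds_drop_nothing(self):
        rng = np.random.default_rng(5)
        t = make_table(
            {"a": rng.random(50), "b": rng.random(50)},
            rng.integers(0, 2, 50),
            {"a": "numeric", "b": "numeric"},
        )
        out, _ = filter_irrelevant(t, low_out=0.0, high_in=1.0)
        assert out.feature_names == ["a", "b"]


class TestStratifiedKFold:
    def test_registry_sized_cohort_fold_class_counts(self):
        """1622 positives and 9633 negatives over 5 folds split 324-325 / 1926-1927."""
        y = np.array([1] * 1622 + [0] * 9633)
        assignment = stratified_kfold(y, K=5, seed=0)
        for k in range(5):
            fold_y = y[assignment == k]
            assert int((fold_y == 1).sum()) in (324, 325)
            assert int((fold_y == 0).sum()) in (1926, 1927)

    def test_ten_records_five_folds_one_positive_each(self):
        y = np.array([1, 0] * 5)
        assignment = stratified_kfold(y, K=5, seed=1)
        for k in range(5):
            assert (y[assignment == k] == 1).sum() == 1

    def test_folds_partition_all_indices(self):
        y = np.array([0] * 30 + [1] * 12)
        assignment = stratified_kfold(y, K=4, seed=2)
        assert set(assignment) == {0, 1, 2, 3}
        assert len(assignment) == 42

    def test_k_exceeding_minority_count_rejected(self):
        y = np.array([1, 1, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="minority"):
            stratified_kfold(y, K=3, seed=0)


class TestOversampleMinority:
    def test_20_80_becomes_80_80(self):
        rng = np.random.default_rng(0)
        t = make_table(
            {"a": rng.random(100)}, [1] * 20 + [0] * 80, {"a": "numeric"}
        )
        out = oversample_minority(t, seed=0)
        counts = out.outcome.value_counts()
        assert counts[0] == 80 and counts[1] == 80

    def test_balanced_table_unchanged(self):
        t = make_table({"a": [1.0, 2.0, 3.0, 4.0]}, [0, 0, 1, 1], {"a": "numeric"})
        out = oversample_minority(t, seed=1)
        assert out.n_records == 4

    def test_every_original_record_retained(self):
        rng = np.random.default_rng(1)
        values = rng.random(50)
        t = make_table({"a": values}, [1] * 10 + [0] * 40, {"a": "numeric"})
        out = oversample_minority(t, seed=2)
        assert set(np.round(values, 12)) <= set(np.round(out.data["a"], 12))

    def test_single_class_rejected(self):
        t = make_table({"a": [1.0, 2.0]}, [1, 1], {"a": "numeric"})
        with pytest.raises(ValueError):
            oversample_minority(t, seed=0)


class TestRemoveOutliers:
    def test_noop_detector_is_identity(self):
        rng = np.random.default_rng(2)
        t = make_table({"a": rng.random(30)}, rng.integers(0, 2, 30), {"a": "numeric"})
        out, flagged = remove_outliers(t, noop_detector)
        assert out.n_records == 30 and len(flagged) == 0

    def test_planted_extreme_record_flagged(self):
        rng = np.random.default_rng(8)
        X = rng.random((500, 4))
        X[250] = 10.0  # far outside the unit cube
        t = FeatureTable(
            data=pd.DataFrame(X, columns=list("abcd")),
            outcome=pd.Series(rng.integers(0, 2, 500)),
            feature_types={c: "numeric" for c in "abcd"},
        )
        out, flagged = remove_outliers(t)
        assert 250 in flagged
        assert out.n_records == 500 - len(flagged)

    def test_flag_everything_is_an_error(self):
        t = make_table({"a": [1.0, 2.0]}, [0, 1], {"a": "numeric"})
        with pytest.raises(ValueError):
            remove_outliers(t, lambda X: np.ones(len(X), dtype=bool))


class TestPipeline:
    def test_output_dense_numeric_unit_interval(self, processed_cohort):
        _, processed = processed_cohort
        M = processed.matrix()
        assert not np.isnan(M).any()
        assert M.min() >= 0.0 and M.max() <= 1.0

    def test_idempotence_on_training_table(self, small_cohort, processed_cohort):
        _, table, _ = small_cohort
        pipeline, processed = processed_cohort
        again = pipeline.transform(table)
        assert again.feature_names == processed.feature_names
        np.testing.assert_allclose(again.matrix(), processed.matrix(), atol=1e-12)

    def test_transform_does_not_change_fitted_statistics(self, small_cohort):
        config, table, _ = small_cohort
        pipeline = PreprocessPipeline()
        pipeline.fit_transform(table)
        params_before = dict(pipeline.report.scaling_params)
        half = table.subset_rows(np.arange(table.n_records // 2))
        pipeline.transform(half)
        assert pipeline.report.scaling_params == params_before
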