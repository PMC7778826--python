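"""Preprocessing: missingness pruning, imputation, encoding, scaling, filtering.

The chain turns a raw mixed-type :class:`~psnstack.table.FeatureTable` into a
dense numeric matrix in [0, 1]:

1. drop features, then records, whose missing fraction exceeds 20% (strict);
2. impute numeric cells with the column mean, categorical with the mode;
3. dummy-code each nominal feature with m levels into m-1 indicators
   (reference level = most frequent, for encoding stability);
4. min-max scale every column;
5. drop features nearly uncorrelated with the outcome or nearly collinear
   with another feature (Pearson correlation).

All statistics are fitted on training data only; :class:`PreprocessPipeline`
then applies them unchanged to held-out records.  Sampling utilities
(stratified K-fold, minority oversampling, pluggable outlier removal) live
here too.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest
from sklearn.model_selection import StratifiedKFold

from .table import CATEGORICAL_KINDS, FeatureTable


@dataclass
class PreprocessReport:
    """Audit trail of every preprocessing decision."""

    dropped_features_missing: dict[str, float] = field(default_factory=dict)
    dropped_records_missing: dict[int, float] = field(default_factory=dict)
    dropped_features_correlation: dict[str, dict] = field(default_factory=dict)
    encoding_map: dict[str, list[str]] = field(default_factory=dict)
    reference_levels: dict[str, str] = field(default_factory=dict)
    scaling_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    impute_values: dict[str, object] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dropped_features_missing": self.dropped_features_missing,
            "dropped_records_missing": {str(k): v for k, v in self.dropped_records_missing.items()},
            "dropped_features_correlation": self.dropped_features_correlation,
            "encoding_map": self.encoding_map,
            "reference_levels": self.reference_levels,
            "scaling_params": {k: list(v) for k, v in self.scaling_params.items()},
            "impute_values": {k: (v if isinstance(v, str) else float(v)) for k, v in self.impute_values.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ----------------------------------------------------------------------
# individual operations


def drop_high_missing(
    table: FeatureTable, threshold: float = 0.20, report: PreprocessReport | None = None
) -> tuple[FeatureTable, PreprocessReport]:
    """Remove features, then records, with missing fraction strictly above ``threshold``."""
    if not (0.0 <= threshold < 1.0):
        raise ValueError(f"threshold must lie in [0, 1), got {threshold}")
    report = report or PreprocessReport()
    frac_by_col = table.missing_mask.mean(axis=0)
    keep_cols = [c for c in table.feature_names if frac_by_col[c] <= threshold]
    for c in table.feature_names:
        if frac_by_col[c] > threshold:
            report.dropped_features_missing[c] = float(frac_by_col[c])
    if not keep_cols:
        raise ValueError(
            f"every feature exceeds the {threshold:.0%} missing-rate threshold"
        )
    data = table.data[keep_cols]
    frac_by_row = data.isna().mean(axis=1).to_numpy()
    keep_rows = np.flatnonzero(frac_by_row <= threshold)
    for i in np.flatnonzero(frac_by_row > threshold):
        report.dropped_records_missing[int(i)] = float(frac_by_row[i])
    out = FeatureTable(
        data=data.iloc[keep_rows].reset_index(drop=True),
        outcome=table.outcome.iloc[keep_rows].reset_index(drop=True),
        feature_types={c: table.feature_types[c] for c in keep_cols},
        group_ids=None
        if table.group_ids is None
        else table.group_ids.iloc[keep_rows].reset_index(drop=True),
    )
    return out, report


def fit_impute_values(table: FeatureTable) -> dict[str, object]:
    """Column mean (numeric) or mode (categorical), from observed values only.

    Mode ties break to the lexicographically smallest level.
    """
    values: dict[str, object] = {}
    for c in table.feature_names:
        observed = table.data[c].dropna()
        if observed.empty:
            raise ValueError(f"column {c!r} is entirely missing; drop it first")
        if table.feature_types[c] == "numeric":
            values[c] = float(observed.astype(float).mean())
        else:
            counts = observed.value_counts()
            top = counts[counts == counts.max()].index
            values[c] = sorted(top, key=str)[0]
    return values


def impute(
    table: FeatureTable, values: dict[str, object] | None = None
) -> FeatureTable:
    """Fill missing cells with the fitted (or freshly computed) column statistics."""
    values = values if values is not None else fit_impute_values(table)
    out = table.copy()
    for c in out.feature_names:
        if c in values and out.data[c].isna().any():
            out.data[c] = out.data[c].fillna(values[c])
    return out


def dummy_encode(
    table: FeatureTable,
    encoding_map: dict[str, list[str]] | None = None,
    reference_levels: dict[str, str] | None = None,
    report: PreprocessReport | None = None,
) -> tuple[FeatureTable, PreprocessReport]:
    """m-level nominal/binominal feature -> m-1 indicator columns.

    The reference (dropped) level is the most frequent at fit time, which keeps
    encodings stable under resampling.  A level unseen at fit time maps to the
    all-zero (reference) row with a warning.  Binary features pass through as a
    single 0/1 column.
    """
    report = report or PreprocessReport()
    fit_mode = encoding_map is None
    encoding_map = {} if fit_mode else encoding_map
    reference_levels = {} if reference_levels is None else reference_levels

    cols: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    for c in table.feature_names:
        kind = table.feature_types[c]
        if kind == "numeric":
            cols[c] = table.data[c].to_numpy(dtype=float)
            kinds[c] = "numeric"
        elif kind == "binary" and table.data[c].dtype != object:
            cols[c] = table.data[c].to_numpy(dtype=float)
            kinds[c] = "binary"
        else:  # nominal / binominal
            raw = table.data[c].astype(str)
            if fit_mode:
                counts = raw.value_counts()
                top = counts[counts == counts.max()].index
                ref = sorted(top, key=str)[0]
                keep = sorted(lv for lv in counts.index if lv != ref)
                encoding_map[c] = [f"{c}={lv}" for lv in keep]
                reference_levels[c] = ref
            ref = reference_levels[c]
            known = {name.split("=", 1)[1] for name in encoding_map[c]}
            unseen = set(raw.unique()) - known - {ref}
            if unseen:
                warnings.warn(
                    f"column {c!r}: unseen levels {sorted(unseen)} encoded as reference",
                    stacklevel=2,
                )
            for name in encoding_map[c]:
                lv = name.split("=", 1)[1]
                cols[name] = (raw == lv).to_numpy(dtype=float)
                kinds[name] = "binary"
    report.encoding_map = dict(encoding_map)
    report.reference_levels = dict(reference_levels)
    out = FeatureTable(
        data=pd.DataFrame(cols),
        outcome=table.outcome.copy(),
        feature_types=kinds,
        group_ids=None if table.group_ids is None else table.group_ids.copy(),
    )
    return out, report


def minmax_normalize(
    table: FeatureTable,
    scaling_params: dict[str, tuple[float, float]] | None = None,
    report: PreprocessReport | None = None,
) -> tuple[FeatureTable, PreprocessReport]:
    """x -> (x - min) / (max - min) with fit-time min/max; clipped to [0, 1].

    A constant column (max == min) maps to all zeros.
    """
    report = report or PreprocessReport()
    fit_mode = scaling_params is None
    scaling_params = {} if fit_mode else scaling_params
    out = table.copy()
    for c in out.feature_names:
        x = out.data[c].to_numpy(dtype=float)
        if fit_mode:
            scaling_params[c] = (float(np.min(x)), float(np.max(x)))
        lo, hi = scaling_params[c]
        if hi > lo:
            out.data[c] = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
        else:
            out.data[c] = np.zeros_like(x)
    report.scaling_params = dict(scaling_params)
    return out, report


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson linear correlation; a constant vector yields 0 with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least two observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx**2).sum())
    sy = np.sqrt((dy**2).sum())
    if sx == 0.0 or sy == 0.0:
        warnings.warn("correlation of a constant vector is undefined; returning 0", stacklevel=2)
        return 0.0
    return float((dx * dy).sum() / (sx * sy))


def filter_irrelevant(
    table: FeatureTable,
    low_out: float = 0.01,
    high_in: float = 0.95,
    keep_columns: list[str] | None = None,
    report: PreprocessReport | None = None,
) -> tuple[FeatureTable, PreprocessReport]:
    """Drop outcome-irrelevant and mutually redundant features.

    First drop features with |corr(feature, outcome)| < ``low_out``; then for
    every remaining pair with |corr| > ``high_in`` drop the member with the
    smaller |corr with outcome| (tie: the later column).  When
    ``keep_columns`` is given (transform mode) the stored selection is applied
    verbatim instead.
    """
    report = report or PreprocessReport()
    if keep_columns is not None:
        missing = [c for c in keep_columns if c not in table.data.columns]
        if missing:
            raise ValueError(f"stored columns missing from table: {missing}")
        return _select_columns(table, keep_columns), report

    if not (0.0 <= low_out <= 1.0 and 0.0 <= high_in <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    y = table.outcome.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corr_out = {
            c: abs(pearson_corr(table.data[c].to_numpy(dtype=float), y))
            for c in table.feature_names
        }
    survivors = []
    for c in table.feature_names:
        if corr_out[c] < low_out:
            report.dropped_features_correlation[c] = {
                "rule": "low_outcome_correlation",
                "corr_with_outcome": corr_out[c],
            }
        else:
            survivors.append(c)
    if not survivors:
        raise ValueError("correlation filter removed every feature")

    X = table.data[survivors].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        cmat = np.corrcoef(X, rowvar=False)
    cmat = np.nan_to_num(np.atleast_2d(cmat), nan=0.0)
    dropped: set[str] = set()
    for i in range(len(survivors)):
        if survivors[i] in dropped:
            continue
        for j in range(i + 1, len(survivors)):
            if survivors[j] in dropped:
                continue
            r = abs(cmat[i, j])
            if r > high_in:
                a, b = survivors[i], survivors[j]
                # drop the member less correlated with the outcome; tie -> later column
                victim = a if corr_out[a] < corr_out[b] else b
                dropped.add(victim)
                report.dropped_features_correlation[victim] = {
                    "rule": "high_pairwise_correlation",
                    "partner": b if victim == a else a,
                    "pairwise_corr": float(r),
                    "corr_with_outcome": corr_out[victim],
                }
                if victim == a:
                    break
    keep = [c for c in survivors if c not in dropped]
    if not keep:
        raise ValueError("correlation filter removed every feature")
    return _select_columns(table, keep), report


def _select_columns(table: FeatureTable, columns: list[str]) -> FeatureTable:
    return FeatureTable(
        data=table.data[columns].copy(),
        outcome=table.outcome.copy(),
        feature_types={c: table.feature_types[c] for c in columns},
        group_ids=None if table.group_ids is None else table.group_ids.copy(),
    )


# ----------------------------------------------------------------------
# sampling utilities


def stratified_kfold(outcomes: Sequence[int], K: int, seed: int) -> np.ndarray:
    """Fold assignment (0..K-1 per record); per-fold class counts differ by <= 1."""
    y = np.asarray(outcomes)
    if K < 2:
        raise ValueError("K must be at least 2")
    counts = np.unique(y, return_counts=True)[1]
    if K > counts.min():
        raise ValueError(
            f"K={K} exceeds the minority class count ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


def oversample_minority(table: FeatureTable, seed: int) -> FeatureTable:
    """Duplicate minority records uniformly at random until classes balance."""
    y = table.outcome.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversampling needs both classes present")
    minority = classes[np.argmin(counts)]
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    minority_idx = np.flatnonzero(y == minority)
    extra = rng.choice(minority_idx, size=deficit, replace=True)
    order = np.concatenate([np.arange(len(y)), extra])
    return table.subset_rows(order)


OutlierDetector = Callable[[np.ndarray], np.ndarray]


def isolation_forest_detector(
    contamination: float = 0.01, seed: int = 0, **kwargs
) -> OutlierDetector:
    """Off-the-shelf isolation-forest scorer: returns a boolean outlier mask."""

    def detect(X: np.ndarray) -> np.ndarray:
        model = IsolationForest(
            contamination=contamination, random_state=seed, **kwargs
        )
        return model.fit_predict(X) == -1

    return detect


def noop_detector(X: np.ndarray) -> np.ndarray:
    return np.zeros(len(X), dtype=bool)


def remove_outliers(
    table: FeatureTable, detector: OutlierDetector | None = None
) -> tuple[FeatureTable, np.ndarray]:
    """Drop records flagged by the detector; returns (table, flagged indices)."""
    detector = detector or isolation_forest_detector()
    flagged = np.asarray(detector(table.matrix()), dtype=bool)
    if flagged.all():
        raise ValueError("outlier detector flagged every record")
    keep = np.flatnonzero(~flagged)
    return table.subset_rows(keep), np.flatnonzero(flagged)


# ----------------------------------------------------------------------
# fitted pipeline


class PreprocessPipeline:
    """Fit-once / transform-many preprocessing chain.

    ``fit_transform`` learns every statistic (impute values, encodings, scaling
    bounds, retained columns) from the training table; ``transform`` replays
    them on held-out records without refitting, so the training geometry is
    never contaminated by test data.
    """

    def __init__(
        self,
        missing_threshold: float = 0.20,
        low_out: float = 0.01,
        high_in: float = 0.95,
    ) -> None:
        self.missing_threshold = missing_threshold
        self.low_out = low_out
        self.high_in = high_in
        self.report: PreprocessReport | None = None
        self._impute_values: dict[str, object] | None = None
        self._kept_raw_columns: list[str] | None = None
        self._final_columns: list[str] | None = None
        self._raw_types: dict[str, str] | None = None

    @property
    def fitted(self) -> bool:
        return self.report is not None

    def fit_transform(self, table: FeatureTable) -> FeatureTable:
        report = PreprocessReport()
        t, report = drop_high_missing(table, self.missing_threshold, report)
        self._kept_raw_columns = t.feature_names
        self._raw_types = dict(t.feature_types)
        self._impute_values = fit_impute_values(t)
        report.impute_values = dict(self._impute_values)
        t = impute(t, self._impute_values)
        t, report = dummy_encode(t, report=report)
        t, report = minmax_normalize(t, report=report)
        t, report = filter_irrelevant(t, self.low_out, self.high_in, report=report)
        self._final_columns = t.feature_names
        self.report = report
        return t

    def transform(self, table: FeatureTable) -> FeatureTable:
        if not self.fitted:
            raise RuntimeError("pipeline is not fitted")
        cols = [c for c in self._kept_raw_columns if c in table.data.columns]
        missing = set(self._kept_raw_columns) - set(cols)
        if missing:
            raise ValueError(f"table lacks fitted columns: {sorted(missing)}")
        t = _select_columns_raw(table, self._kept_raw_columns, self._raw_types)
        t = impute(t, self._impute_values)
        t, _ = dummy_encode(
            t,
            encoding_map=self.report.encoding_map,
            reference_levels=self.report.reference_levels,
        )
        t, _ = minmax_normalize(t, scaling_params=self.report.scaling_params)
        t, _ = filter_irrelevant(t, keep_columns=self._final_columns)
        return t


def _select_columns_raw(
    table: FeatureTable, columns: list[str], types: dict[str, str]
) -> FeatureTable:
    return FeatureTable(
        data=table.data[columns].copy(),
        outcome=table.outcome.copy(),
        feature_types={c: types[c] for c in columns},
        group_ids=None if table.group_ids is None else table.group_ids.copy(),
    )
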