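"""Model / Results facade over the full similarity-network stacking pipeline.

:class:`SimilarityEnsembleModel` is constructed from a
:class:`~psnstack.table.FeatureTable` (or a DataFrame via
:meth:`~SimilarityEnsembleModel.from_dataframe`); ``fit()`` runs the chain —
preprocessing, per-record CN1/CN2/CN3 networks, the 17 engineered contrast
features, the two-layer stacked ensemble — and returns a
:class:`SimilarityEnsembleResults` carrying the fitted components, validation
diagnostics and a ``summary()`` table.  Prediction and evaluation on new
records hang off the results object.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import StackedConfig, StackedModel, fit_stacked
from .evaluation import EvaluationReport, confusion_metrics
from .features import engineer_table
from .network import DEFAULT_COMMUNITY_SIZE_LIMIT, DEFAULT_TAU_FACTOR
from .preprocess import PreprocessPipeline
from .table import FeatureTable

FEATURE_SET_MODES = ("original", "engineered", "both")


class SimilarityEnsembleModel:
    """Similarity-network feature engineering + stacked-ensemble classifier.

    Parameters
    ----------
    table : FeatureTable
        Raw training records (mixed types, missing values allowed).
    feature_set : {"original", "engineered", "both"}
        Which matrix feeds the ensemble: the preprocessed original features,
        the 17 network-engineered features, or their concatenation.
    tau_factor : float
        Edge threshold as a multiple of the mean pairwise distance.
    missing_threshold, low_out, high_in :
        Preprocessing thresholds (missing-rate drop, outcome-correlation
        floor, pairwise-correlation ceiling).
    stacked_config : StackedConfig, optional
        Ensemble layer families, grids and diversity ceiling.
    """

    def __init__(
        self,
        table: FeatureTable,
        feature_set: str = "both",
        tau_factor: float = DEFAULT_TAU_FACTOR,
        missing_threshold: float = 0.20,
        low_out: float = 0.01,
        high_in: float = 0.95,
        stacked_config: StackedConfig | None = None,
        community_size_limit: int = DEFAULT_COMMUNITY_SIZE_LIMIT,
    ) -> None:
        if feature_set not in FEATURE_SET_MODES:
            raise ValueError(f"feature_set must be one of {FEATURE_SET_MODES}")
        self.table = table
        self.feature_set = feature_set
        self.tau_factor = tau_factor
        self.missing_threshold = missing_threshold
        self.low_out = low_out
        self.high_in = high_in
        self.stacked_config = stacked_config or StackedConfig()
        self.community_size_limit = community_size_limit

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str = "outcome",
        group: str | None = None,
        feature_types: dict[str, str] | None = None,
        **kwargs,
    ) -> "SimilarityEnsembleModel":
        """Build from a DataFrame holding features plus the outcome column."""
        if outcome not in df.columns:
            raise ValueError(f"outcome column {outcome!r} not in DataFrame")
        data = df.drop(columns=[outcome] + ([group] if group else []))
        table = FeatureTable(
            data=data,
            outcome=df[outcome].astype(int).reset_index(drop=True),
            feature_types=dict(feature_types) if feature_types else {},
            group_ids=df[group].reset_index(drop=True) if group else None,
        )
        return cls(table, **kwargs)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0) -> "SimilarityEnsembleResults":
        """Run the full chain and return the fitted results object."""
        pipeline = PreprocessPipeline(
            missing_threshold=self.missing_threshold,
            low_out=self.low_out,
            high_in=self.high_in,
        )
        processed = pipeline.fit_transform(self.table)
        design = self._design_matrix(processed, processed, is_training=True, seed=seed)
        stacked = fit_stacked(design, processed.outcome.to_numpy(), self.stacked_config, seed=seed)
        return SimilarityEnsembleResults(
            model=self,
            preprocess=pipeline,
            training_processed=processed,
            stacked=stacked,
            seed=seed,
        )

    def _design_matrix(
        self,
        table: FeatureTable,
        training: FeatureTable,
        is_training: bool,
        seed: int,
    ) -> np.ndarray:
        if self.feature_set == "original":
            return table.matrix()
        engineered = engineer_table(
            table,
            training,
            tau_factor=self.tau_factor,
            is_training=is_training,
            size_limit=self.community_size_limit,
            seed=seed,
        ).to_numpy()
        if self.feature_set == "engineered":
            return engineered
        return np.hstack([table.matrix(), engineered])


@dataclass
class SimilarityEnsembleResults:
    """Fitted pipeline + ensemble with prediction and reporting methods."""

    model: SimilarityEnsembleModel
    preprocess: PreprocessPipeline
    training_processed: FeatureTable
    stacked: StackedModel
    seed: int

    # ------------------------------------------------------------------
    def _prepare(self, table: FeatureTable) -> np.ndarray:
        processed = self.preprocess.transform(table)
        return self.model._design_matrix(
            processed, self.training_processed, is_training=False, seed=self.seed
        )

    def predict_score(self, table: FeatureTable) -> np.ndarray:
        """Positive-class score in [0, 1] per record."""
        return self.stacked.predict_score(self._prepare(table))

    def predict(self, table: FeatureTable) -> np.ndarray:
        return (self.predict_score(table) >= 0.5).astype(int)

    def evaluate(self, table: FeatureTable) -> EvaluationReport:
        """Confusion metrics (and AUC) of the fitted model on held-out records."""
        scores = self.predict_score(table)
        return confusion_metrics(table.outcome.to_numpy(), (scores >= 0.5).astype(int), scores)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of the fitted stack."""
        lines = [
            "Similarity-network stacked ensemble",
            "=" * 52,
            f"records (after preprocessing): {self.training_processed.n_records}",
            f"retained feature columns:      {len(self.training_processed.feature_names)}",
            f"feature set mode:              {self.model.feature_set}",
            f"tau factor:                    {self.model.tau_factor}",
            f"seed:                          {self.seed}",
            "-" * 52,
            f"layer 1 members ({len(self.stacked.layer1)}):",
        ]
        for i, l in enumerate(self.stacked.layer1):
            acc = self.stacked.validation_accuracy.get(f"layer1_{i}_{l.family}", float("nan"))
            lines.append(f"  {l.family:<22} val acc {acc:.3f}  {l.hyperparameters}")
        lines.append(f"layer 2 members ({len(self.stacked.layer2)}), vote weight = val acc:")
        for i, (l, w) in enumerate(zip(self.stacked.layer2, self.stacked.vote_weights)):
            lines.append(f"  {l.family:<22} weight  {w:.3f}  {l.hyperparameters}")
        lines.append("=" * 52)
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialize the fitted results (learner states, weights, preprocessing)."""
        with open(path, "wb") as fh:
            pickle.dump({"version": 1, "results": self}, fh)

    @staticmethod
    def load(path: str | Path) -> "SimilarityEnsembleResults":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("version") != 1:
            raise ValueError("unrecognized model archive version")
        return payload["results"]
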