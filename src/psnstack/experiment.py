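"""End-to-end experiment runner: K-fold x repetitions over a cohort.

A :class:`RunConfig` names the input (CSV path or synthetic cohort), the
preprocessing thresholds, the network threshold factor, the ensemble layout,
the fold/repetition counts and the feature-set mode; ``run_experiment``
executes preprocess -> networks -> feature engineering -> stacked ensemble ->
evaluation per fold and repetition, aggregates mean +- sd over folds, and
writes every artifact with a manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import CohortConfig, generate_cohort
from .ensemble import StackedConfig
from .evaluation import EvaluationReport, confusion_metrics
from .model import FEATURE_SET_MODES, SimilarityEnsembleModel
from .network import DEFAULT_TAU_FACTOR
from .preprocess import stratified_kfold
from .table import FeatureTable

_KNOWN_KEYS = {
    "input_csv",
    "outcome_column",
    "group_column",
    "missing_token",
    "synthetic",
    "missing_threshold",
    "low_out",
    "high_in",
    "tau_factor",
    "feature_set",
    "k_folds",
    "repetitions",
    "seed",
    "output_dir",
    "meta_mode",
    "validation_fraction",
}


@dataclass
class RunConfig:
    """Everything a full experiment needs; unknown keys are rejected."""

    input_csv: str | None = None
    outcome_column: str = "outcome"
    group_column: str = "couple_id"
    missing_token: str = ""
    synthetic: CohortConfig | None = None
    missing_threshold: float = 0.20
    low_out: float = 0.01
    high_in: float = 0.95
    tau_factor: float = DEFAULT_TAU_FACTOR
    feature_set: str = "both"
    k_folds: int = 5
    repetitions: int = 1
    seed: int = 0
    output_dir: str | None = None
    meta_mode: str = "score"
    validation_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.input_csv is None and self.synthetic is None:
            raise ValueError("either input_csv or a synthetic cohort config is required")
        if self.feature_set not in FEATURE_SET_MODES:
            raise ValueError(f"feature_set must be one of {FEATURE_SET_MODES}")
        if not (0.0 <= self.missing_threshold < 1.0):
            raise ValueError("missing_threshold must lie in [0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be at least 1")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load YAML/JSON config; flag-style overrides win over file keys."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(raw.get("synthetic"), dict):
            syn = dict(raw["synthetic"])
            if "informative_features" in syn:
                syn["informative_features"] = {
                    int(k): float(v) for k, v in syn["informative_features"].items()
                }
            if "cycle_distribution" in syn:
                syn["cycle_distribution"] = tuple(syn["cycle_distribution"])
            raw["synthetic"] = CohortConfig(**syn)
        return cls(**raw)


def load_table(config: RunConfig) -> FeatureTable:
    """Resolve the config's input to a FeatureTable (CSV or synthetic)."""
    if config.input_csv is not None:
        return read_table(config.input_csv, config)
    table, _ = generate_cohort(config.synthetic)
    return table


def read_table(path: str | Path, config: RunConfig) -> FeatureTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return FeatureTable.from_csv(
        path,
        outcome_column=config.outcome_column,
        group_column=config.group_column,
        missing_token=config.missing_token,
    )


@dataclass
class ExperimentResult:
    """Aggregated per-fold evaluation of one experiment."""

    fold_reports: list[EvaluationReport]
    mean: dict[str, float]
    sd: dict[str, float]
    config: RunConfig
    manifest: dict = field(default_factory=dict)


_METRICS = ("accuracy", "sensitivity", "specificity", "f_score", "auc")


def run_experiment(config: RunConfig) -> ExperimentResult:
    """K-fold x repetitions evaluation of the similarity-ensemble model."""
    table = load_table(config)
    y = table.outcome.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate data: a single outcome class")

    reports: list[EvaluationReport] = []
    for rep in range(config.repetitions):
        rep_seed = config.seed + 104729 * rep
        assignment = stratified_kfold(y, config.k_folds, seed=rep_seed)
        for k in range(config.k_folds):
            train = table.subset_rows(np.flatnonzero(assignment != k))
            test = table.subset_rows(np.flatnonzero(assignment == k))
            model = SimilarityEnsembleModel(
                train,
                feature_set=config.feature_set,
                tau_factor=config.tau_factor,
                missing_threshold=config.missing_threshold,
                low_out=config.low_out,
                high_in=config.high_in,
                stacked_config=StackedConfig(
                    meta_mode=config.meta_mode,
                    validation_fraction=config.validation_fraction,
                ),
            )
            results = model.fit(seed=rep_seed + k)
            reports.append(results.evaluate(test))

    mean, sd = _aggregate(reports)
    manifest = {
        "config": _config_payload(config),
        "n_records": int(table.n_records),
        "n_folds": config.k_folds,
        "repetitions": config.repetitions,
        "metrics_mean": mean,
        "metrics_sd": sd,
    }
    result = ExperimentResult(
        fold_reports=reports, mean=mean, sd=sd, config=config, manifest=manifest
    )
    if config.output_dir:
        write_outputs(result, config.output_dir)
    return result


def _aggregate(reports: list[EvaluationReport]) -> tuple[dict, dict]:
    mean, sd = {}, {}
    for m in _METRICS:
        vals = [getattr(r, m) for r in reports if getattr(r, m) is not None]
        if vals:
            mean[m] = float(np.mean(vals))
            sd[m] = float(np.std(vals))
    return mean, sd


def _config_payload(config: RunConfig) -> dict:
    payload = asdict(config)
    if payload.get("synthetic") is not None:
        syn = payload["synthetic"]
        syn["informative_features"] = {
            str(k): v for k, v in syn["informative_features"].items()
        }
        syn["cycle_distribution"] = list(syn["cycle_distribution"])
    return payload


def write_outputs(result: ExperimentResult, directory: str | Path) -> None:
    """Persist fold reports + manifest as JSON artifacts."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    folds = [r.to_dict() for r in result.fold_reports]
    (directory / "fold_reports.json").write_text(json.dumps(folds, indent=2))
    summary = {"mean": result.mean, "sd": result.sd}
    (directory / "summary.json").write_text(json.dumps(summary, indent=2))
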