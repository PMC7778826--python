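"""Synthetic clinical cohorts for intrauterine-insemination outcome modelling.

Real IUI registries are private, so this module generates cohorts that carry
the same statistical skeleton: couples contributing 1-7 treatment cycles
(heavily skewed toward a single cycle), a mixed census of numeric, binary,
nominal and binominal features, a rare positive outcome (~14% clinical
pregnancy per cycle), and feature-wise missingness.  The outcome follows a
logistic model over a chosen set of informative features, with the intercept
calibrated numerically so the marginal positive rate matches the requested
base rate; a small couple-level random intercept ties the repeated cycles of
one couple together.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .table import FeatureTable

#: empirical cycle-count distribution of the emulated registry:
#: ~72% of couples do one cycle, 22% two, 5% three, <1% four to seven.
DEFAULT_CYCLE_DISTRIBUTION = (0.72, 0.22, 0.05, 0.005, 0.003, 0.001, 0.001)


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror the emulated registry: 86 numeric, 152 binary, 51 nominal
    and 7 binominal features; a 14.4% marginal positive rate; couples treated
    for 1-7 cycles with the skew above.
    """

    n_couples: int = 500
    cycle_distribution: tuple[float, ...] = DEFAULT_CYCLE_DISTRIBUTION
    n_numeric: int = 86
    n_binary: int = 152
    n_nominal: int = 51
    n_binominal: int = 7
    nominal_levels: int = 4
    #: map feature index (column position) -> log-odds effect size
    informative_features: dict[int, float] = field(default_factory=dict)
    base_rate: float = 0.144
    #: per-feature missing probability, keyed by column name
    missing_rates: dict[str, float] = field(default_factory=dict)
    #: variance of the couple-level random intercept (0 = independent cycles)
    couple_intercept_sd: float = 0.1
    #: Bernoulli skew of the binary features
    binary_p: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        dist = np.asarray(self.cycle_distribution, dtype=float)
        if abs(dist.sum() - 1.0) > 1e-12:
            raise ValueError(f"cycle_distribution sums to {dist.sum()!r}, expected 1")
        if (dist < 0).any():
            raise ValueError("cycle_distribution entries must be non-negative")
        for n in (self.n_numeric, self.n_binary, self.n_nominal, self.n_binominal):
            if n < 0:
                raise ValueError("feature counts must be non-negative")
        if self.n_couples <= 0:
            raise ValueError("n_couples must be positive")
        if not (0.0 < self.base_rate < 1.0):
            raise ValueError(f"base_rate must lie in (0, 1), got {self.base_rate}")
        if self.nominal_levels < 3:
            raise ValueError("nominal features need at least 3 levels")
        for name, rate in self.missing_rates.items():
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"missing rate for {name!r} must lie in [0, 1)")
        n_total = self.n_numeric + self.n_binary + self.n_nominal + self.n_binominal
        bad = [j for j in self.informative_features if not (0 <= j < n_total)]
        if bad:
            raise ValueError(f"informative feature indices out of range: {bad}")

    @property
    def n_features(self) -> int:
        return self.n_numeric + self.n_binary + self.n_nominal + self.n_binominal

    def feature_names(self) -> list[str]:
        return (
            [f"num_{i}" for i in range(self.n_numeric)]
            + [f"bin_{i}" for i in range(self.n_binary)]
            + [f"nom_{i}" for i in range(self.n_nominal)]
            + [f"bnm_{i}" for i in range(self.n_binominal)]
        )

    def feature_kinds(self) -> dict[str, str]:
        kinds: dict[str, str] = {}
        kinds.update({f"num_{i}": "numeric" for i in range(self.n_numeric)})
        kinds.update({f"bin_{i}": "binary" for i in range(self.n_binary)})
        kinds.update({f"nom_{i}": "nominal" for i in range(self.n_nominal)})
        kinds.update({f"bnm_{i}": "binominal" for i in range(self.n_binominal)})
        return kinds


@dataclass
class GroundTruth:
    """What the generator knows and the analyst is asked to recover."""

    informative_features: dict[str, float]  # column name -> log-odds effect
    intercept: float
    base_rate: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        return cls(**raw)


def generate_cohort(config: CohortConfig) -> tuple[FeatureTable, GroundTruth]:
    """Draw a synthetic cohort; identical configs and seeds reproduce it exactly.

    One record per treatment cycle.  The outcome is Bernoulli with
    logit(p_i) = alpha + u_couple(i) + sum_j beta_j x_ij over the informative
    features; alpha is calibrated by root finding so the population-average
    positive probability equals ``config.base_rate``.
    """
    rng = np.random.default_rng(config.seed)
    names = config.feature_names()
    kinds = config.feature_kinds()

    cycles = 1 + rng.choice(
        len(config.cycle_distribution),
        size=config.n_couples,
        p=np.asarray(config.cycle_distribution, dtype=float),
    )
    n_records = int(cycles.sum())
    if n_records == 0:
        raise ValueError("zero records requested")
    couple_id = np.repeat(np.arange(config.n_couples), cycles)

    cols: dict[str, np.ndarray] = {}
    for i in range(config.n_numeric):
        cols[f"num_{i}"] = rng.standard_normal(n_records)
    for i in range(config.n_binary):
        cols[f"bin_{i}"] = (rng.random(n_records) < config.binary_p).astype(float)
    # nominal levels drawn with a mildly skewed categorical distribution
    nom_p = np.arange(config.nominal_levels, 0, -1, dtype=float)
    nom_p /= nom_p.sum()
    for i in range(config.n_nominal):
        draws = rng.choice(config.nominal_levels, size=n_records, p=nom_p)
        cols[f"nom_{i}"] = np.array([f"L{d}" for d in draws], dtype=object)
    # "binominal": two-level nominal, distinct from the 0/1 binary block
    for i in range(config.n_binominal):
        draws = rng.choice(2, size=n_records, p=[0.6, 0.4])
        cols[f"bnm_{i}"] = np.array([f"A{d}" for d in draws], dtype=object)
    data = pd.DataFrame({name: cols[name] for name in names})

    # linear predictor over informative features (numeric codes for categoricals)
    eta = np.zeros(n_records)
    informative_named: dict[str, float] = {}
    for j, beta in config.informative_features.items():
        name = names[j]
        informative_named[name] = float(beta)
        col = data[name]
        if kinds[name] == "numeric":
            x = col.to_numpy(dtype=float)
        elif kinds[name] == "binary":
            x = col.to_numpy(dtype=float)
        else:  # nominal / binominal: use the level index as the score
            x = col.str.slice(1).astype(float).to_numpy()
        eta += beta * x

    u = rng.normal(0.0, config.couple_intercept_sd, size=config.n_couples)[couple_id]
    eta += u

    alpha = _calibrate_intercept(eta, config.base_rate)
    p = expit(alpha + eta)
    outcome = (rng.random(n_records) < p).astype(int)

    table = FeatureTable(
        data=data,
        outcome=pd.Series(outcome, name="outcome"),
        feature_types=kinds,
        group_ids=pd.Series(couple_id, name="couple_id"),
    )
    truth = GroundTruth(
        informative_features=informative_named,
        intercept=float(alpha),
        base_rate=config.base_rate,
        seed=config.seed,
    )
    return table, truth


def _calibrate_intercept(eta: np.ndarray, base_rate: float) -> float:
    """Solve mean(expit(alpha + eta)) = base_rate for alpha."""

    def gap(alpha: float) -> float:
        return float(np.mean(expit(alpha + eta)) - base_rate)

    lo, hi = -40.0, 40.0
    return float(brentq(gap, lo, hi, xtol=1e-12))


def inject_missingness(table: FeatureTable, config: CohortConfig) -> FeatureTable:
    """Mask feature values completely at random at per-feature rates.

    The outcome is never masked; asking to mask it is an error.  Uses the
    config seed (offset so it does not replay the generation stream).
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    out = table.copy()
    for name, rate in config.missing_rates.items():
        if name == table.outcome.name:
            raise ValueError("the outcome column must never be masked")
        if name not in out.data.columns:
            raise ValueError(f"cannot mask unknown column {name!r}")
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"missing rate for {name!r} must lie in [0, 1)")
        mask = rng.random(out.n_records) < rate
        col = out.data[name]
        if col.dtype == object:
            out.data.loc[mask, name] = None
        else:
            out.data[name] = col.astype(float)
            out.data.loc[mask, name] = np.nan
    return out
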