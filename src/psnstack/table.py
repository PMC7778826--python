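"""Mixed-type feature table with a binary outcome.

The central in-memory container: a pandas DataFrame of features, each tagged
with one of the four clinical column kinds (``numeric``, ``binary``,
``nominal``, ``binominal``), a binary outcome vector, and an optional couple
identifier linking repeated treatment cycles of the same couple.  Missingness
lives in the DataFrame itself as NaN/NA values; :attr:`FeatureTable.missing_mask`
is derived, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

FEATURE_KINDS = ("numeric", "binary", "nominal", "binominal")

#: kinds treated as categorical during imputation / encoding
CATEGORICAL_KINDS = ("binary", "nominal", "binominal")


@dataclass
class FeatureTable:
    """Records x mixed-type features plus a binary outcome.

    Parameters
    ----------
    data : DataFrame
        Feature columns only (no outcome).  Missing cells are NaN/NA.
    outcome : Series
        Binary labels aligned with ``data`` (0 = negative, 1 = positive).
        Never missing.
    feature_types : mapping of column name -> kind
        One of :data:`FEATURE_KINDS` per column.
    group_ids : Series, optional
        Couple identifier per record; repeated cycles of a couple share one id.
    """

    data: pd.DataFrame
    outcome: pd.Series
    feature_types: dict[str, str] = field(default_factory=dict)
    group_ids: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(self.data) != len(self.outcome):
            raise ValueError(
                f"data has {len(self.data)} rows but outcome has {len(self.outcome)}"
            )
        if self.outcome.isna().any():
            raise ValueError("outcome must not contain missing values")
        levels = set(pd.unique(self.outcome))
        if not levels <= {0, 1}:
            raise ValueError(f"outcome must be binary 0/1, found levels {sorted(levels)}")
        if not self.feature_types:
            self.feature_types = {c: _infer_kind(self.data[c]) for c in self.data.columns}
        unknown = set(self.feature_types) - set(self.data.columns)
        if unknown:
            raise ValueError(f"feature_types refers to unknown columns: {sorted(unknown)}")
        bad = {c: k for c, k in self.feature_types.items() if k not in FEATURE_KINDS}
        if bad:
            raise ValueError(f"unknown feature kinds: {bad}")

    # ------------------------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean per-cell mask, True where a value is missing."""
        return self.data.isna()

    def type_census(self) -> dict[str, int]:
        """Count of features per kind, e.g. ``{"numeric": 86, ...}``."""
        census = {k: 0 for k in FEATURE_KINDS}
        for kind in self.feature_types.values():
            census[kind] += 1
        return census

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            data=self.data.copy(),
            outcome=self.outcome.copy(),
            feature_types=dict(self.feature_types),
            group_ids=None if self.group_ids is None else self.group_ids.copy(),
        )

    def subset_rows(self, index) -> "FeatureTable":
        """Row subset by positional indices; row order follows ``index``."""
        idx = np.asarray(index)
        return FeatureTable(
            data=self.data.iloc[idx].reset_index(drop=True),
            outcome=self.outcome.iloc[idx].reset_index(drop=True),
            feature_types=dict(self.feature_types),
            group_ids=None
            if self.group_ids is None
            else self.group_ids.iloc[idx].reset_index(drop=True),
        )

    def matrix(self) -> np.ndarray:
        """Dense float matrix of the feature columns (requires numeric data)."""
        return self.data.to_numpy(dtype=float)

    # ------------------------------------------------------------------
    # CSV round trip
    def to_csv(
        self,
        path: str | Path,
        outcome_column: str = "outcome",
        group_column: str = "couple_id",
        missing_token: str = "",
    ) -> None:
        """Write the table to CSV with a header row.

        Missing cells are written as ``missing_token`` (default: empty field).
        """
        out = self.data.copy()
        out[outcome_column] = self.outcome.to_numpy()
        if self.group_ids is not None:
            out[group_column] = self.group_ids.to_numpy()
        out.to_csv(path, index=False, na_rep=missing_token)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        outcome_column: str = "outcome",
        group_column: str = "couple_id",
        missing_token: str = "",
        feature_types: Mapping[str, str] | None = None,
    ) -> "FeatureTable":
        """Read a CSV written by :meth:`to_csv` (or any compatible file).

        Columns absent from ``feature_types`` fall back to type inference:
        numeric if every observed value parses as a number, else nominal.
        """
        na_values = [missing_token] if missing_token else None
        df = pd.read_csv(path, na_values=na_values, keep_default_na=True)
        if outcome_column not in df.columns:
            raise ValueError(f"outcome column {outcome_column!r} not found in {path}")
        outcome = df.pop(outcome_column).astype(int)
        group = df.pop(group_column) if group_column in df.columns else None
        types = dict(feature_types) if feature_types else {}
        for col in df.columns:
            if col not in types:
                types[col] = _infer_kind(df[col])
        return cls(data=df, outcome=outcome, feature_types=types, group_ids=group)


def _infer_kind(col: pd.Series) -> str:
    """Numeric if parseable as numbers; two observed levels -> binary; else nominal."""
    observed = col.dropna()
    if observed.empty:
        return "numeric"
    as_num = pd.to_numeric(observed, errors="coerce")
    if not as_num.isna().any():
        levels = set(as_num.unique())
        if levels <= {0, 1}:
            return "binary"
        return "numeric"
    return "binary" if observed.nunique() == 2 else "nominal"
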