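"""The 17 network-contrast features engineered per record.

The working hypothesis: a record sits closer to training records of its own
class, so its centrality inside the own-class network (CN2 for positives)
should dominate its centrality in the other-class network.  The 17 features
contrast the query node's statistics between CN2 and CN3:

* F1-F6   — (CN2 - CN3) / CN1 for degree, weighted degree, closeness,
            eigenvector centrality, betweenness, clustering coefficient;
* F7      — ratio of minimum shortest-path lengths CN2 / CN3;
* F8      — ratio of 2-hop neighbour counts CN2 / CN3;
* F9-F12  — plain CN2 / CN3 ratios of degree, closeness, eigenvector,
            betweenness;
* F13-F17 — (normalized CN2 - normalized CN3) / max(normalized CN2,
            normalized CN3) for degree, closeness, eigenvector, betweenness,
            clustering coefficient (normalization = divide by the network max).

Every division goes through :func:`safe_ratio` so degenerate geometry
(isolated query nodes, empty networks) still yields finite values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import (
    DEFAULT_COMMUNITY_SIZE_LIMIT,
    DEFAULT_TAU_FACTOR,
    NetworkTriple,
    NodeMetrics,
    build_triple,
    compute_node_metrics,
)
from .table import FeatureTable

FEATURE_NAMES = tuple(f"F{i}" for i in range(1, 18))

DEFAULT_RATIO_CAP = 10.0


@dataclass
class EngineeredFeatures:
    """The 17-vector F1..F17 plus the node statistics it came from."""

    values: dict[str, float]
    provenance: tuple[NodeMetrics, NodeMetrics, NodeMetrics] | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.values[name] for name in FEATURE_NAMES])


def safe_ratio(numerator: float, denominator: float, cap: float = DEFAULT_RATIO_CAP) -> float:
    """num / den with magnitude capped; 0/0 -> 0; x/0 -> +-cap."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    if denominator != 0.0:
        r = numerator / denominator
        return math.copysign(min(abs(r), cap), r)
    if numerator == 0.0:
        return 0.0
    return math.copysign(cap, numerator)


def _sp_ratio(num: float, den: float, cap: float) -> float:
    """Ratio for shortest-path lengths, resolving the unreachable sentinels."""
    num_inf = math.isinf(num)
    den_inf = math.isinf(den)
    if num_inf and den_inf:
        return 1.0
    if den_inf:  # finite / infinity
        return 0.0
    if num_inf:  # infinity / finite
        return cap
    return safe_ratio(num, den, cap)


def engineer_features(
    triple: NetworkTriple, cap: float = DEFAULT_RATIO_CAP
) -> EngineeredFeatures:
    """Evaluate F1..F17 for the triple's query node."""
    q = triple.query_node
    m1 = compute_node_metrics(triple.cn1, q)
    m2 = compute_node_metrics(triple.cn2, q)
    m3 = compute_node_metrics(triple.cn3, q)

    v: dict[str, float] = {}
    # F1-F6: class contrast normalized by the full-cohort network
    contrast_metrics = (
        "degree",
        "weighted_degree",
        "closeness",
        "eigenvector",
        "betweenness",
        "clustering_coefficient",
    )
    for i, name in enumerate(contrast_metrics, start=1):
        v[f"F{i}"] = safe_ratio(
            getattr(m2, name) - getattr(m3, name), getattr(m1, name), cap
        )

    v["F7"] = _sp_ratio(m2.min_shortest_path, m3.min_shortest_path, cap)
    v["F8"] = safe_ratio(m2.two_hop_count, m3.two_hop_count, cap)

    # F9-F12: direct own-class / other-class ratios
    ratio_metrics = ("degree", "closeness", "eigenvector", "betweenness")
    for i, name in enumerate(ratio_metrics, start=9):
        v[f"F{i}"] = safe_ratio(getattr(m2, name), getattr(m3, name), cap)

    # F13-F17: contrasts of max-normalized metrics over the pairwise max
    norm_metrics = (
        "degree",
        "closeness",
        "eigenvector",
        "betweenness",
        "clustering_coefficient",
    )
    for i, name in enumerate(norm_metrics, start=13):
        a = m2.normalized[name]
        b = m3.normalized[name]
        v[f"F{i}"] = safe_ratio(a - b, max(a, b), cap)

    assert all(math.isfinite(x) for x in v.values())
    return EngineeredFeatures(values=v, provenance=(m1, m2, m3))


def engineer_table(
    table: FeatureTable,
    training: FeatureTable,
    tau_factor: float = DEFAULT_TAU_FACTOR,
    cap: float = DEFAULT_RATIO_CAP,
    is_training: bool = False,
    size_limit: int = DEFAULT_COMMUNITY_SIZE_LIMIT,
    seed: int = 0,
) -> pd.DataFrame:
    """17-column engineered matrix, one row per record of ``table``.

    ``is_training=True`` means ``table`` *is* the training table (row by row):
    each query's own labelled copy is excluded from its networks.  Both tables
    must already be preprocessed by the same fitted pipeline.
    """
    X = table.matrix()
    rows = []
    for i in range(len(X)):
        triple = build_triple(
            X[i],
            training,
            tau_factor=tau_factor,
            query_index=i if is_training else None,
            size_limit=size_limit,
            seed=seed,
        )
        rows.append(engineer_features(triple, cap=cap).values)
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES))
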