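"""SMOTE oversampling of the minority (preterm) class.

Preterm recordings are rare (~51 of 326 in the reference cohorts), and
classifiers trained on the raw imbalance are biased toward the majority
class.  SMOTE creates synthetic minority rows by convex interpolation
between a minority sample and one of its k nearest minority neighbours:
x_new = x + u * (x_nn - x), u ~ U(0, 1).

Neighbour distances are Euclidean on z-scored features (the features span
orders of magnitude: Hz vs mV^3), while interpolation happens in the
original feature space, so synthetic values always lie between their two
parents feature-wise.

By default the whole table is balanced before partitioning, which
faithfully reproduces the reference protocol but lets information about
synthetic-row parents leak across train/validation/test splits; the caveat
is logged.  Training-fold-only application is available to callers by
balancing each fold's sub-table instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .dataset import META_COLUMNS

__all__ = ["SmoteConfig", "smote_balance"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmoteConfig:
    k: int = 5
    seed: int = 0
    scale_before_distance: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"SMOTE k must be >= 1, got {self.k}")


def smote_balance(table: pd.DataFrame, cfg: SmoteConfig = SmoteConfig()) -> pd.DataFrame:
    """Oversample the minority class to parity with the majority.

    Original rows are preserved verbatim (``is_synthetic`` False); synthetic
    rows get the minority label, generated subject ids and ``is_synthetic``
    True.  Deterministic under a fixed ``cfg.seed``.
    """
    counts = table["label"].value_counts()
    if len(counts) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(counts.index)}")
    minority = counts.idxmin()
    n_needed = int(counts.max() - counts.min())
    feature_cols = [c for c in table.columns
                    if c not in META_COLUMNS and c != "is_synthetic"]

    out = table.copy()
    out["is_synthetic"] = False
    if n_needed == 0:
        logger.info("classes already balanced; SMOTE is a no-op")
        return out.reset_index(drop=True)

    min_rows = table.loc[table["label"] == minority, feature_cols].to_numpy(
        dtype=np.float64
    )
    if len(min_rows) <= cfg.k:
        raise ValueError(
            f"minority class has {len(min_rows)} rows but SMOTE k={cfg.k}; "
            f"use k < minority count"
        )

    if cfg.scale_before_distance:
        mu = table[feature_cols].to_numpy(dtype=np.float64).mean(axis=0)
        sd = table[feature_cols].to_numpy(dtype=np.float64).std(axis=0)
        sd[sd == 0] = 1.0
        scaled = (min_rows - mu) / sd
    else:
        scaled = min_rows
    nn = NearestNeighbors(n_neighbors=cfg.k + 1).fit(scaled)
    # drop column 0: each row's nearest neighbour is itself
    neighbor_idx = nn.kneighbors(scaled, return_distance=False)[:, 1:]

    rng = np.random.default_rng(cfg.seed)
    parents = rng.integers(0, len(min_rows), size=n_needed)
    picks = rng.integers(0, cfg.k, size=n_needed)
    us = rng.uniform(0.0, 1.0, size=n_needed)
    synth = np.empty((n_needed, len(feature_cols)))
    for i in range(n_needed):
        x = min_rows[parents[i]]
        x_nn = min_rows[neighbor_idx[parents[i], picks[i]]]
        synth[i] = x + us[i] * (x_nn - x)

    synth_df = pd.DataFrame(synth, columns=feature_cols)
    synth_df["label"] = minority
    synth_df["subject_id"] = [f"smote{i:04d}" for i in range(n_needed)]
    synth_df["is_synthetic"] = True
    logger.info(
        "SMOTE: added %d synthetic %s rows (balanced %d/%d); applied before "
        "partitioning, so synthetic-parent information crosses splits",
        n_needed, minority, counts.max(), counts.max(),
    )
    balanced = pd.concat([out, synth_df[out.columns]], ignore_index=True)
    return balanced
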