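"""Class balancing by self-adaptive synthetic over-sampling.

EHG cohorts are heavily term-dominated (~87% term in TPEHG), which biases
classifiers toward the majority class.  This module equalises class counts
by generating synthetic minority feature rows as convex combinations of
real minority neighbours, in the self-adaptive spirit of SASYNO: no
user-set neighbourhood size.  Instead,

* each minority sample's generative weight grows with the rank of its mean
  distance to the rest of the minority cloud, so sparse regions receive
  proportionally more synthetic mass;
* the interpolation partner is drawn from the sample's ceil(sqrt(m-1))
  nearest minority neighbours (m = minority count), an adaptive
  neighbourhood that scales with the cohort;
* the interpolation weight is Uniform(0, 1).

A plain SMOTE strategy (uniform parent choice, k = 5 neighbours) is kept
behind the ``strategy`` switch for comparison.  Synthetic rows are convex
combinations of exactly two real parents, so every synthetic value lies
inside its parents' per-feature range by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .io_ehg import feature_columns, validate_feature_table

__all__ = ["BalancedTable", "balance_classes"]


@dataclass
class BalancedTable:
    """A feature table with equal class counts plus generation metadata."""

    frame: pd.DataFrame
    seed: int
    strategy: str
    #: per synthetic record_id, the record_ids of its two real parents
    parents: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def n_synthetic(self) -> int:
        return int((self.frame["provenance"] == "synthetic").sum())


def _pick_parents(X: np.ndarray, n_new: int, strategy: str,
                  rng: np.random.Generator) -> list[tuple[int, int]]:
    m = X.shape[0]
    dist = squareform(pdist(X)) if m > 1 else np.zeros((1, 1))
    if strategy == "sasyno":
        mean_dist = dist.sum(axis=1) / max(m - 1, 1)
        order = np.argsort(np.argsort(mean_dist))  # 0 = densest
        weights = (order + 1).astype(float)
        weights /= weights.sum()
        k = max(1, math.ceil(math.sqrt(m - 1)))
    elif strategy == "smote":
        weights = np.full(m, 1.0 / m)
        k = min(5, m - 1)
    else:
        raise ValueError(f"unknown balancing strategy {strategy!r}")
    pairs = []
    for _ in range(n_new):
        i = int(rng.choice(m, p=weights))
        neighbours = np.argsort(dist[i])
        neighbours = neighbours[neighbours != i][:k]
        j = int(rng.choice(neighbours))
        pairs.append((i, j))
    return pairs


def balance_classes(table: pd.DataFrame, seed: int = 0,
                    strategy: str = "sasyno") -> BalancedTable:
    """Over-sample the minority class of a feature table to exact balance.

    Real rows pass through unchanged; appended synthetic rows carry
    ``provenance == "synthetic"`` and fresh record ids.  Deterministic for
    a fixed seed.
    """
    validate_feature_table(table)
    counts = table["label"].value_counts()
    if len(counts) < 2:
        raise ValueError("balance_classes: only one class present")
    minority = counts.idxmin()
    n_new = int(counts.max() - counts.min())
    if n_new == 0:
        return BalancedTable(table.copy(), seed, strategy)
    minority_rows = table[table["label"] == minority].reset_index(drop=True)
    if len(minority_rows) < 2:
        raise ValueError(
            "balance_classes: need >=2 minority rows to interpolate")

    feats = feature_columns(table)
    X = minority_rows[feats].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    pairs = _pick_parents(X, n_new, strategy, rng)

    new_rows = []
    parents: dict[str, tuple[str, str]] = {}
    group = minority_rows["group"].iloc[0]
    for s, (i, j) in enumerate(pairs):
        u = rng.uniform()
        values = X[i] + u * (X[j] - X[i])
        rid = f"syn_{strategy}_{minority}_{s:04d}"
        row = {"record_id": rid, "label": minority, "group": group,
               "provenance": "synthetic"}
        row.update(dict(zip(feats, values)))
        new_rows.append(row)
        parents[rid] = (str(minority_rows["record_id"].iloc[i]),
                        str(minority_rows["record_id"].iloc[j]))

    frame = pd.concat([table, pd.DataFrame(new_rows)], ignore_index=True)
    return BalancedTable(frame, seed, strategy, parents)
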