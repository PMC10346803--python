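"""Rank-based feature screening with the Mann-Whitney U test.

Each of the 72 features is tested between term and preterm rows; features
with p < 0.05 survive.  The statistic is U = min(U_a, U_b) with midranks
for ties.  Small pooled samples (n1 + n2 <= 16) get an exact permutation
p-value by enumerating every group assignment; larger samples use the
normal approximation with tie and continuity corrections.  No
multiple-testing correction is applied across features by default — the
screen is a univariate filter, not an inference — though ``holm=True``
turns one on for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .io_ehg import feature_columns, validate_feature_table

__all__ = ["SelectionResult", "mann_whitney_u", "select_features"]

#: pooled-size threshold below which the exact permutation p-value is used
EXACT_MAX_N = 16


@dataclass
class SelectionResult:
    """Per-feature U statistics and the selected subset."""

    stats: pd.DataFrame  # columns: feature, U, p, selected
    alpha: float
    group: str | None = None

    @property
    def selected(self) -> list[str]:
        return list(self.stats.loc[self.stats["selected"], "feature"])

    def reduce(self, table: pd.DataFrame) -> pd.DataFrame:
        """Project a feature table onto the selected features."""
        meta = [c for c in table.columns if c not in feature_columns(table)]
        return table[meta + self.selected]


def _u_from_ranks(ranks_a: np.ndarray, n1: int, n2: int) -> tuple[float, float]:
    r1 = float(np.sum(ranks_a))
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    return u1, u2


def _exact_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """P(min(U1, U2) <= u_obs) by full enumeration of group assignments."""
    n = pooled.size
    n2 = n - n1
    ranks = stats.rankdata(pooled)
    hits = 0
    for idx in combinations(range(n), n1):
        u1, u2 = _u_from_ranks(ranks[list(idx)], n1, n2)
        if min(u1, u2) <= u_obs + 1e-12:
            hits += 1
    return hits / comb(n, n1)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p) with U = min(Ua, Ub)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney_u: empty sample")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u1, u2 = _u_from_ranks(ranks[:n1], n1, n2)
    u = min(u1, u2)

    if n1 + n2 <= EXACT_MAX_N:
        return u, _exact_p(pooled, n1, u)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all values identical
        return u, 1.0
    z = (u - mu + 0.5) / np.sqrt(var)  # continuity correction toward mean
    p = min(1.0, 2.0 * stats.norm.cdf(z))
    return u, float(p)


def select_features(table: pd.DataFrame, alpha: float = 0.05,
                    holm: bool = False,
                    group: str | None = None) -> SelectionResult:
    """Screen every feature of a (balanced) table at level ``alpha``."""
    validate_feature_table(table)
    labels = table["label"]
    if labels.nunique() < 2:
        raise ValueError("select_features: need both classes present")
    term = table[labels == "term"]
    preterm = table[labels == "preterm"]
    rows = []
    for feat in feature_columns(table):
        u, p = mann_whitney_u(term[feat].to_numpy(),
                              preterm[feat].to_numpy())
        rows.append({"feature": feat, "U": u, "p": p})
    result = pd.DataFrame(rows)
    if holm:
        from statsmodels.stats.multitest import multipletests
        reject, p_adj, _, _ = multipletests(result["p"], alpha, "holm")
        result["p_holm"] = p_adj
        result["selected"] = reject
    else:
        result["selected"] = result["p"] < alpha
    return SelectionResult(result, alpha, group)
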