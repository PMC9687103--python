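"""Univariate group comparisons: Pearson chi-square and Kruskal-Wallis
with Dunn pairwise post-hoc tests.

Categorical demographics are compared across groups with the Pearson
chi-square test (no continuity correction); ordinal/continuous scale
scores with the Kruskal-Wallis rank test (midranks, tie correction),
followed by Dunn's pairwise z tests on the pooled mean ranks with Holm
(default) or Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ContingencyTable", "GroupSamples", "chi_square",
           "kruskal_wallis", "pairwise_posthoc"]


@dataclass
class ContingencyTable:
    """Groups x categories count matrix."""

    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("counts must be a matrix with >= 2 rows and columns")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("grand total must be positive")
        if not self.row_labels:
            self.row_labels = [f"row{i}" for i in range(self.counts.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"col{j}" for j in range(self.counts.shape[1])]


@dataclass
class GroupSamples:
    """Named groups of real-valued observations."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        self.groups = {k: np.asarray(v, dtype=float)
                       for k, v in self.groups.items()}
        if any(len(v) == 0 for v in self.groups.values()):
            raise ValueError("every group must be nonempty")


def chi_square(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square of independence: (statistic, df, p).

    Expected counts come from the row/column margins; df = (R-1)(C-1).
    A zero row or column margin is an error.
    """
    counts = table.counts
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("zero row or column margin")
    res = sps.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def kruskal_wallis(groups: GroupSamples) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H: (H, df, p) with df = k - 1.

    All-identical observations give H = 0, p = 1 (the tie-corrected
    denominator would otherwise vanish).
    """
    arrays = list(groups.groups.values())
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, len(arrays) - 1, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), len(arrays) - 1, float(p)


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def pairwise_posthoc(groups: GroupSamples, method: str = "dunn-holm",
                     alpha: float = 0.05) -> pd.DataFrame:
    """Dunn's pairwise z tests following a Kruskal-Wallis test.

    z is computed from the pooled midranks with the standard tie
    correction; two-sided p values are adjusted by Holm (``dunn-holm``) or
    Bonferroni (``dunn-bonferroni``).  ``direction`` reports which group
    has the larger mean rank (``"none"`` for exact rank ties) and
    ``significant`` flags adjusted p < alpha.
    """
    if method not in ("dunn-holm", "dunn-bonferroni"):
        raise ValueError("unknown post-hoc method")
    names = list(groups.groups.keys())
    arrays = [groups.groups[n] for n in names]
    sizes = np.array([len(a) for a in arrays])
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array([ranks[bounds[i]:bounds[i + 1]].mean()
                           for i in range(len(arrays))])

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term

    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            diff = mean_ranks[i] - mean_ranks[j]
            z = 0.0 if se == 0 else diff / se
            p = 2.0 * sps.norm.sf(abs(z))
            if diff > 0:
                direction = f"{names[i]} > {names[j]}"
            elif diff < 0:
                direction = f"{names[j]} > {names[i]}"
            else:
                direction = "none"
            rows.append({"group_a": names[i], "group_b": names[j],
                         "z": float(z), "p_raw": float(p),
                         "direction": direction})
    out = pd.DataFrame(rows)
    praw = out["p_raw"].to_numpy()
    if method == "dunn-holm":
        out["p_adjusted"] = _holm(praw)
    else:
        out["p_adjusted"] = np.minimum(1.0, praw * len(praw))
    out["significant"] = out["p_adjusted"] < alpha
    return out
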