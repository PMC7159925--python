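"""Rank-based multigroup statistics: Kruskal–Wallis + Dunn, pairwise rank-sum
tests, the Nemenyi post-hoc with its studentized-range critical value, and the
classic unpaired t-test.

The Nemenyi construction for unequal group sizes compares, for groups i and j
with mean joint ranks R̄ᵢ, R̄ⱼ and sizes nᵢ, nⱼ,

    q_ij = |R̄ᵢ − R̄ⱼ| / sqrt( N(N+1)/12 · (1/nᵢ + 1/nⱼ) )

against q_c = q(α, k, ∞) / √2, the upper-α studentized-range quantile for k
groups at infinite degrees of freedom. At k = 2 this reduces to the two-sided
normal critical value z_{1−α/2}. Mid-ranks are used for ties throughout; the
Kruskal–Wallis H carries the standard tie correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupedSamples:
    """Scalar measurements with one group label per value."""

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if len(self.values) != len(self.labels):
            raise ValueError("values and labels must align")
        self.groups = [g for g in pd.unique(self.labels)]
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        for g in self.groups:
            if not (self.labels == g).any():
                raise ValueError(f"group {g!r} is empty")

    @classmethod
    def from_dict(cls, d: dict) -> "GroupedSamples":
        values = np.concatenate([np.asarray(v, dtype=float) for v in d.values()])
        labels = np.concatenate([np.full(len(v), k, dtype=object) for k, v in d.items()])
        return cls(values, labels)

    @property
    def k(self) -> int:
        return len(self.groups)

    def group_values(self) -> list[np.ndarray]:
        return [self.values[self.labels == g] for g in self.groups]


@dataclass
class NemenyiResult:
    """Pairwise q statistics against the studentized-range critical value."""

    q: np.ndarray           # (k, k), symmetric, zero diagonal
    q_c: float
    alpha: float
    k: int
    reject: np.ndarray      # boolean, q > q_c
    mean_ranks: np.ndarray
    groups: list


def _rank_infrastructure(g: GroupedSamples):
    """Joint mid-ranks, per-group mean ranks and sizes, and the tie term Σ(t³−t)."""
    ranks = sps.rankdata(g.values)
    n_i = np.array([(g.labels == grp).sum() for grp in g.groups])
    mean_ranks = np.array([ranks[g.labels == grp].mean() for grp in g.groups])
    _, counts = np.unique(g.values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    return ranks, mean_ranks, n_i, tie_term


def kruskal_dunn(g: GroupedSamples, alpha: float = 0.05) -> tuple[float, pd.DataFrame]:
    """Kruskal–Wallis omnibus p-value plus Dunn pairwise comparisons.

    Dunn z-statistics use mean joint ranks with the pooled-rank standard error
    (tie-corrected); pairwise p-values are Bonferroni-adjusted for the
    k(k−1)/2 comparisons.
    """
    if np.ptp(g.values) == 0:
        omnibus_p = 1.0  # H = 0 when every value is identical
    else:
        _, omnibus_p = sps.kruskal(*g.group_values())

    ranks, mean_ranks, n_i, tie_term = _rank_infrastructure(g)
    N = len(g.values)
    tie_corr = tie_term / (12.0 * (N - 1)) if N > 1 else 0.0
    m = g.k * (g.k - 1) // 2
    rows = []
    for (i, gi), (j, gj) in combinations(enumerate(g.groups), 2):
        se = np.sqrt((N * (N + 1) / 12.0 - tie_corr) * (1.0 / n_i[i] + 1.0 / n_i[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group_a": gi,
                "group_b": gj,
                "z": z,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, p_raw * m),
                "significant": min(1.0, p_raw * m) < alpha,
            }
        )
    return float(omnibus_p), pd.DataFrame(rows)


def pairwise_wilcoxon(g: GroupedSamples) -> pd.DataFrame:
    """Two-sided rank-sum (Mann–Whitney) test per group pair.

    The exact null distribution is used when the combined sample is ≤ 20
    observations without ties; otherwise the tie-corrected normal approximation.
    Degenerate pairs (fewer than 2 values in a group) get a missing p-value.
    """
    rows = []
    for (i, gi), (j, gj) in combinations(enumerate(g.groups), 2):
        a = g.values[g.labels == gi]
        b = g.values[g.labels == gj]
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"pair ({gi!r}, {gj!r}) degenerate; p missing", stacklevel=2)
            rows.append({"group_a": gi, "group_b": gj, "p": np.nan, "method": "none"})
            continue
        pooled = np.concatenate([a, b])
        exact = len(pooled) <= 20 and len(np.unique(pooled)) == len(pooled)
        method = "exact" if exact else "asymptotic"
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append({"group_a": gi, "group_b": gj, "p": float(p), "method": method})
    return pd.DataFrame(rows)


def nemenyi_critical_value(alpha: float, k: int) -> float:
    """q_c = studentized-range upper-α quantile (k groups, infinite df) / √2."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if k < 2:
        raise ValueError("k must be >= 2")
    return float(sps.studentized_range.ppf(1.0 - alpha, k, np.inf) / np.sqrt(2.0))


def nemenyi_test(g: GroupedSamples, alpha: float = 0.05) -> NemenyiResult:
    """Nemenyi post-hoc comparison for unequal sample sizes.

    The null of equal medians is rejected for pair (i, j) when q_ij > q_c.
    """
    _, mean_ranks, n_i, _ = _rank_infrastructure(g)
    N = len(g.values)
    k = g.k
    q = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(N * (N + 1) / 12.0 * (1.0 / n_i[i] + 1.0 / n_i[j]))
            q[i, j] = q[j, i] = abs(mean_ranks[i] - mean_ranks[j]) / se
    q_c = nemenyi_critical_value(alpha, k)
    reject = q > q_c
    np.fill_diagonal(reject, False)
    return NemenyiResult(q, q_c, alpha, k, reject, mean_ranks, list(g.groups))


def unpaired_t(a, b, welch: bool = False) -> tuple[float, float, float]:
    """Two-sample t-test: (t, df, two-sided p). Pooled variance unless ``welch``.

    With zero variance in both samples the p-value is undefined and reported
    as NaN with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        warnings.warn("zero variance in both samples; p undefined", stacklevel=2)
        return np.nan, float(len(a) + len(b) - 2), np.nan
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = res.df if hasattr(res, "df") else len(a) + len(b) - 2
    return float(res.statistic), float(df), float(res.pvalue)
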