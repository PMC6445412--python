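"""Nonparametric comparison machinery for region-wise map analysis.

Two tracks mirror the analysis the maps feed:

* per-meridian two-group comparisons (naked eye vs lens profiles) with the
  Mann-Whitney U test and Benjamini-Hochberg FDR control, which defines a
  per-meridian critical p-value;
* per-region omnibus comparisons across condition groups with the
  Kruskal-Wallis test followed by Dunn-type pairwise contrasts on mean
  ranks under familywise-error control — by default the Tukey-Kramer
  (studentized-range) criterion on mean ranks, with Holm as an
  alternative.  The effective corrected critical p-value is reported as
  an output of the procedure.

Pixels within a region are treated as independent observations (n in the
thousands per region); see the methods note for why that pseudo-
replication is reproduced rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "KWResult",
    "PairwiseTable",
    "kruskal_wallis",
    "mann_whitney_u",
    "benjamini_hochberg",
    "posthoc_pairwise",
    "region_condition_analysis",
    "RegionAnalysis",
]

_FACTORS = ("scene", "optic", "profile")


@dataclass(frozen=True)
class KWResult:
    """Kruskal-Wallis omnibus result plus the rank bookkeeping the
    post-hoc contrasts need."""

    H: float
    df: int
    p: float
    group_mean_ranks: np.ndarray
    n_per_group: np.ndarray
    tie_sum: float  # sum of (t^3 - t) over tie groups in the pooled sample

    @property
    def n_total(self) -> int:
        return int(self.n_per_group.sum())

    @property
    def k(self) -> int:
        return len(self.n_per_group)


@dataclass(frozen=True)
class PairwiseTable:
    """All unordered pairwise contrasts of a Kruskal-Wallis family.

    ``table`` columns: group_a, group_b, z (Dunn statistic on mean ranks),
    raw_p, adjusted_p, significant.  ``critical_p`` is the effective
    per-comparison critical value implied by the familywise criterion on
    the raw two-sided normal scale.
    """

    table: pd.DataFrame
    method: str
    alpha: float
    critical_p: float


def _validate_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    return groups


def _tie_sum(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: Sequence[np.ndarray]) -> KWResult:
    """Tie-corrected Kruskal-Wallis H with chi-square upper-tail p.

    Degenerate case: if every pooled value is identical the statistic is
    defined as 0 with p = 1.
    """
    groups = _validate_groups(groups)
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = np.array([g.size for g in groups])
    edges = np.cumsum(n)[:-1]
    mean_ranks = np.array([r.mean() for r in np.split(ranks, edges)])
    tie_sum = _tie_sum(pooled)
    df = len(groups) - 1
    if np.all(pooled == pooled[0]):
        return KWResult(0.0, df, 1.0, mean_ranks, n, tie_sum)
    H, p = stats.kruskal(*groups)
    return KWResult(float(H), df, float(p), mean_ranks, n, tie_sum)


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U of ``a`` (rank-sum form) with two-sided p.

    The p-value is exact (full enumeration) when the smaller sample has at
    most 8 values and the pooled sample is tie-free; otherwise the normal
    approximation with tie-corrected variance (no continuity correction)
    is used.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(pvals: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up FDR control.

    Returns per-hypothesis reject flags (in input order) and the critical
    p-value ``(i*/m) * q`` of the largest rejected rank (0 if none).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = (np.arange(1, m + 1) / m) * q
    passing = np.nonzero(p[order] <= thresholds)[0]
    if passing.size == 0:
        return np.zeros(m, dtype=bool), 0.0
    i_star = passing[-1]
    reject = np.zeros(m, dtype=bool)
    reject[order[: i_star + 1]] = True
    return reject, float(thresholds[i_star])


def _dunn_z(kw: KWResult, i: int, j: int) -> float:
    """Dunn statistic on mean ranks with pooled tie-corrected variance."""
    N = kw.n_total
    s2 = N * (N + 1) / 12.0 - kw.tie_sum / (12.0 * (N - 1))
    se = np.sqrt(s2 * (1.0 / kw.n_per_group[i] + 1.0 / kw.n_per_group[j]))
    if se == 0.0:
        return 0.0
    return float((kw.group_mean_ranks[i] - kw.group_mean_ranks[j]) / se)


def posthoc_pairwise(
    kw: KWResult,
    alpha: float = 0.05,
    method: str = "tukey-ranks",
    labels: Sequence[str] | None = None,
) -> PairwiseTable:
    """All pairwise Dunn contrasts with familywise-error control.

    method "tukey-ranks" (default): each |z| is referred to the
    studentized-range distribution via ``q = sqrt(2) |z|`` with k groups
    and infinite degrees of freedom — the Tukey-Kramer criterion applied
    to mean ranks.  method "holm": Holm step-down on the raw two-sided
    normal p-values.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    k = kw.k
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels must match the number of groups")
    pairs = list(combinations(range(k), 2))
    z = np.array([_dunn_z(kw, i, j) for i, j in pairs])
    raw_p = 2.0 * stats.norm.sf(np.abs(z))
    if method == "tukey-ranks":
        adj = stats.studentized_range.sf(np.sqrt(2.0) * np.abs(z), k, np.inf)
        adj = np.clip(adj, 0.0, 1.0)
        reject = adj < alpha
        q_crit = stats.studentized_range.ppf(1.0 - alpha, k, np.inf)
        critical_p = float(2.0 * stats.norm.sf(q_crit / np.sqrt(2.0)))
    elif method == "holm":
        reject, adj, _, _ = multipletests(raw_p, alpha=alpha, method="holm")
        # largest raw p still rejected, on the per-comparison scale
        critical_p = float(raw_p[reject].max()) if reject.any() else 0.0
    else:
        raise ValueError(f"unknown method {method!r}; use 'tukey-ranks' or 'holm'")
    table = pd.DataFrame(
        {
            "group_a": [labels[i] for i, _ in pairs],
            "group_b": [labels[j] for _, j in pairs],
            "z": z,
            "raw_p": raw_p,
            "adjusted_p": adj,
            "significant": reject,
        }
    )
    return PairwiseTable(table, method, alpha, critical_p)


@dataclass(frozen=True)
class RegionAnalysis:
    """Region-wise Kruskal-Wallis + post-hoc results over a factor.

    ``kw`` has one row per (region, held-conditions) family; ``pairwise``
    one row per contrast; ``nonsignificant`` the subset of contrasts whose
    null was not rejected — the structure summarised by the
    non-significance panels.
    """

    factor: str
    kw: pd.DataFrame
    pairwise: pd.DataFrame
    nonsignificant: pd.DataFrame


def region_condition_analysis(
    regions: pd.DataFrame,
    factor: str,
    alpha: float = 0.05,
    method: str = "tukey-ranks",
) -> RegionAnalysis:
    """Compare a factor's levels within every region and held condition.

    ``regions`` is the tidy table with columns scene, optic, profile,
    ring, quadrant, value.  For each ring x quadrant region and each
    combination of the two held factors' levels, the factor's groups are
    compared with Kruskal-Wallis followed by familywise-corrected
    pairwise contrasts; contrasts that are not significant are collected.
    """
    if factor not in _FACTORS:
        raise ValueError(f"factor must be one of {_FACTORS}")
    held = [f for f in _FACTORS if f != factor]
    required = {*_FACTORS, "ring", "quadrant", "value"}
    missing = required - set(regions.columns)
    if missing:
        raise ValueError(f"region table missing columns {sorted(missing)}")
    kw_rows, pw_frames = [], []
    group_cols = ["ring", "quadrant", *held]
    for keys, cell in regions.groupby(group_cols, sort=False, observed=True):
        levels = [str(lvl) for lvl, _ in cell.groupby(factor, sort=False, observed=True)]
        groups = [g["value"].to_numpy() for _, g in cell.groupby(factor, sort=False, observed=True)]
        if any(g.size == 0 for g in groups) or len(groups) < 2:
            raise ValueError(f"region/condition cell {keys} lacks data for some level")
        kw = kruskal_wallis(groups)
        pw = posthoc_pairwise(kw, alpha=alpha, method=method, labels=levels)
        meta = dict(zip(group_cols, keys))
        kw_rows.append({**meta, "H": kw.H, "df": kw.df, "p": kw.p,
                        "critical_p": pw.critical_p})
        pw_frames.append(pw.table.assign(**meta))
    kw_table = pd.DataFrame(kw_rows)
    pairwise = pd.concat(pw_frames, ignore_index=True)
    nonsig = pairwise[~pairwise["significant"]].reset_index(drop=True)
    return RegionAnalysis(factor, kw_table, pairwise, nonsig)
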