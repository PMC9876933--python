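"""Nonparametric statistics layer: Kruskal-Wallis + Dunn, Fisher's exact,
Wilcoxon rank sum.

These are the procedures used throughout the analysis: Kruskal-Wallis with
Dunn's multiple-comparisons follow-up for multi-condition sleep parameters,
Fisher's exact test for sleep-episode incidence, and the Wilcoxon rank-sum
test for per-cell transition-probability contrasts. Computation delegates to
scipy/statsmodels; the module fixes the exact-vs-asymptotic policy and the
Dunn family adjustment so results are reproducible across call sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05  # study-wide significance threshold

_ADJUST_METHODS = {"holm": "holm", "bonferroni": "bonferroni", "none": None}


@dataclass(frozen=True)
class KruskalDunnResult:
    """Omnibus Kruskal-Wallis H plus Dunn pairwise z-tests on mean ranks."""

    h_statistic: float
    p_omnibus: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adjusted, significant
    adjustment: str
    alpha: float = ALPHA


def kruskal_wallis_h(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must contain at least one value")
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]],
    alpha: float = ALPHA,
    adjustment: str = "holm",
) -> KruskalDunnResult:
    """Kruskal-Wallis omnibus test followed by Dunn's pairwise comparisons.

    Dunn's test compares mean ranks of each group pair with a z-statistic
    using the tie-corrected pooled-rank variance. The family adjustment
    defaults to Holm; ``"bonferroni"`` and ``"none"`` are available, and the
    mode used is recorded in the result.
    """
    if adjustment not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    labels = list(groups)
    values = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if any(v.size == 0 for v in values):
        raise ValueError("every group must contain at least one value")
    n_total = int(sum(v.size for v in values))
    if n_total < 3:
        raise ValueError("need at least three observations in total")

    h, p_omni = kruskal_wallis_h(values)

    pooled = np.concatenate(values)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    pos = 0
    for k, v in zip(labels, values):
        mean_ranks[k] = float(ranks[pos : pos + v.size].mean())
        sizes[k] = v.size
        pos += v.size
    # tie correction: sum(t^3 - t) over tied groups
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            se = math.sqrt(var_factor * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p_raw = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p_raw})
    table = pd.DataFrame(rows)
    method = _ADJUST_METHODS[adjustment]
    if method is None or table.empty:
        table["p_adjusted"] = table["p_raw"]
    else:
        table["p_adjusted"] = multipletests(table["p_raw"].to_numpy(), method=method)[1]
    table["significant"] = table["p_adjusted"] <= alpha
    return KruskalDunnResult(h, p_omni, table, adjustment, alpha)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 contingency table.

    Sums hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


_EXACT_ENUM_CAP = 200_000  # max group assignments to enumerate


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided p by enumerating all group assignments.

    Handles ties by counting equal cross-pairs at 1/2 in the U statistic;
    the permutation-null U distribution is symmetric about n1*n2/2, so the
    two-sided p is the tail at least as far from that centre as observed.
    """
    from itertools import combinations

    pooled = np.concatenate([a, b])
    n, n1 = pooled.size, a.size
    mean = a.size * b.size / 2.0

    def u_stat(x: np.ndarray, y: np.ndarray) -> float:
        diff = x[:, None] - y[None, :]
        return float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    u_obs = u_stat(a, b)
    total = tail = 0
    idx = np.arange(n)
    for comb in combinations(range(n), n1):
        sel = np.zeros(n, dtype=bool)
        sel[list(comb)] = True
        u = u_stat(pooled[sel], pooled[~sel])
        tail += abs(u - mean) >= abs(u_obs - mean) - 1e-12
        total += 1
    return tail / total


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null enumeration (ties handled by half-counting) when the smaller
    sample has fewer than 10 observations and the enumeration is tractable;
    otherwise a tie-corrected normal approximation with continuity
    correction. Degenerate inputs with zero rank variance (e.g. identical
    constant samples) return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        return 1.0
    small = min(a.size, b.size) < 10
    if small and math.comb(pooled.size, a.size) <= _EXACT_ENUM_CAP:
        return _exact_ranksum_p(a, b)
    p = float(
        sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")[1]
    )
    if math.isnan(p):
        return 1.0
    return min(p, 1.0)
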