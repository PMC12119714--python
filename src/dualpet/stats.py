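"""Nonparametric comparisons used by the cohort analysis.

Paired scan-1 vs scan-2 organ uptake uses the Wilcoxon matched-pairs
signed-rank test; three or more lesion groups are compared with the
Kruskal-Wallis test followed by Dunn's pairwise z tests with a
Bonferroni-family multiplicity adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_WILCOXON_MAX_N = 25


def paired_rank_test(x, y) -> tuple[float, float]:
    """Wilcoxon matched-pairs signed-rank test, two-sided.

    Zero differences are dropped (Wilcoxon's original treatment); the exact
    null distribution is used for n <= 25 without ties in |difference|, the
    normal approximation otherwise. All-zero differences return (0, 1) — no
    evidence of a shift.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1-D samples with n >= 1")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    abs_d = np.abs(d)
    ties = np.unique(abs_d).size < abs_d.size
    method = "exact" if (d.size <= EXACT_WILCOXON_MAX_N and not ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class GroupComparison:
    """Kruskal-Wallis omnibus result plus Dunn's pairwise comparisons."""

    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame
    """columns: group_i, group_j, z, p_adjusted (Bonferroni over all pairs)."""


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    pooled = np.concatenate(list(groups.values()))
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    start = 0
    for name, g in groups.items():
        mean_ranks[name] = float(ranks[start:start + g.size].mean())
        start += g.size
    # tie correction to the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))) \
        if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    names = list(groups)
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            gi, gj = names[a], names[b]
            se = np.sqrt(base_var * (1.0 / groups[gi].size + 1.0 / groups[gj].size))
            z = (mean_ranks[gi] - mean_ranks[gj]) / se if se > 0 else 0.0
            p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * n_pairs)
            rows.append({"group_i": gi, "group_j": gj, "z": float(z), "p_adjusted": float(p)})
    return pd.DataFrame(rows)


def group_comparison(groups: dict[str, np.ndarray] | list[np.ndarray]) -> GroupComparison:
    """Kruskal-Wallis H (tie-corrected) with Dunn's adjusted pairwise tests.

    Requires at least three groups; for two paired samples use
    :func:`paired_rank_test` instead.
    """
    if not isinstance(groups, dict):
        groups = {f"group{i}": g for i, g in enumerate(groups)}
    groups = {k: np.asarray(v, float).ravel() for k, v in groups.items()}
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use paired_rank_test for two samples")
    if any(g.size < 1 for g in groups.values()):
        raise ValueError("each group needs n >= 1")
    if np.ptp(np.concatenate(list(groups.values()))) == 0:
        # all values identical: no rank variation, H defined as 0
        return GroupComparison(0.0, 1.0, _dunn_pairwise(groups))
    h, p = sps.kruskal(*groups.values())
    return GroupComparison(float(h), float(p), _dunn_pairwise(groups))
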