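"""Nonparametric group statistics on hyperedge weights.

Per hyperedge: Shapiro-Wilk normality screen (informational — the pipeline
is always nonparametric), Kruskal-Wallis omnibus test across the clinical
groups, Benjamini-Hochberg FDR correction across hyperedges, absolute
Cliff's delta effect sizes averaged over group pairs, and two-sided
Mann-Whitney post-hoc tests (FDR-corrected within each group-pair family)
restricted to the hyperedges the omnibus stage flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .panels import ContractError
from .weighting import WeightTable

__all__ = [
    "normality_screen",
    "kruskal_wallis",
    "cliffs_delta",
    "global_effect_size",
    "fdr_bh",
    "mann_whitney",
    "omnibus_test",
    "posthoc_pairwise",
    "run_group_stats",
    "GroupStatsResult",
]


def normality_screen(table: WeightTable) -> tuple[pd.DataFrame, bool]:
    """Shapiro-Wilk p-value per (hyperedge, group) plus an overall flag.

    The flag is True when any cell rejects normality at 0.05. It is
    informational only: the battery proceeds nonparametrically regardless.
    """
    groups = sorted(table.group_labels.unique())
    rows = {}
    for g in groups:
        sub = table.group(g)
        if len(sub) < 3:
            raise ContractError(f"group {g!r} has fewer than 3 subjects")
        rows[g] = [float(sps.shapiro(sub[h]).pvalue) for h in table.hyperedge_ids]
    pvals = pd.DataFrame(rows, index=table.hyperedge_ids)
    return pvals, bool((pvals < 0.05).any().any())


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All observations identical is a well-defined degenerate case: there is
    no evidence of any group difference, so H = 0 and p = 1.
    """
    if len(groups) < 2:
        raise ContractError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ContractError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def cliffs_delta(x: np.ndarray, y: np.ndarray) -> float:
    """Cliff's delta: P(x > y) - P(x < y) over all cross-group pairs.

    Dominance effect size in [-1, 1]; antisymmetric in its arguments.
    Computed via the rank of each x within the pooled sample, which is
    O((n+m) log(n+m)) rather than the quadratic pair count.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ContractError("cliffs_delta needs non-empty samples")
    # #{x_i > y_j} - #{x_i < y_j} via searchsorted on sorted y
    ys = np.sort(y)
    greater = np.searchsorted(ys, x, side="left").sum()
    less = (y.size - np.searchsorted(ys, x, side="right")).sum()
    return float((greater - less) / (x.size * y.size))


def global_effect_size(groups: list[np.ndarray]) -> float:
    """Mean absolute Cliff's delta over all unordered group pairs."""
    if len(groups) < 2:
        raise ContractError("need at least 2 groups")
    deltas = [abs(cliffs_delta(a, b)) for a, b in combinations(groups, 2)]
    return float(np.mean(deltas))


def fdr_bh(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ContractError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both samples are tie-free and no larger than
    20; otherwise the tie-corrected normal approximation (the exact null
    distribution does not account for ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ContractError("mann_whitney needs non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    method = "exact" if (not has_ties and max(x.size, y.size) <= 20) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupStatsResult:
    """Omnibus + post-hoc battery output for one weight table."""

    omnibus: pd.DataFrame  # per hyperedge: H, p_raw, p_fdr, significant, effect_size
    posthoc: pd.DataFrame  # per (hyperedge, pair): U, p_raw, p_fdr, cliffs_delta
    alpha: float
    groups: list[str]

    @property
    def significant_ids(self) -> list[str]:
        return list(self.omnibus.index[self.omnibus["significant"]])


def omnibus_test(table: WeightTable, alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis per hyperedge with BH-FDR across all hyperedges.

    Returns one row per hyperedge: H statistic, raw and adjusted p-value,
    the rejection flag at ``alpha``, and the global effect size (mean
    absolute Cliff's delta over group pairs).
    """
    groups = sorted(table.group_labels.unique())
    if len(groups) < 2:
        raise ContractError("need at least 2 groups")
    per_group = {g: table.group(g) for g in groups}
    stats_rows = []
    for h in table.hyperedge_ids:
        samples = [per_group[g][h].to_numpy() for g in groups]
        H, p = kruskal_wallis(samples)
        stats_rows.append((h, H, p, global_effect_size(samples)))
    out = pd.DataFrame(stats_rows, columns=["hyperedge", "H", "p_raw", "effect_size"]).set_index(
        "hyperedge"
    )
    out["p_fdr"], out["significant"] = fdr_bh(out["p_raw"].to_numpy(), alpha)
    return out[["H", "p_raw", "p_fdr", "significant", "effect_size"]]


def posthoc_pairwise(
    table: WeightTable, significant_ids: list[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Mann-Whitney post-hoc tests on the omnibus-significant hyperedges.

    FDR is applied *within each group-pair family* across the significant
    hyperedges, mirroring the per-pair reporting of the omnibus stage.
    An empty significant set returns an empty frame.
    """
    cols = ["hyperedge", "pair", "U", "p_raw", "p_fdr", "significant", "cliffs_delta"]
    if not significant_ids:
        return pd.DataFrame(columns=cols).set_index(["hyperedge", "pair"])
    groups = sorted(table.group_labels.unique())
    per_group = {g: table.group(g) for g in groups}
    records = []
    for ga, gb in combinations(groups, 2):
        pair = f"{ga}_vs_{gb}"
        pvals, rows = [], []
        for h in significant_ids:
            x = per_group[ga][h].to_numpy()
            y = per_group[gb][h].to_numpy()
            U, p = mann_whitney(x, y)
            rows.append((h, pair, U, p, cliffs_delta(x, y)))
            pvals.append(p)
        p_adj, reject = fdr_bh(np.asarray(pvals), alpha)
        for (h, pr, U, p, d), pa, rj in zip(rows, p_adj, reject):
            records.append((h, pr, U, p, float(pa), bool(rj), d))
    return pd.DataFrame(records, columns=cols).set_index(["hyperedge", "pair"])


def run_group_stats(table: WeightTable, alpha: float = 0.05) -> GroupStatsResult:
    """Full battery: omnibus with FDR, then pairwise post-hoc on survivors."""
    omnibus = omnibus_test(table, alpha)
    sig = list(omnibus.index[omnibus["significant"]])
    posthoc = posthoc_pairwise(table, sig, alpha)
    return GroupStatsResult(
        omnibus=omnibus,
        posthoc=posthoc,
        alpha=alpha,
        groups=sorted(table.group_labels.unique()),
    )
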