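"""Signature-ASV selection: averaged Gini importance and scree breakpoints.

For each source, candidate ASVs are ranked by mean decrease Gini (MDG)
averaged over many random-forest replicates; the top of the ranking is
treated as a scree curve, segmented into piecewise-constant plateaus by
least-squares dynamic programming, and the ASVs ranked before the first
breakpoint become the source's signature set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

# forest parallelism; the CLI's --threads flag overrides
N_JOBS = 1

__all__ = [
    "GiniRanking",
    "rank_asvs_by_gini",
    "estimate_breakpoints",
    "select_signature_asvs",
    "exhaustive_breakpoints",
]


@dataclass
class GiniRanking:
    """Per-ASV mean decrease Gini averaged over forest replicates."""

    mdg: pd.Series  # index = ASV ids, values >= 0
    n_replicates: int
    n_trees_per_replicate: int
    seed: int

    def top(self, n: int) -> pd.Series:
        """The n largest MDG values, descending (ties broken by ASV id)."""
        df = self.mdg.rename("mdg").reset_index()
        df = df.sort_values(["mdg", "index"], ascending=[False, True])
        s = df.set_index("index")["mdg"].head(n)
        s.index.name = None
        return s


def replicate_seeds(master_seed: int, n: int, stream: int = 0) -> np.ndarray:
    """Derive n deterministic sub-seeds from a master seed.

    ``stream`` separates independent uses (ranking vs training vs
    robustness repeats) so they never share a seed sequence.
    """
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(stream,))
    return ss.generate_state(n) % (2**31 - 1)


def _mean_decrease_gini(forest: RandomForestClassifier) -> np.ndarray:
    # Unnormalised impurity decrease per tree, averaged across trees --
    # the R randomForest MDG semantics rather than sklearn's sum-to-one
    # feature_importances_. Rank order is what selection consumes.
    total = np.zeros(forest.n_features_in_)
    for tree in forest.estimators_:
        total += tree.tree_.compute_feature_importances(normalize=False)
    return total / len(forest.estimators_)


def rank_asvs_by_gini(
    abundances: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_replicates: int = 100,
    n_trees: int = 10_000,
    seed: int = 0,
) -> GiniRanking:
    """Average MDG over ``n_replicates`` forests of ``n_trees`` each.

    ``abundances`` is samples x ASVs relative abundance; ``labels`` is
    the one-vs-rest binary vector. Forests use classification defaults:
    sqrt(p) predictors per split, n-of-n bootstrap, unlimited depth.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ranking requires both classes present")
    if abundances.shape[1] < 1:
        raise ValueError("no candidate ASVs")
    if min(np.bincount(y.astype(int))) < 2:
        raise ValueError("need >= 2 samples per class")

    X = abundances.to_numpy()
    acc = np.zeros(X.shape[1])
    for sub_seed in replicate_seeds(seed, n_replicates, stream=0):
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            bootstrap=True,
            random_state=int(sub_seed),
            n_jobs=N_JOBS,
        )
        forest.fit(X, y)
        acc += _mean_decrease_gini(forest)
    mdg = pd.Series(acc / n_replicates, index=abundances.columns)
    return GiniRanking(mdg, n_replicates, n_trees, seed)


# --- least-squares segmentation ---------------------------------------


def _segment_costs(series: np.ndarray) -> np.ndarray:
    """cost[i, j] = SSE of fitting a constant on series[i..j] inclusive."""
    n = len(series)
    s1 = np.concatenate([[0.0], np.cumsum(series)])
    s2 = np.concatenate([[0.0], np.cumsum(series**2)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    length = j - i + 1
    tot = s1[j + 1] - s1[i]
    sq = s2[j + 1] - s2[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        cost = sq - tot**2 / length
    return np.where(length >= 1, np.maximum(cost, 0.0), np.inf)


def _optimal_cuts(cost: np.ndarray, n_breaks: int, min_seg: int) -> tuple[float, list[int]]:
    """DP over cut positions: minimal total SSE with exactly n_breaks cuts.

    Returns (RSS, breakpoints) where each breakpoint b means the cut
    falls after index b (0-based; segment ends at b). Infeasible
    configurations return (inf, []).
    """
    n = cost.shape[0]
    m = n_breaks + 1  # segments
    INF = np.inf
    # dp[k][e] = min cost of covering series[0..e] with k segments
    dp = np.full((m + 1, n), INF)
    back = np.full((m + 1, n), -1, dtype=int)
    for e in range(n):
        if e + 1 >= min_seg:
            dp[1, e] = cost[0, e]
    for k in range(2, m + 1):
        for e in range(n):
            if e + 1 < k * min_seg:
                continue
            starts = np.arange(k - 1, e + 1)
            starts = starts[(starts >= (k - 1) * min_seg) & (e - starts + 1 >= min_seg)]
            if len(starts) == 0:
                continue
            cand = dp[k - 1, starts - 1] + cost[starts, e]
            best = int(np.argmin(cand))
            dp[k, e] = cand[best]
            back[k, e] = starts[best]
    if not np.isfinite(dp[m, n - 1]):
        return INF, []
    cuts: list[int] = []
    e, k = n - 1, m
    while k > 1:
        s = back[k, e]
        cuts.append(s - 1)
        e, k = s - 1, k - 1
    return float(dp[m, n - 1]), sorted(cuts)


def estimate_breakpoints(
    series: np.ndarray | list[float],
    max_breaks: int = 5,
    min_segment: int | None = None,
) -> list[int]:
    """Optimal piecewise-constant breakpoints of a scree series.

    Minimises the within-segment sum of squared deviations by dynamic
    programming; the number of breaks (0..max_breaks) is chosen by BIC
    with 2m parameters for m segments. Returned indices are 0-based
    last-positions of each segment but the final one; a constant series
    yields [].
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < 3:
        raise ValueError("series must have length >= 3")
    if np.ptp(series) == 0:
        return []
    if min_segment is None:
        min_segment = max(2, int(np.ceil(0.05 * n)))

    cost = _segment_costs(series)
    best_bic, best_cuts = np.inf, []
    for b in range(0, max_breaks + 1):
        rss, cuts = _optimal_cuts(cost, b, min_segment)
        if not np.isfinite(rss):
            continue
        m = b + 1
        bic = n * np.log(max(rss, 1e-300) / n) + 2 * m * np.log(n)
        if bic < best_bic - 1e-12:
            best_bic, best_cuts = bic, cuts
    return best_cuts


def exhaustive_breakpoints(
    series: np.ndarray | list[float], n_breaks: int, min_segment: int = 2
) -> tuple[float, list[int]]:
    """Brute-force optimal cuts by enumerating all cut sets (oracle)."""
    series = np.asarray(series, dtype=float)
    n = len(series)
    best: tuple[float, list[int]] = (np.inf, [])
    for cuts in combinations(range(n - 1), n_breaks):
        bounds = [-1, *cuts, n - 1]
        if any(b - a < min_segment for a, b in zip(bounds, bounds[1:])):
            continue
        rss = 0.0
        for a, b in zip(bounds, bounds[1:]):
            seg = series[a + 1 : b + 1]
            rss += float(((seg - seg.mean()) ** 2).sum())
        if rss < best[0] - 1e-12:
            best = (rss, list(cuts))
    return best


def select_signature_asvs(ranking: GiniRanking, cap: int = 200, max_breaks: int = 5) -> list[str]:
    """Choose signature ASVs from the top-``cap`` scree curve.

    The MDG values of the top-cap ASVs are segmented; all ASVs ranked
    at or before the first breakpoint are selected. When segmentation
    finds no breakpoint (flat scree) the fallback is the top 10% of cap.
    """
    if ranking.mdg.empty:
        raise ValueError("empty ranking")
    top = ranking.top(cap)
    if len(top) < 3:
        return list(top.index)
    cuts = estimate_breakpoints(top.to_numpy(), max_breaks=max_breaks)
    if not cuts:
        return list(top.index[: max(1, int(round(0.10 * cap)))])
    return list(top.index[: cuts[0] + 1])
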