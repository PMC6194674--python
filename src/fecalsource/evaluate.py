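"""Benchmarks: prediction robustness, spike-in sensitivity, proxy accuracy.

Robustness repeats the ensemble training and prediction (signature
selection is reused) and summarises the spread of voting probabilities.
The sensitivity sweep spikes one source at a time into a freshwater
background at defined fractions and records the call band, mirroring
the artificial-assemblage benchmark. Proxy accuracy is the Spearman
rank correlation between the expected contamination proportions and
the proportion proxy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis
from scipy.stats import spearmanr

from .model import SourceTrackingResults, call_band, match_and_renormalize
from .seq_prep import ASVTable
from .simulate import MixSpec, SourcePanel, mix_assemblage

__all__ = [
    "robustness",
    "sensitivity_sweep",
    "detection_threshold",
    "proxy_correlation",
    "bray_curtis",
    "DEFAULT_SPIKE_FRACTIONS",
]

# default spike fractions: 1, 0.5, 0.1, 0.01 percent of the assemblage
DEFAULT_SPIKE_FRACTIONS = (0.01, 0.005, 0.001, 0.0001)


def robustness(
    results: SourceTrackingResults,
    table: ASVTable,
    n_repeats: int = 100,
    master_seed: int = 0,
    repeat_seeds: list[int] | None = None,
) -> pd.DataFrame:
    """Mean and SD of vote percentages over re-trained ensembles.

    Each repeat re-trains every source's forests with a fresh sub-seed
    (the signature ASVs are fixed) and re-predicts ``table``. Returns
    one row per (sample, source) with mean_vote_pct and sd_vote_pct.
    Passing explicit ``repeat_seeds`` (e.g. all identical) overrides
    the derived per-repeat seeds.
    """
    if repeat_seeds is None:
        if n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")
        ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(2,))
        repeat_seeds = [int(s) for s in ss.generate_state(n_repeats) % (2**31 - 1)]
    votes = []
    for seed in repeat_seeds:
        rep = results.retrain(seed)
        report = rep.predict(table)
        votes.append(report.set_index(["sample", "source"])["vote_pct"])
    stacked = pd.concat(votes, axis=1)
    # center on the first repeat so identical repeats give SD exactly 0
    centered = stacked.sub(stacked.iloc[:, 0], axis=0)
    out = pd.DataFrame(
        {"mean_vote_pct": stacked.mean(axis=1), "sd_vote_pct": centered.std(axis=1, ddof=0)}
    )
    return out.reset_index()


def sensitivity_sweep(
    results: SourceTrackingResults,
    panel: SourcePanel,
    fractions=DEFAULT_SPIKE_FRACTIONS,
    depth: int = 100_000,
    n_repeats: int = 20,
    master_seed: int = 0,
    sources: list[str] | None = None,
    background: str = "Freshwater",
    communities: dict | None = None,
) -> pd.DataFrame:
    """Spike each source into the background at each fraction; classify.

    Follows the artificial-assemblage protocol: one held-out community
    per source (and one background community) is drawn once, then for
    every (source, fraction) the assemblage of ``depth`` reads is
    rebuilt ``n_repeats`` times by independently seeded rarefying
    subsamples of the two components, and each repeat is classified by
    that source's classifier. ``communities`` overrides the held-out
    draws with explicit count vectors. Returns one row per repeat with
    vote_pct, band, matched reads and the fraction of assemblage reads
    matching the classifier.
    """
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must be in (0, 1]")
    sources = sources if sources is not None else [
        s for s in results.sources if s in panel.spec.sources
    ]
    rng = np.random.default_rng(master_seed)
    if communities is None:
        # held-out test communities, deep enough to cover any share
        communities = {
            name: panel.draw_sample(name, 2 * depth, rng)
            for name in [*sources, background]
        }
    rows = []
    for source in sources:
        clf = results.classifiers[source]
        vecs, meta = [], []
        for fraction in fractions:
            mix = MixSpec(
                {source: fraction, background: 1.0 - fraction},
                depth=depth,
                n_repeats=n_repeats,
                seed=int(rng.integers(2**31 - 1)),
            )
            mixed = mix_assemblage(mix, communities)
            for r in range(n_repeats):
                counts = pd.Series(mixed.counts[r], index=panel.asv_ids)
                vec, matched = match_and_renormalize(counts, panel.asv_sequences, clf)
                vecs.append(vec)
                meta.append((source, fraction, mix.seed, r, matched))
        probs = clf.vote_probabilities(np.vstack(vecs))
        for (src, fraction, seed, r, matched), p in zip(meta, probs):
            rows.append(
                {
                    "source": src,
                    "spike_fraction_pct": 100.0 * fraction,
                    "seed": seed,
                    "repeat": r,
                    "vote_pct": 100.0 * p,
                    "band": call_band(p),
                    "matched_reads": matched,
                    "matched_fraction_pct": 100.0 * matched / depth,
                }
            )
    return pd.DataFrame(rows)


def detection_threshold(grid: pd.DataFrame, min_positive_rate: float = 0.95) -> pd.Series:
    """Smallest spike fraction (percent) at which each source is called
    positive in at least ``min_positive_rate`` of assemblages."""
    out = {}
    for source, sub in grid.groupby("source"):
        rate = (
            sub.assign(pos=sub.band == "positive")
            .groupby("spike_fraction_pct")["pos"]
            .mean()
        )
        ok = rate[rate >= min_positive_rate]
        out[source] = float(ok.index.min()) if len(ok) else float("nan")
    return pd.Series(out, name="detection_threshold_pct")


def proxy_correlation(expected, proxy) -> tuple[float, float, int]:
    """Spearman rank correlation (average-rank ties) between expected
    contamination proportions and the proportion proxy.

    Returns (rho, p_value, n). A constant input vector has no defined
    rank correlation and raises."""
    expected = np.asarray(expected, dtype=float)
    proxy = np.asarray(proxy, dtype=float)
    if len(expected) != len(proxy):
        raise ValueError("paired vectors must have equal length")
    if len(expected) < 5:
        raise ValueError("need at least 5 pairs")
    if np.ptp(expected) == 0 or np.ptp(proxy) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = spearmanr(expected, proxy)
    return float(rho), float(p), len(expected)


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity on relative abundances: 0 for identical
    composition, 1 for disjoint support."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("zero-total vector")
    return float(braycurtis(a / a.sum(), b / b.sum()))
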