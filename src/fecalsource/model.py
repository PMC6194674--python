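"""One-vs-rest random-forest source tracking: model, fit, predict.

`SourceTrackingModel` holds an ASV count table and a sample-to-source
label map; `fit()` builds one classifier per source (plus composite
sources such as Pet = Cat+Dog) by ranking ASVs on averaged mean
decrease Gini, cutting the scree at its first breakpoint, recomputing
relative abundance over the selected signature ASVs and training a
pooled voting ensemble. The resulting `SourceTrackingResults` predicts
unknown samples by the fraction of trees voting "contaminated", bands
the votes (positive > 50%, marginal 45-50% and 40-45%), and ranks
sources by a proportion proxy: the share of a sample's sequences
matching each source's classifier among sequences matching any.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import signatures
from .seq_prep import ASVTable, relative_abundance
from .signatures import (
    GiniRanking,
    rank_asvs_by_gini,
    replicate_seeds,
    select_signature_asvs,
)

__all__ = [
    "ForestParams",
    "SourceLabelMap",
    "ClassifierModel",
    "Prediction",
    "ProxyReport",
    "SourceTrackingModel",
    "SourceTrackingResults",
    "make_binary_labels",
    "match_and_renormalize",
    "call_band",
]

DEFAULT_COMPOSITES = {"Pet": frozenset({"Cat", "Dog"}), "Ruminant": frozenset({"Cow", "Deer"})}


@dataclass(frozen=True)
class ForestParams:
    """Replicate/tree counts and selection caps.

    Defaults are the full-scale protocol: ranking with 100 replicates
    of 10,000 trees, training with 100 replicates of 1,000 trees pooled
    into one voting ensemble, scree cap 200. Scaled-down profiles (e.g.
    10 x 1,000 ranking forests) are set here for cheaper runs.
    """

    n_rank_replicates: int = 100
    n_rank_trees: int = 10_000
    n_train_replicates: int = 100
    n_train_trees: int = 1_000
    scree_cap: int = 200
    max_breaks: int = 5
    renormalize_within_selected: bool = True


@dataclass
class SourceLabelMap:
    """sample_id -> base source, plus composite (merged) sources."""

    labels: dict[str, str]
    composite_sources: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITES)
    )

    def __post_init__(self) -> None:
        base = set(self.labels.values())
        self.composite_sources = {
            name: frozenset(members)
            for name, members in self.composite_sources.items()
            if frozenset(members) <= base
        }

    @property
    def base_sources(self) -> list[str]:
        return sorted(set(self.labels.values()))

    @property
    def all_sources(self) -> list[str]:
        return self.base_sources + sorted(self.composite_sources)

    def members(self, source: str) -> frozenset[str]:
        if source in self.composite_sources:
            return self.composite_sources[source]
        if source in set(self.labels.values()):
            return frozenset({source})
        raise KeyError(f"unknown source {source!r}")


def make_binary_labels(labels: SourceLabelMap, target: str, sample_ids: list[str]) -> np.ndarray:
    """One-vs-rest vector: 1 for samples of ``target`` (or its composite
    members), 0 for every other sample."""
    members = labels.members(target)
    y = np.array([1 if labels.labels[s] in members else 0 for s in sample_ids])
    if y.sum() == 0:
        raise ValueError(f"positive class empty for source {target!r}")
    if y.sum() == len(y):
        raise ValueError(f"negative class empty for source {target!r}")
    return y


def call_band(vote_probability: float) -> str:
    """Band a voting-tree probability.

    positive requires a strict majority (> 0.50); 0.45-0.50 and
    0.40-0.45 are the marginal bands; below 0.40 is a no-call.
    """
    p = float(vote_probability)
    if not 0 <= p <= 1:
        raise ValueError("vote probability must be in [0, 1]")
    if p > 0.50:
        return "positive"
    if p >= 0.45:
        return "marginal_high"
    if p >= 0.40:
        return "marginal_low"
    return "negative"


@dataclass
class ClassifierModel:
    """A single source's signature ASVs plus its trained voting ensemble."""

    source: str
    selected_asvs: list[str]
    asv_sequences: dict[str, str]
    mdg: pd.Series
    forests: list[RandomForestClassifier]
    oob_error: float
    seed: int
    params: ForestParams
    training_samples: list[str]

    @property
    def n_trees(self) -> int:
        return sum(len(f.estimators_) for f in self.forests)

    def vote_probabilities(self, X: np.ndarray) -> np.ndarray:
        """Fraction of pooled trees voting the positive class, per row."""
        if not self.forests:
            raise ValueError(f"classifier {self.source!r} is untrained")
        X = np.atleast_2d(np.asarray(X))
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        votes = np.zeros(X.shape[0])
        total = 0
        for forest in self.forests:
            pos = int(np.where(forest.classes_ == 1)[0][0])
            for tree in forest.estimators_:
                # leaf class-count vector; argmax = the tree's vote
                counts = tree.tree_.predict(X32)
                counts = counts.reshape(counts.shape[0], -1)
                votes += (np.argmax(counts, axis=1) == pos).astype(float)
            total += len(forest.estimators_)
        return votes / total


@dataclass(frozen=True)
class Prediction:
    sample_id: str
    source: str
    vote_probability: float
    call_band: str
    matched_sequence_count: int


@dataclass
class ProxyReport:
    """Per-source proportion proxy for one sample (percent, sums to 100)."""

    sample_id: str
    proxy: dict[str, float]
    denominator: int

    @property
    def no_match(self) -> bool:
        return self.denominator == 0


def match_and_renormalize(
    sample_counts: pd.Series,
    sample_sequences: dict[str, str],
    classifier: ClassifierModel,
) -> tuple[np.ndarray, int]:
    """Align a sample's counts onto a classifier's signature ASVs.

    Matching is exact identity of representative sequences. Returns the
    abundance vector over the classifier's ASVs (renormalized to sum 1
    over matched ASVs; zero where unmatched, all-zero when nothing
    matches) and the total matched read count.
    """
    by_seq = {classifier.asv_sequences[a]: i for i, a in enumerate(classifier.selected_asvs)}
    vec = np.zeros(len(classifier.selected_asvs))
    for asv_id, count in sample_counts.items():
        if count <= 0:
            continue
        pos = by_seq.get(sample_sequences.get(asv_id, ""))
        if pos is not None:
            vec[pos] += count
    matched = int(vec.sum())
    if matched > 0:
        vec = vec / vec.sum()
    return vec, matched


class SourceTrackingModel:
    """Random-forest fecal source-tracking model over an ASV count table.

    Parameters
    ----------
    table : ASVTable
        Training counts (samples x ASVs) with representative sequences,
        restricted to one bacterial group (e.g. Clostridiales).
    labels : SourceLabelMap or dict
        sample_id -> source; composite sources default to
        Pet = Cat+Dog and Ruminant = Cow+Deer when their members exist.
    params : ForestParams
        Replicate/tree counts for ranking and training.
    """

    def __init__(
        self,
        table: ASVTable,
        labels: SourceLabelMap | dict[str, str],
        params: ForestParams = ForestParams(),
        sources: list[str] | None = None,
    ):
        if isinstance(labels, dict):
            labels = SourceLabelMap(dict(labels))
        missing = [s for s in table.sample_ids if s not in labels.labels]
        if missing:
            raise ValueError(f"samples without a source label: {missing[:5]}")
        self.table = table
        self.labels = labels
        self.params = params
        self.sources = sources if sources is not None else labels.all_sources

    @classmethod
    def from_dataframe(
        cls,
        counts: pd.DataFrame,
        metadata: pd.DataFrame,
        sequences: dict[str, str] | None = None,
        **kwargs,
    ) -> "SourceTrackingModel":
        """Build from a counts DataFrame and a metadata frame with
        columns ``sample_id`` and ``source`` (or an indexed series)."""
        if "sample_id" in metadata.columns:
            metadata = metadata.set_index("sample_id")
        labels = metadata["source"].to_dict()
        seqs = sequences if sequences is not None else {a: a for a in counts.columns}
        return cls(ASVTable(counts.astype(int), seqs), labels, **kwargs)

    # -- fitting -------------------------------------------------------

    def _rank(self, source: str, seed: int) -> GiniRanking:
        abund = relative_abundance(self.table)
        y = make_binary_labels(self.labels, source, self.table.sample_ids)
        return rank_asvs_by_gini(
            abund,
            y,
            n_replicates=self.params.n_rank_replicates,
            n_trees=self.params.n_rank_trees,
            seed=seed,
        )

    def _train_ensemble(
        self, X: np.ndarray, y: np.ndarray, seed: int
    ) -> tuple[list[RandomForestClassifier], float]:
        forests, oob = [], []
        for sub_seed in replicate_seeds(seed, self.params.n_train_replicates, stream=1):
            forest = RandomForestClassifier(
                n_estimators=self.params.n_train_trees,
                max_features="sqrt",
                bootstrap=True,
                oob_score=True,
                random_state=int(sub_seed),
                n_jobs=signatures.N_JOBS,
            )
            forest.fit(X, y)
            forests.append(forest)
            oob.append(1.0 - forest.oob_score_)
        return forests, float(np.mean(oob))

    def build_classifier(
        self, source: str, seed: int, selected: list[str] | None = None
    ) -> ClassifierModel:
        """Rank, select and train the voting ensemble for one source.

        ``selected`` skips ranking/selection and reuses a fixed
        signature set (used by robustness repeats, which re-train but
        do not re-select).
        """
        y = make_binary_labels(self.labels, source, self.table.sample_ids)
        if y.sum() < 2:
            raise ValueError(f"positive class for {source!r} has < 2 samples")
        if selected is None:
            ranking = self._rank(source, seed)
            selected = select_signature_asvs(
                ranking, cap=self.params.scree_cap, max_breaks=self.params.max_breaks
            )
            mdg = ranking.mdg.loc[selected]
        else:
            mdg = pd.Series(np.nan, index=selected)
        if not selected:
            raise ValueError(f"no signature ASVs selected for {source!r}")

        X = _recalculated_abundance(
            self.table.counts, selected, within_selected=self.params.renormalize_within_selected
        )
        forests, oob = self._train_ensemble(X, y, seed)
        return ClassifierModel(
            source=source,
            selected_asvs=list(selected),
            asv_sequences={a: self.table.asv_sequences[a] for a in selected},
            mdg=mdg,
            forests=forests,
            oob_error=oob,
            seed=seed,
            params=self.params,
            training_samples=self.table.sample_ids,
        )

    def fit(self, seed: int = 0) -> "SourceTrackingResults":
        """Build one classifier per source; deterministic given seed."""
        classifiers: dict[str, ClassifierModel] = {}
        for i, source in enumerate(self.sources):
            classifiers[source] = self.build_classifier(source, seed=seed + 1000 * i)
        return SourceTrackingResults(self, classifiers, seed)


def _recalculated_abundance(
    counts: pd.DataFrame, selected: list[str], within_selected: bool = True
) -> np.ndarray:
    """Re-calculated relative abundance over the signature set.

    Each sample's selected-ASV counts are renormalized to sum 1 within
    the set (all-zero rows stay zero); the alternative normalizes
    against the whole sample.
    """
    sub = counts[selected].to_numpy(dtype=float)
    denom = sub.sum(axis=1) if within_selected else counts.to_numpy(dtype=float).sum(axis=1)
    out = np.zeros_like(sub)
    nz = denom > 0
    out[nz] = sub[nz] / denom[nz, None]
    return out


class SourceTrackingResults:
    """Fitted per-source classifiers plus prediction and reporting."""

    def __init__(
        self,
        model: SourceTrackingModel,
        classifiers: dict[str, ClassifierModel],
        seed: int,
    ):
        self.model = model
        self.classifiers = classifiers
        self.seed = seed

    @property
    def sources(self) -> list[str]:
        return list(self.classifiers)

    @property
    def oob_errors(self) -> pd.Series:
        return pd.Series({s: c.oob_error for s, c in self.classifiers.items()})

    def summary(self) -> pd.DataFrame:
        """One row per source: signature size, OOB error, ensemble size."""
        rows = []
        for s, c in self.classifiers.items():
            rows.append(
                {
                    "source": s,
                    "n_signature_asvs": len(c.selected_asvs),
                    "oob_error": c.oob_error,
                    "n_trees": c.n_trees,
                    "n_training_samples": len(c.training_samples),
                }
            )
        return pd.DataFrame(rows).set_index("source")

    # -- prediction ----------------------------------------------------

    def predict_source(self, sample_counts: pd.Series, sample_sequences: dict[str, str],
                       source: str, sample_id: str = "sample") -> Prediction:
        clf = self.classifiers[source]
        vec, matched = match_and_renormalize(sample_counts, sample_sequences, clf)
        p = float(clf.vote_probabilities(vec[None, :])[0])
        return Prediction(sample_id, source, p, call_band(p), matched)

    def proportion_proxy(
        self, sample_counts: pd.Series, sample_sequences: dict[str, str],
        sample_id: str = "sample", denominator: str = "multiset"
    ) -> ProxyReport:
        """Share of classifier-matching sequences per source (percent).

        With the default multiset denominator an ASV shared by k
        classifiers contributes to k numerators and k times to the
        denominator; ``denominator="union"`` counts each matching read
        once.
        """
        numerators: dict[str, int] = {}
        union_reads = 0
        seq_sets = {s: set(c.asv_sequences.values()) for s, c in self.classifiers.items()}
        any_seqs = set().union(*seq_sets.values()) if seq_sets else set()
        for asv_id, count in sample_counts.items():
            if count <= 0:
                continue
            seq = sample_sequences.get(asv_id, "")
            for s, seqs in seq_sets.items():
                if seq in seqs:
                    numerators[s] = numerators.get(s, 0) + int(count)
            if seq in any_seqs:
                union_reads += int(count)
        numerators = {s: numerators.get(s, 0) for s in self.classifiers}
        denom = sum(numerators.values()) if denominator == "multiset" else union_reads
        if denom == 0:
            return ProxyReport(sample_id, {s: 0.0 for s in self.classifiers}, 0)
        return ProxyReport(sample_id, {s: 100.0 * n / denom for s, n in numerators.items()}, denom)

    def predict(self, table: ASVTable, denominator: str = "multiset") -> pd.DataFrame:
        """Classify every sample of an unknown table against every source.

        Returns a long-format frame with columns sample, source,
        vote_pct, band, proxy_pct, matched_reads — one row per
        (sample, source), the layout of a contamination report table.
        """
        # Batch: per classifier, one vote pass over all samples.
        rows = []
        matched_mat: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for s, clf in self.classifiers.items():
            vecs, matched = [], []
            for sid in table.sample_ids:
                v, m = match_and_renormalize(table.counts.loc[sid], table.asv_sequences, clf)
                vecs.append(v)
                matched.append(m)
            probs = clf.vote_probabilities(np.vstack(vecs))
            matched_mat[s] = (probs, np.array(matched))
        proxies = {
            sid: self.proportion_proxy(
                table.counts.loc[sid], table.asv_sequences, sid, denominator=denominator
            )
            for sid in table.sample_ids
        }
        for i, sid in enumerate(table.sample_ids):
            for s in self.classifiers:
                probs, matched = matched_mat[s]
                rows.append(
                    {
                        "sample": sid,
                        "source": s,
                        "vote_pct": 100.0 * probs[i],
                        "band": call_band(probs[i]),
                        "proxy_pct": proxies[sid].proxy[s],
                        "matched_reads": int(matched[i]),
                    }
                )
        return pd.DataFrame(rows)

    def retrain(self, seed: int) -> "SourceTrackingResults":
        """Re-train every ensemble with a new seed, reusing the already
        selected signature ASVs (the robustness-repeat protocol)."""
        classifiers = {
            s: self.model.build_classifier(s, seed=seed + 1000 * i, selected=c.selected_asvs)
            for i, (s, c) in enumerate(self.classifiers.items())
        }
        return SourceTrackingResults(self.model, classifiers, seed)
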