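"""Read quality control and entropy-based ASV partitioning.

Merged amplicon reads are screened for ambiguous bases, long homopolymer
runs and aberrant lengths, then partitioned into amplicon sequence
variants (ASVs) by minimum entropy decomposition (MED): reads are split
recursively at the nucleotide position of highest Shannon entropy until
every node falls below an entropy criterion, and nodes smaller than the
minimum substantive abundance M = floor(N / divisor) are discarded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SequenceRead",
    "QCParams",
    "MEDParams",
    "ASVTable",
    "filter_reads",
    "med_partition",
    "relative_abundance",
    "positional_entropy",
]

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SequenceRead:
    """A merged amplicon read assigned to a sample."""

    read_id: str
    bases: str
    sample_id: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"read {self.read_id!r}: empty sequence")


@dataclass(frozen=True)
class QCParams:
    """Quality-screen thresholds.

    ``length_tolerance`` is a fraction of the median read length: the
    V6 region uses 0.10 around its 60 bp median, V4V5 uses 0.05 around
    372 bp. ``median_length`` is computed from the data when ``None``.
    """

    max_homopolymer_run: int = 8
    length_tolerance: float = 0.10
    median_length: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.length_tolerance < 1:
            raise ValueError("length_tolerance must be in (0, 1)")
        if self.max_homopolymer_run < 1:
            raise ValueError("max_homopolymer_run must be >= 1")


@dataclass(frozen=True)
class MEDParams:
    """MED decomposition controls.

    ``min_substantive_abundance_divisor`` sets M = floor(N / divisor):
    50,000 for V6, 10,000 for V4V5. ``entropy_threshold`` (bits) is the
    maximum positional entropy a final node may retain; an explicit
    knob (default 0.1) since no single value suits every region and depth.
    ``length_policy`` handles unequal read lengths: "trim" cuts all
    reads to the modal length, "error" refuses.
    """

    min_substantive_abundance_divisor: int = 50_000
    entropy_threshold: float = 0.1
    length_policy: str = "trim"

    def __post_init__(self) -> None:
        if self.min_substantive_abundance_divisor < 1:
            raise ValueError("divisor must be >= 1")
        if self.entropy_threshold < 0:
            raise ValueError("entropy_threshold must be >= 0")
        if self.length_policy not in ("trim", "error"):
            raise ValueError("length_policy must be 'trim' or 'error'")


@dataclass
class ASVTable:
    """Per-sample ASV counts with representative sequences.

    ``counts`` is a samples x ASVs DataFrame of non-negative integers;
    ``asv_sequences`` maps each ASV column id to its representative DNA
    sequence.
    """

    counts: pd.DataFrame
    asv_sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.asv_sequences)
        if self.asv_sequences and missing:
            raise ValueError(f"ASVs without a representative sequence: {sorted(missing)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total_sequences(self) -> int:
        return int(self.counts.to_numpy().sum())

    def subset_samples(self, sample_ids) -> "ASVTable":
        return ASVTable(self.counts.loc[list(sample_ids)].copy(), dict(self.asv_sequences))


def _longest_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > best:
            best = run
    return best


def filter_reads(
    reads: list[SequenceRead], params: QCParams = QCParams()
) -> tuple[list[SequenceRead], pd.DataFrame]:
    """Screen merged reads; returns (kept reads, rejection log).

    A read is discarded when it contains a base outside {A,C,G,T}, has a
    single-base run longer than ``max_homopolymer_run``, or has a length
    outside median*(1 +- tolerance) (inclusive bounds). The log has one
    row per rejected read with columns read_id, sample_id, reason.
    """
    if not reads:
        return [], pd.DataFrame(columns=["read_id", "sample_id", "reason"])

    median = params.median_length
    if median is None:
        median = int(np.median([len(r.bases) for r in reads]))
    lo = median * (1 - params.length_tolerance)
    hi = median * (1 + params.length_tolerance)

    kept: list[SequenceRead] = []
    rejected: list[tuple[str, str, str]] = []
    for r in reads:
        seq = r.bases.upper()
        if set(seq) - _VALID_BASES:
            rejected.append((r.read_id, r.sample_id, "ambiguous base"))
        elif _longest_run(seq) > params.max_homopolymer_run:
            rejected.append((r.read_id, r.sample_id, "homopolymer"))
        elif not (lo <= len(seq) <= hi):
            rejected.append((r.read_id, r.sample_id, "length"))
        else:
            kept.append(r)
    log = pd.DataFrame(rejected, columns=["read_id", "sample_id", "reason"])
    return kept, log


# --- MED ---------------------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def positional_entropy(matrix: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) at each column of an encoded read matrix."""
    n, length = matrix.shape
    ent = np.zeros(length)
    for j in range(length):
        _, counts = np.unique(matrix[:, j], return_counts=True)
        p = counts / n
        ent[j] = -(p * np.log2(p)).sum()
    return ent


def _encode(reads: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(reads).encode("ascii"), dtype=np.uint8)
    return arr.reshape(len(reads), len(reads[0]))


def med_partition(
    reads: list[SequenceRead], params: MEDParams = MEDParams()
) -> tuple[ASVTable, dict]:
    """Partition QC-passed reads into ASVs by minimum entropy decomposition.

    Splits the read pool at the highest-entropy position (leftmost on
    ties), recursing until every node's maximum positional entropy is at
    or below ``entropy_threshold``; nodes with fewer than M reads are
    then discarded. The representative sequence of an ASV is its most
    frequent read. Returns the ASV table and a diagnostics dict with
    N, M, retained read count and retained fraction.
    """
    if not reads:
        raise ValueError("no reads to partition")

    lengths = Counter(len(r.bases) for r in reads)
    if len(lengths) > 1:
        if params.length_policy == "error":
            raise ValueError(f"unequal read lengths {sorted(lengths)} with length_policy='error'")
        modal = lengths.most_common(1)[0][0]
        reads = [
            SequenceRead(r.read_id, r.bases[:modal], r.sample_id)
            for r in reads
            if len(r.bases) >= modal
        ]
        if not reads:
            raise ValueError("no reads at or above the modal length")

    n_total = len(reads)
    m_min = n_total // params.min_substantive_abundance_divisor
    if m_min >= n_total:
        raise ValueError(f"M = {m_min} >= N = {n_total}: no ASV can satisfy the abundance floor")
    m_min = max(m_min, 1)

    seqs = [r.bases.upper() for r in reads]
    mat = _encode(seqs)
    samples = np.array([r.sample_id for r in reads])

    final_nodes: list[np.ndarray] = []

    def decompose(idx: np.ndarray) -> None:
        sub = mat[idx]
        ent = positional_entropy(sub)
        peak = int(np.argmax(ent))  # leftmost max
        if ent[peak] <= params.entropy_threshold:
            final_nodes.append(idx)
            return
        col = sub[:, peak]
        for base in sorted(np.unique(col)):
            decompose(idx[col == base])

    decompose(np.arange(n_total))

    # Stable node order: by representative sequence, so input order never matters.
    survivors = [node for node in final_nodes if len(node) >= m_min]
    reps: list[tuple[str, np.ndarray]] = []
    for node in survivors:
        counter = Counter(seqs[i] for i in node)
        top = max(counter.items(), key=lambda kv: (kv[1], kv[0]))[0]
        reps.append((top, node))
    reps.sort(key=lambda t: (-len(t[1]), t[0]))

    sample_ids = sorted(set(samples))
    asv_ids = [f"ASV_{k + 1:04d}" for k in range(len(reps))]
    counts = pd.DataFrame(0, index=sample_ids, columns=asv_ids, dtype=int)
    for asv_id, (_, node) in zip(asv_ids, reps):
        for sid, c in Counter(samples[node]).items():
            counts.loc[sid, asv_id] = c

    table = ASVTable(counts, {a: rep for a, (rep, _) in zip(asv_ids, reps)})
    retained = int(sum(len(node) for node in survivors))
    diagnostics = {
        "N": n_total,
        "M": m_min,
        "n_asvs": len(reps),
        "n_retained": retained,
        "retained_fraction": retained / n_total,
    }
    return table, diagnostics


def relative_abundance(table: ASVTable | pd.DataFrame) -> pd.DataFrame:
    """Row-normalize counts to proportions; each row sums to 1."""
    counts = table.counts if isinstance(table, ASVTable) else table
    totals = counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero count row(s): {list(zero.index)}")
    return counts.div(totals, axis=0)
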