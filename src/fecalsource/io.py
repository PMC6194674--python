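"""Readers, writers and classifier-bundle serialization.

Native exchange formats: TSV count tables (rows = samples, columns =
ASV ids), FASTA for representative sequences, JSON manifests. A fitted
model is persisted as a bundle directory: manifest.json with every
parameter and seed, a signature-ASV FASTA and a joblib-serialized
ensemble per source, plus a probe vector whose stored vote probability
is re-checked on load.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import ClassifierModel, ForestParams, SourceTrackingResults
from .seq_prep import ASVTable, MEDParams, QCParams, SequenceRead

__all__ = [
    "RunConfig",
    "read_count_table",
    "write_count_table",
    "read_fasta_reads",
    "write_fasta",
    "save_bundle",
    "load_bundle",
]

BUNDLE_VERSION = 1


@dataclass
class RunConfig:
    """All pipeline stage parameters plus the master seed.

    Serialises losslessly to/from YAML so a recorded run can be
    reproduced from its config file alone.
    """

    qc: QCParams = field(default_factory=QCParams)
    med: MEDParams = field(default_factory=MEDParams)
    forest: ForestParams = field(default_factory=ForestParams)
    seed: int = 0
    output_dir: str = "."
    verbosity: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "qc": asdict(self.qc),
            "med": asdict(self.med),
            "forest": asdict(self.forest),
            "seed": self.seed,
            "output_dir": self.output_dir,
            "verbosity": self.verbosity,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            qc=QCParams(**payload.get("qc", {})),
            med=MEDParams(**payload.get("med", {})),
            forest=ForestParams(**payload.get("forest", {})),
            seed=payload.get("seed", 0),
            output_dir=payload.get("output_dir", "."),
            verbosity=payload.get("verbosity", "INFO"),
        )


def read_count_table(path: str | Path, fasta: str | Path | None = None) -> ASVTable:
    """Read a samples x ASVs TSV (first column sample ids), optionally
    joining representative sequences from a companion FASTA."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.has_duplicates:
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s): {dupes}")
    if counts.columns.has_duplicates:
        dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate ASV id(s): {dupes}")
    try:
        arr = counts.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if (arr < 0).any():
        raise ValueError(f"negative count in {path}")
    if (arr != np.floor(arr)).any():
        raise ValueError(f"non-integer count in {path}")
    counts = counts.astype(int)
    sequences: dict[str, str] = {}
    if fasta is not None:
        sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
        missing = set(counts.columns) - set(sequences)
        if missing:
            raise ValueError(f"FASTA lacks sequences for ASVs: {sorted(missing)[:5]}")
    else:
        sequences = {a: a for a in counts.columns}
    return ASVTable(counts, sequences)


def write_count_table(table: ASVTable, path: str | Path, fasta: str | Path | None = None) -> None:
    table.counts.to_csv(path, sep="\t")
    if fasta is not None:
        write_fasta(table.asv_sequences, fasta)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_reads(
    path: str | Path, sample_map: dict[str, str] | None = None, sample_id: str | None = None
) -> list[SequenceRead]:
    """Load merged reads from a (optionally gzipped) FASTA.

    Sample assignment: ``sample_id`` labels every read, or
    ``sample_map`` maps read-id prefixes (text before the last '_') to
    samples; default falls back to the prefix itself.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    reads = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if sample_id is not None:
                sid = sample_id
            else:
                prefix = rec.id.rsplit("_", 1)[0]
                sid = sample_map.get(prefix, prefix) if sample_map else prefix
            reads.append(SequenceRead(rec.id, str(rec.seq).upper(), sid))
    return reads


# -- classifier bundles -------------------------------------------------


def save_bundle(results: SourceTrackingResults, path: str | Path) -> None:
    """Persist fitted classifiers to a directory with a manifest.

    A probe prediction (the all-ones renormalized vector through each
    ensemble) is stored so that load can verify the deserialized
    forests reproduce votes exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": BUNDLE_VERSION,
        "seed": results.seed,
        "params": vars(results.model.params),
        "sources": {},
    }
    for source, clf in results.classifiers.items():
        probe = np.full((1, len(clf.selected_asvs)), 1.0 / len(clf.selected_asvs))
        manifest["sources"][source] = {
            "n_signature_asvs": len(clf.selected_asvs),
            "selected_asvs": clf.selected_asvs,
            "oob_error": clf.oob_error,
            "seed": clf.seed,
            "n_replicates": clf.params.n_train_replicates,
            "n_trees_per_replicate": clf.params.n_train_trees,
            "training_samples": clf.training_samples,
            "probe_vote_probability": float(clf.vote_probabilities(probe)[0]),
            "model_file": f"{source}.joblib",
            "fasta_file": f"{source}.fasta",
        }
        joblib.dump(
            {"forests": clf.forests, "mdg": clf.mdg}, path / f"{source}.joblib", compress=3
        )
        write_fasta(clf.asv_sequences, path / f"{source}.fasta")
        clf.mdg.rename("mean_decrease_gini").rename_axis("asv_id").to_csv(
            path / f"{source}_mdg.tsv", sep="\t"
        )
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_bundle(path: str | Path) -> dict[str, ClassifierModel]:
    """Load a bundle directory back into per-source classifiers,
    verifying version and the stored probe vote probability."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("version") != BUNDLE_VERSION:
        raise ValueError(f"bundle version {manifest.get('version')} != {BUNDLE_VERSION}")
    params = ForestParams(**manifest["params"])
    classifiers: dict[str, ClassifierModel] = {}
    for source, entry in manifest["sources"].items():
        model_file = path / entry["model_file"]
        if not model_file.exists():
            raise FileNotFoundError(f"bundle missing model file for source {source!r}")
        payload = joblib.load(model_file)
        sequences = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(path / entry["fasta_file"]), "fasta")
        }
        clf = ClassifierModel(
            source=source,
            selected_asvs=entry["selected_asvs"],
            asv_sequences=sequences,
            mdg=payload["mdg"],
            forests=payload["forests"],
            oob_error=entry["oob_error"],
            seed=entry["seed"],
            params=params,
            training_samples=entry["training_samples"],
        )
        probe = np.full((1, len(clf.selected_asvs)), 1.0 / len(clf.selected_asvs))
        got = float(clf.vote_probabilities(probe)[0])
        if got != entry["probe_vote_probability"]:
            raise ValueError(
                f"bundle corrupt: probe vote {got} != stored "
                f"{entry['probe_vote_probability']} for {source!r}"
            )
        classifiers[source] = clf
    return classifiers
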