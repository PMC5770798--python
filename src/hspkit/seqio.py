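"""Protein sequence I/O and residue validation.

Reads and writes multi-record FASTA, enforces the 20-letter standard
amino-acid alphabet (sequences containing B, J, O, U, X, Z, ``*`` or gap
characters are rejected or dropped), and handles labeled datasets and
tab-separated feature tables with full round-trip precision.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

log = logging.getLogger("hspkit")

#: The 20 standard amino acids, the fixed alphabet of every encoder.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class SequenceError(ValueError):
    """Malformed FASTA input or an invalid sequence record."""


class ValidationError(SequenceError):
    """A record failed the standard-residue filter under policy='reject'."""


@dataclass(frozen=True)
class RawRecord:
    """A FASTA entry before residue validation."""

    id: str
    residues: str
    description: str = ""


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence over the 20 standard amino acids."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - AA_SET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains non-standard residues: "
                f"{''.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Rejection:
    """Record of a sequence excluded by the standard-residue filter."""

    id: str
    offending: str  # sorted unique offending characters


@dataclass
class LabeledDataset:
    """Parallel lists of validated sequences and class labels."""

    sequences: list[ProteinSequence]
    labels: list[str]
    label_set: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ValueError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        if self.label_set is None:
            self.label_set = frozenset(self.labels)
        else:
            self.label_set = frozenset(self.label_set)
            extra = set(self.labels) - self.label_set
            if extra:
                raise ValueError(f"labels outside declared label set: {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def subset(self, mask) -> "LabeledDataset":
        idx = np.flatnonzero(np.asarray(mask))
        return LabeledDataset(
            [self.sequences[i] for i in idx],
            [self.labels[i] for i in idx],
            self.label_set,
        )


def read_fasta(path: str | os.PathLike) -> list[RawRecord]:
    """Parse a FASTA file into raw records (no residue validation).

    Header lines are split on the first whitespace into id and description;
    sequence lines are concatenated, whitespace-stripped and uppercased.
    Raises :class:`SequenceError` for text before the first ``>``, or for a
    record with an empty sequence.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such FASTA file: {path}")
    with open(path) as handle:
        for line in handle:
            if line.strip():
                if not line.startswith(">"):
                    raise SequenceError(
                        f"{path}: text before first '>' header: {line.strip()[:40]!r}"
                    )
                break
        handle.seek(0)
        records = []
        for title, seq in SimpleFastaParser(handle):
            parts = title.split(None, 1)
            rid = parts[0] if parts else ""
            desc = parts[1] if len(parts) > 1 else ""
            residues = "".join(seq.split()).upper()
            if not rid:
                raise SequenceError(f"{path}: record with empty header")
            if not residues:
                raise SequenceError(f"{path}: record {rid!r} has an empty sequence")
            records.append(RawRecord(id=rid, residues=residues, description=desc))
    return records


def write_fasta(sequences, path: str | os.PathLike, width: int = 60) -> None:
    """Write sequences as wrapped multi-line FASTA."""
    with open(path, "w") as out:
        for s in sequences:
            header = s.id if not s.description else f"{s.id} {s.description}"
            out.write(f">{header}\n")
            for i in range(0, len(s.residues), width):
                out.write(s.residues[i : i + width] + "\n")


def validate_residues(
    record: RawRecord, policy: str = "reject"
) -> ProteinSequence | Rejection:
    """Apply the standard-residue filter to one record.

    Under ``policy='reject'`` a record with any character outside the
    20-letter alphabet raises :class:`ValidationError` naming the offending
    characters; under ``policy='drop'`` it returns a :class:`Rejection`
    the caller is expected to exclude. Valid records pass through unchanged.
    """
    if policy not in ("reject", "drop"):
        raise ValueError(f"unknown policy {policy!r}; expected 'reject' or 'drop'")
    residues = record.residues.upper()
    bad = set(residues) - AA_SET
    if bad:
        offending = "".join(sorted(bad))
        if policy == "reject":
            raise ValidationError(
                f"sequence {record.id!r} contains non-standard residues: {offending}"
            )
        return Rejection(id=record.id, offending=offending)
    return ProteinSequence(id=record.id, residues=residues, description=record.description)


def validate_dataset(
    records, policy: str = "reject"
) -> tuple[list[ProteinSequence], list[Rejection]]:
    """Validate a list of raw records; returns (kept, rejected).

    Under ``policy='reject'`` the first invalid record raises. Under
    ``policy='drop'`` invalid records are excluded and counted in the log.
    """
    kept: list[ProteinSequence] = []
    rejected: list[Rejection] = []
    for rec in records:
        out = validate_residues(rec, policy=policy)
        if isinstance(out, Rejection):
            rejected.append(out)
        else:
            kept.append(out)
    if rejected:
        log.info(
            "dropped %d sequence(s) with non-standard residues: %s",
            len(rejected),
            ", ".join(r.id for r in rejected[:10]),
        )
    return kept, rejected


def read_label_table(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column (id, label) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "label"], dtype=str)
    return dict(zip(df["id"], df["label"]))


def write_label_table(ids, labels, path: str | os.PathLike) -> None:
    pd.DataFrame({"id": ids, "label": labels}).to_csv(
        path, sep="\t", header=False, index=False
    )


def load_labeled_dataset(
    fasta_path, labels_path, policy: str = "reject", label_set=None
) -> LabeledDataset:
    """Read FASTA plus an (id, label) TSV into a LabeledDataset."""
    kept, _ = validate_dataset(read_fasta(fasta_path), policy=policy)
    table = read_label_table(labels_path)
    missing = [s.id for s in kept if s.id not in table]
    if missing:
        raise ValueError(f"no label for sequence id(s): {missing[:10]}")
    return LabeledDataset(kept, [table[s.id] for s in kept], label_set)


def save_labeled_dataset(data: LabeledDataset, fasta_path, labels_path) -> None:
    write_fasta(data.sequences, fasta_path)
    write_label_table(data.ids, data.labels, labels_path)


def write_feature_table(matrix, ids, names, path: str | os.PathLike) -> None:
    """Write a feature matrix as TSV (first column ``id``) at full precision."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("feature matrix must be 2-dimensional")
    if matrix.shape[0] != len(ids):
        raise ValueError(f"{matrix.shape[0]} rows but {len(ids)} ids")
    if matrix.shape[1] != len(names):
        raise ValueError(f"{matrix.shape[1]} columns but {len(names)} names")
    df = pd.DataFrame(matrix, index=pd.Index(ids, name="id"), columns=list(names))
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV written by :func:`write_feature_table` (index = id)."""
    return pd.read_csv(path, sep="\t", index_col="id", float_precision="round_trip")
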