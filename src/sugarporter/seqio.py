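"""Sequence records, alignments and the flat-file formats they travel in.

Everything downstream (profile screening, tree building, motif scanning)
works on two in-memory containers: :class:`ProteinRecord` for unaligned
protein sequences and :class:`MSA` for aligned ones.  Parsing of
FASTA/Stockholm is delegated to Biopython.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP_CHARS = frozenset("-.")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class ProteinRecord:
    """A protein sequence plus the annotation the pipeline consumes.

    ``substrate_labels`` is only populated for characterized reference
    transporters; candidates carry an empty set and never contribute to
    label propagation.
    """

    id: str
    sequence: str
    species: str = ""
    is_reference: bool = False
    substrate_labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")
        self.sequence = self.sequence.upper()
        self.substrate_labels = frozenset(self.substrate_labels)

    def __len__(self) -> int:
        return len(self.sequence)


class MSA:
    """A multiple sequence alignment: unique row ids, equal-length rows.

    Gap characters are '-' and '.'; both are treated identically and
    normalized to '-'.
    """

    def __init__(self, ids: Sequence[str], sequences: Sequence[str]):
        ids = list(ids)
        sequences = [s.upper().replace(".", "-") for s in sequences]
        if not ids:
            raise ValueError("alignment must contain at least one row")
        if len(ids) != len(sequences):
            raise ValueError("ids and sequences differ in number")
        if len(set(ids)) != len(ids):
            raise ValueError("alignment row ids must be unique")
        ncol = len(sequences[0])
        if any(len(s) != ncol for s in sequences):
            raise ValueError("alignment rows must all have the same length")
        self.ids = ids
        self.sequences = sequences

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.sequences[0])

    def to_array(self) -> np.ndarray:
        """Rows x columns array of single characters."""
        return np.array([list(s) for s in self.sequences], dtype="U1")

    def gap_fraction(self) -> np.ndarray:
        """Per-column fraction of gap characters."""
        arr = self.to_array()
        return (arr == "-").mean(axis=0)

    def select_columns(self, columns: Iterable[int]) -> "MSA":
        cols = list(columns)
        seqs = ["".join(s[c] for c in cols) for s in self.sequences]
        return MSA(self.ids, seqs)

    def row(self, row_id: str) -> str:
        return self.sequences[self.ids.index(row_id)]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, MSA)
            and self.ids == other.ids
            and self.sequences == other.sequences
        )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sequence ids in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_alignment(path: str | Path, fmt: str | None = None) -> MSA:
    """Read an aligned FASTA or Stockholm file.

    The format is inferred from the extension when ``fmt`` is None
    (``.sto``/``.stk``/``.stockholm`` -> Stockholm, everything else FASTA).
    """
    path = Path(path)
    if fmt is None:
        fmt = (
            "stockholm"
            if path.suffix.lower() in {".sto", ".stk", ".stockholm"}
            else "fasta"
        )
    aln = AlignIO.read(str(path), fmt)
    return MSA([rec.id for rec in aln], [str(rec.seq) for rec in aln])


def write_alignment(msa: MSA, path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(msa.ids, msa.sequences)
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_label_table(path: str | Path) -> dict[str, dict]:
    """Read the reference label table.

    TSV with header ``id``, ``species``, ``substrate_labels``; labels are
    semicolon-separated.  Returns id -> {species, substrate_labels}.
    """
    out: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "species", "substrate_labels"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"label table {path} must have columns {sorted(required)}"
            )
        for row in reader:
            labels = frozenset(
                tok.strip() for tok in row["substrate_labels"].split(";") if tok.strip()
            )
            out[row["id"]] = {"species": row["species"], "substrate_labels": labels}
    if not out:
        raise ValueError(f"label table {path} has no data rows")
    return out


def apply_labels(
    records: Iterable[ProteinRecord], labels: dict[str, dict]
) -> list[ProteinRecord]:
    """Mark the records present in the label table as references."""
    out = []
    for rec in records:
        if rec.id in labels:
            info = labels[rec.id]
            rec = ProteinRecord(
                id=rec.id,
                sequence=rec.sequence,
                species=info["species"],
                is_reference=True,
                substrate_labels=info["substrate_labels"],
            )
        out.append(rec)
    return out
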