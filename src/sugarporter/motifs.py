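"""Degenerate signature-motif grammar, scanning and clade conservation.

Sugar porter signature motifs are written in the field's compact notation:
uppercase residues match exactly, ``x`` matches any residue, and ``/``
joins the flanking residues into a single alternative position (so
``YYxP/T`` is a four-position motif whose last position is P or T).
Motifs are scanned against unaligned sequences; per clade the fraction of
members carrying each motif and the observed variant strings are tabulated
(the conservation-table view of the family), and position-frequency
matrices can be exported from an alignment in place of rendered logos.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .phylo import CladeAssignment
from .seqio import AMINO_ACIDS, MSA, ProteinRecord

# token: tuple of allowed residues, or None for the 'x' wildcard
Token = tuple[str, ...] | None

DEFAULT_CONSERVATION_THRESHOLD = 0.9


@dataclass(frozen=True)
class MotifPattern:
    name: str
    tokens: tuple[Token, ...]
    region_hint: int | None = None  # TMH index (1-12), annotation only

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("motif must have at least one token")
        for tok in self.tokens:
            if tok is not None and len(set(tok)) < 1:
                raise ValueError("alternative set must be non-empty")
            if tok is not None and len(tok) != len(set(tok)):
                raise ValueError("alternative set has repeated residues")
        if self.region_hint is not None and not 1 <= self.region_hint <= 12:
            raise ValueError("region_hint must be a TMH index in 1..12")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    pattern: str
    start: int  # 0-based
    matched: str


def parse_motif(
    text: str, name: str | None = None, region_hint: int | None = None
) -> MotifPattern:
    """Parse a degenerate motif string like ``GGxxxGxD`` or ``YYxP/T``.

    ``/`` binds exactly the two flanking single residues into one
    alternative position; chained alternatives (``A/B/C``) are accepted.
    ``x`` is the wildcard.  Errors: leading/trailing ``/``, ``//``, and
    ``/`` adjacent to ``x``.
    """
    if not text:
        raise ValueError("empty motif string")
    tokens: list[Token] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "/":
            raise ValueError(f"motif {text!r}: '/' must be between two residues")
        if ch == "x":
            tokens.append(None)
            i += 1
            continue
        if ch not in AMINO_ACIDS:
            raise ValueError(f"motif {text!r}: invalid character {ch!r}")
        alts = [ch]
        i += 1
        while i < n and text[i] == "/":
            if i + 1 >= n:
                raise ValueError(f"motif {text!r}: trailing '/'")
            nxt = text[i + 1]
            if nxt == "/":
                raise ValueError(f"motif {text!r}: '//' is not allowed")
            if nxt == "x":
                raise ValueError(f"motif {text!r}: '/' cannot join the wildcard")
            if nxt not in AMINO_ACIDS:
                raise ValueError(f"motif {text!r}: invalid character {nxt!r}")
            alts.append(nxt)
            i += 2
        tokens.append(tuple(alts))
    return MotifPattern(
        name=name if name is not None else text,
        tokens=tuple(tokens),
        region_hint=region_hint,
    )


def write_motif(pattern: MotifPattern) -> str:
    """Canonical motif string; inverse of :func:`parse_motif`."""
    parts = []
    for tok in pattern.tokens:
        parts.append("x" if tok is None else "/".join(tok))
    return "".join(parts)


def scan_sequence(
    pattern: MotifPattern,
    protein: ProteinRecord | str,
    window: tuple[int, int] | None = None,
) -> list[MotifHit]:
    """All (possibly overlapping) motif matches, in ascending position.

    ``window`` restricts the scan to a half-open interval of start
    positions whose full match still fits inside the window.  Ambiguous
    'X' residues in the sequence match only the wildcard.
    """
    if isinstance(protein, ProteinRecord):
        pid, seq = protein.id, protein.sequence
    else:
        pid, seq = "", protein
    m = len(pattern.tokens)
    lo, hi = 0, len(seq)
    if window is not None:
        lo, hi = window
        if not (0 <= lo <= hi <= len(seq)):
            raise ValueError(f"window {window} outside sequence bounds")
    hits: list[MotifHit] = []
    for start in range(lo, hi - m + 1):
        ok = True
        for tok, ch in zip(pattern.tokens, seq[start : start + m]):
            if tok is not None and ch not in tok:
                ok = False
                break
        if ok:
            hits.append(
                MotifHit(
                    protein_id=pid,
                    pattern=pattern.name,
                    start=start,
                    matched=seq[start : start + m],
                )
            )
    return hits


@dataclass
class ConservationTable:
    """Clade x motif presence fractions plus the observed variant strings."""

    fractions: pd.DataFrame  # clades x motifs, values in [0, 1]
    conserved: pd.DataFrame  # boolean, fractions >= threshold
    variants: dict[tuple[str, str], Counter]
    threshold: float

    def to_tsv(self, path: str | Path) -> None:
        self.fractions.to_csv(path, sep="\t", float_format="%.4f")


def clade_conservation(
    assignment: CladeAssignment,
    proteins: Iterable[ProteinRecord],
    patterns: Sequence[MotifPattern],
    threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
    warn: callable = None,
) -> ConservationTable:
    """Per clade, the fraction of members carrying each motif.

    A member counts once per motif no matter how many hits it has; each
    member's distinct matched variant strings are tallied per clade.  A
    motif is flagged conserved in a clade when its fraction meets the
    threshold.  Clades with zero members are excluded (with a warning via
    ``warn`` when provided).
    """
    by_id = {p.id: p for p in proteins}
    rows = []
    variants: dict[tuple[str, str], Counter] = {}
    clade_ids = []
    for clade in assignment.clades:
        members = [by_id[m] for m in clade.members if m in by_id]
        if not members:
            if warn is not None:
                warn(f"clade {clade.clade_id} has no members with sequences; excluded")
            continue
        missing = [m for m in clade.members if m not in by_id]
        if missing:
            raise ValueError(
                f"clade {clade.clade_id}: no sequence for members {missing}"
            )
        clade_ids.append(clade.clade_id)
        row = []
        for pat in patterns:
            carriers = 0
            var = Counter()
            for rec in members:
                hits = scan_sequence(pat, rec)
                if hits:
                    carriers += 1
                    var[hits[0].matched] += 1
            row.append(carriers / len(members))
            variants[(clade.clade_id, pat.name)] = var
        rows.append(row)
    fractions = pd.DataFrame(
        rows, index=clade_ids, columns=[p.name for p in patterns]
    )
    return ConservationTable(
        fractions=fractions,
        conserved=fractions >= threshold,
        variants=variants,
        threshold=threshold,
    )


def position_frequency_matrix(
    msa: MSA, columns: tuple[int, int] | None = None
) -> pd.DataFrame:
    """Per-column residue frequencies among ungapped rows.

    Returns a (columns x residues) table with an extra ``gap_fraction``
    column; rows of an all-gap column are NaN and listed in the frame's
    ``attrs['all_gap_columns']``.
    """
    arr = msa.to_array()
    lo, hi = (0, msa.n_cols) if columns is None else columns
    if not (0 <= lo < hi <= msa.n_cols):
        raise ValueError(f"column interval {columns} outside alignment")
    records = []
    all_gap = []
    for k in range(lo, hi):
        col = arr[:, k]
        residues = col[col != "-"]
        gap_fraction = 1.0 - len(residues) / len(col)
        if len(residues) == 0:
            freqs = {aa: np.nan for aa in AMINO_ACIDS}
            all_gap.append(k)
        else:
            counts = Counter(residues)
            freqs = {aa: counts.get(aa, 0) / len(residues) for aa in AMINO_ACIDS}
        freqs["gap_fraction"] = gap_fraction
        records.append(freqs)
    out = pd.DataFrame(records, index=range(lo, hi))
    out.attrs["all_gap_columns"] = all_gap
    return out


def read_motif_table(path: str | Path) -> list[MotifPattern]:
    """Motif definitions TSV: columns name, pattern, region_hint (optional)."""
    patterns = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"name", "pattern"}.issubset(reader.fieldnames):
            raise ValueError(f"motif table {path} needs columns name, pattern")
        for row in reader:
            hint = row.get("region_hint") or None
            patterns.append(
                parse_motif(row["pattern"], name=row["name"], region_hint=int(hint) if hint else None)
            )
    if not patterns:
        raise ValueError(f"no motifs in {path}")
    return patterns


def write_hits_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "pattern", "start", "matched"])
        for h in hits:
            writer.writerow([h.protein_id, h.pattern, h.start, h.matched])


# The three substrate-specificity motifs recoverable from the family
# literature; the broader signature catalogue is user-editable input, not
# hard-coded truth.
DEFAULT_MOTIFS = (
    ("GGxxxGxD", 1),  # triple-glycine motif, first TMH
    ("QQLxG", 7),     # glucose-binding site, seventh TMH
    ("YYxP/T", 7),    # glucose/xylose specificity, seventh TMH
)


def default_motifs() -> list[MotifPattern]:
    return [parse_motif(text, region_hint=hint) for text, hint in DEFAULT_MOTIFS]
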