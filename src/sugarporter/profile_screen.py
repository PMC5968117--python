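"""Profile-based screening of a proteome for sugar porter candidates.

A position-specific log-odds profile is built from a trusted alignment of
characterized transporters, every proteome sequence is scored with an
affine-gap local (Smith-Waterman style) profile alignment, and the
acceptance cutoff is calibrated as the lowest score achieved by any
characterized transporter -- so the screen, by construction, keeps every
known positive.

Scores are in log2 (bits-like) units.  An adapter for externally produced
hmmsearch ``--tblout`` tables is provided for users who prefer a full
profile-HMM search upstream; the calibration and screening logic is
identical either way.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import AA_INDEX, AMINO_ACIDS, MSA, ProteinRecord

# Robinson & Robinson (1991) amino-acid background frequencies, the standard
# null model for protein profile scoring; normalized to sum exactly to 1.
_RR = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}
ROBINSON_ROBINSON = np.array([_RR[aa] for aa in AMINO_ACIDS])
ROBINSON_ROBINSON = ROBINSON_ROBINSON / ROBINSON_ROBINSON.sum()

DEFAULT_GAP_OPEN = -11.0
DEFAULT_GAP_EXTEND = -1.0
DEFAULT_PSEUDOCOUNT = 1.0
# Alignment columns with more gaps than this become insert states and are
# dropped from the profile.
DEFAULT_MATCH_COLUMN_MAX_GAP = 0.5


@dataclass
class ProfileModel:
    """Position-specific log-odds scores over the 20 amino acids.

    ``log_odds[k, a]`` is log2 of the ratio between the (pseudocounted)
    observed frequency of residue ``a`` in match column ``k`` and the
    background frequency of ``a``.  A column whose observed frequencies
    equal the background therefore scores 0 everywhere (up to the
    pseudocount).
    """

    log_odds: np.ndarray  # (length, 20)
    background: np.ndarray  # (20,)
    pseudocount: float
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    match_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != len(AMINO_ACIDS):
            raise ValueError("log_odds must be (length, 20)")
        if self.length < 1:
            raise ValueError("profile must have at least one match column")
        if np.any(self.background <= 0) or abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must be positive and sum to 1")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be nonpositive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    def consensus(self) -> str:
        """Highest-scoring residue per column."""
        return "".join(AMINO_ACIDS[i] for i in self.log_odds.argmax(axis=1))


@dataclass(frozen=True)
class DomainScore:
    """Best local profile match on one protein.

    ``segment`` is the half-open 0-based interval of the matched stretch on
    the protein; an empty match scores 0 with an empty segment.
    """

    protein_id: str
    score: float
    segment: tuple[int, int]


@dataclass(frozen=True)
class CutoffCalibration:
    """Screening cutoff set to the minimum score among known positives."""

    cutoff: float
    known_scores: dict[str, float]
    argmin_id: str


def build_profile(
    alignment: MSA,
    background: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    max_gap_fraction: float = DEFAULT_MATCH_COLUMN_MAX_GAP,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> ProfileModel:
    """Build a log-odds profile from an alignment of known transporters.

    Per retained (match) column the score of residue ``a`` is

        log2( ((count_a + pseudocount * bg_a) / (n + pseudocount)) / bg_a )

    where ``n`` is the number of unambiguous residues observed in the
    column.  Columns whose gap fraction exceeds ``max_gap_fraction`` are
    treated as insert states and excluded; 'X' residues are ignored when
    counting.
    """
    if background is None:
        background = ROBINSON_ROBINSON
    background = np.asarray(background, dtype=float)
    if background.shape != (len(AMINO_ACIDS),) or abs(background.sum() - 1) > 1e-9:
        raise ValueError("background must be a 20-vector summing to 1")
    arr = alignment.to_array()
    gap_frac = (arr == "-").mean(axis=0)
    match_cols = [k for k in range(arr.shape[1]) if gap_frac[k] <= max_gap_fraction]
    if not match_cols:
        raise ValueError("no match columns: alignment is all gaps")
    rows = []
    for k in match_cols:
        col = arr[:, k]
        counts = np.zeros(len(AMINO_ACIDS))
        for ch in col:
            if ch == "-" or ch == "X":
                continue
            if ch not in AA_INDEX:
                raise ValueError(f"unknown residue {ch!r} in alignment column {k}")
            counts[AA_INDEX[ch]] += 1
        n = counts.sum()
        freq = (counts + pseudocount * background) / (n + pseudocount)
        rows.append(np.log2(freq / background))
    return ProfileModel(
        log_odds=np.array(rows),
        background=background,
        pseudocount=pseudocount,
        gap_open=gap_open,
        gap_extend=gap_extend,
        match_columns=match_cols,
    )


def _encode(sequence: str) -> np.ndarray:
    """Map a protein sequence to column indices; 'X' -> -1 (scores 0)."""
    idx = np.empty(len(sequence), dtype=np.int64)
    for j, ch in enumerate(sequence):
        if ch == "X":
            idx[j] = -1
        else:
            try:
                idx[j] = AA_INDEX[ch]
            except KeyError:
                raise ValueError(f"invalid residue {ch!r} in sequence") from None
    return idx


def _forward(sub: np.ndarray, go: float, ge: float) -> tuple[float, int, int]:
    """Local three-state DP over a (columns x positions) score matrix.

    States per cell (k, j): M (column k aligned to residue j), D (column k
    deleted, gap in the sequence) and I (residue j inserted, gap in the
    profile).  A gap run of length g costs ``go + (g-1)*ge``; deletion and
    insertion runs may not be adjacent.  Alignments start and end in M, and
    the score is floored at 0.  Returns (best score, k_end, j_end); the
    column loop runs over sequence positions with all per-column work
    vectorized (the D scan is a max-plus prefix scan).
    """
    L, N = sub.shape
    NEG = -np.inf
    rows = np.arange(L, dtype=float)
    best = 0.0
    best_k = best_j = -1
    prev_M = np.full(L, NEG)
    prev_D = np.full(L, NEG)
    prev_I = np.full(L, NEG)
    for j in range(N):
        if j == 0:
            i_state = np.full(L, NEG)
            m = sub[:, 0].copy()
        else:
            i_state = np.maximum(prev_M + go, prev_I + ge)
            b = np.maximum(np.maximum(prev_M, prev_D), prev_I)
            b = np.maximum(b, 0.0)
            m = sub[:, j].copy()
            m[1:] += b[:-1]
        # D[k] = max_{g>=1} m[k-g] + go + (g-1)*ge, via prefix scan
        d = np.full(L, NEG)
        if L > 1:
            run = np.maximum.accumulate(m - rows * ge)
            d[1:] = go + (rows[1:] - 1.0) * ge + run[:-1]
        jbest = int(np.argmax(m))
        if m[jbest] > best:
            best, best_k, best_j = float(m[jbest]), jbest, j
        prev_M, prev_D, prev_I = m, d, i_state
    return best, best_k, best_j


def score_protein(profile: ProfileModel, protein: ProteinRecord) -> DomainScore:
    """Best local alignment of the profile to a protein, affine gaps.

    Smith-Waterman over profile columns x sequence positions; a protein
    with no positive-scoring segment scores exactly 0 with an empty
    segment.  The reported segment is a best-scoring local match on the
    protein (half-open, 0-based); when several segments tie, one of them
    is returned.
    """
    seq_idx = _encode(protein.sequence)
    # per (column, sequence position) substitution scores; 'X' scores 0
    sub = np.where(
        seq_idx[None, :] >= 0, profile.log_odds[:, np.clip(seq_idx, 0, None)], 0.0
    )
    go, ge = profile.gap_open, profile.gap_extend
    best, k_end, j_end = _forward(sub, go, ge)
    if best <= 0:
        return DomainScore(protein_id=protein.id, score=0.0, segment=(0, 0))
    # locate the match start by running the same DP on the reversed slab
    # ending at the winning cell; its end cell is the start of an optimal
    # segment in original coordinates.
    rev = sub[k_end::-1, j_end::-1]
    _, _, rj_end = _forward(rev, go, ge)
    j_start = j_end - rj_end
    return DomainScore(protein_id=protein.id, score=best, segment=(j_start, j_end + 1))


def calibrate_cutoff(known_scores: Mapping[str, float]) -> CutoffCalibration:
    """Cutoff = lowest score among the known transporters.

    Ties at the minimum are broken by lexicographic id so the calibration
    report is deterministic.
    """
    if not known_scores:
        raise ValueError("cannot calibrate a cutoff from an empty score map")
    argmin_id = min(sorted(known_scores), key=lambda k: known_scores[k])
    return CutoffCalibration(
        cutoff=float(known_scores[argmin_id]),
        known_scores={k: float(v) for k, v in known_scores.items()},
        argmin_id=argmin_id,
    )


def screen_proteome(
    proteome: Iterable[ProteinRecord],
    profile: ProfileModel,
    cutoff: float,
) -> list[DomainScore]:
    """Score every protein and keep those with score >= cutoff.

    The comparison is inclusive, so a calibration set screened against its
    own calibrated cutoff is always fully retained.  Results are sorted by
    descending score, ties broken by id.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    hits = [score_protein(profile, rec) for rec in proteome]
    kept = [h for h in hits if h.score >= cutoff]
    return sorted(kept, key=lambda h: (-h.score, h.protein_id))


def parse_search_table(path: str | Path) -> dict[str, float]:
    """Parse an hmmsearch ``--tblout`` per-target table.

    Returns target id -> best full-sequence score (column 6).  Duplicate
    targets keep the maximum score.  Malformed data lines are collected and
    reported with their line numbers.
    """
    scores: dict[str, float] = {}
    bad: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                bad.append(f"line {lineno}: expected >=6 columns")
                continue
            target = fields[0]
            try:
                score = float(fields[5])
            except ValueError:
                bad.append(f"line {lineno}: non-numeric score {fields[5]!r}")
                continue
            if target not in scores or score > scores[target]:
                scores[target] = score
    if bad:
        raise ValueError("malformed hmmsearch table: " + "; ".join(bad))
    if not scores:
        raise ValueError(f"no data rows in {path}")
    return scores


def write_candidates_tsv(hits: Sequence[DomainScore], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "score", "segment_start", "segment_end"])
        for h in hits:
            writer.writerow([h.protein_id, f"{h.score:.4f}", h.segment[0], h.segment[1]])
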