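"""Independent brute-force oracles used by the tests.

These deliberately share no code with the implementation: the profile
aligner is checked against exhaustive enumeration of alignment paths, and
the motif scanner against a naive sliding-window matcher.
"""

from __future__ import annotations

import numpy as np

from sugarporter.seqio import AA_INDEX


def brute_force_local_score(
    log_odds: np.ndarray, sequence: str, gap_open: float, gap_extend: float
) -> float:
    """Best local profile-to-sequence alignment score by enumeration.

    Alignments are operation strings over M (match column/residue), D
    (column deleted) and I (residue inserted); they start and end with M,
    a gap run of length g costs ``gap_open + (g-1)*gap_extend``, and D and
    I runs are never adjacent.  'X' residues score 0 in every column.
    Exponential in the input size -- only for profiles of length <= 5 and
    sequences of length <= 8.
    """
    L = log_odds.shape[0]
    idx = [AA_INDEX.get(ch, -1) for ch in sequence]
    N = len(idx)
    sub = np.zeros((L, N))
    for j, a in enumerate(idx):
        if a >= 0:
            sub[:, j] = log_odds[:, a]
    best = 0.0  # the empty alignment

    def extend(k: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if last == "M" and score > best:
            best = score
        if k + 1 < L and j + 1 < N:
            extend(k + 1, j + 1, score + sub[k + 1, j + 1], "M")
        if k + 1 < L and last != "I":
            extend(k + 1, j, score + (gap_extend if last == "D" else gap_open), "D")
        if j + 1 < N and last != "D":
            extend(k, j + 1, score + (gap_extend if last == "I" else gap_open), "I")

    for k in range(L):
        for j in range(N):
            extend(k, j, sub[k, j], "M")
    return best


def sliding_window_hits(tokens, sequence: str) -> list[int]:
    """All match start positions of a degenerate motif, naive scan.

    ``tokens`` is a list where None is the wildcard and anything else is an
    iterable of allowed residues.
    """
    m = len(tokens)
    out = []
    for start in range(len(sequence) - m + 1):
        window = sequence[start : start + m]
        if all(tok is None or ch in tok for tok, ch in zip(tokens, window)):
            out.append(start)
    return out
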