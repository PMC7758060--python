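"""Affine-gap pairwise and profile-to-sequence alignment.

Implements Smith–Waterman (local) and Needleman–Wunsch (global, end gaps
penalized) alignment with affine gap costs: a gap of length L costs
``gap_open + L * gap_extend``.  A position-specific score table can stand
in for the first sequence (:func:`profile_align_local`), which is how
theme profiles are scanned against domain sequences.

Defaults are BLOSUM62 with gap_open 11 / gap_extend 1, the community
standard for protein local alignment.  Traceback is deterministic:
diagonal beats up beats left on score ties, and the local alignment ends
at the first best-scoring cell in row-major order, so results are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices

from ._alphabet import ALPHABET, ALPHABET_SIZE, encode
from . import _kernels

GAP_OPEN_DEFAULT = 11.0
GAP_EXTEND_DEFAULT = 1.0


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric residue substitution scores over the package alphabet."""

    alphabet: str
    scores: np.ndarray  # (A, A) float64

    def __post_init__(self):
        s = self.scores
        if s.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError("score table shape does not match alphabet")
        if not np.allclose(s, s.T):
            raise ValueError("substitution matrix must be symmetric")


@lru_cache(maxsize=1)
def blosum62() -> SubstitutionMatrix:
    """BLOSUM62 over the package alphabet; 'X' scores the matrix minimum."""
    raw = substitution_matrices.load("BLOSUM62")
    scores = np.zeros((ALPHABET_SIZE, ALPHABET_SIZE))
    lo = float(min(raw[a, b] for a in "ACDEFGHIKLMNPQRSTVWY"
                   for b in "ACDEFGHIKLMNPQRSTVWY"))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            if a == "X" or b == "X":
                scores[i, j] = lo
            else:
                scores[i, j] = float(raw[a, b])
    return SubstitutionMatrix(ALPHABET, scores)


@dataclass(frozen=True)
class AlignmentResult:
    """One pairwise (or profile-sequence) alignment.

    Intervals are 0-based half-open on the respective inputs.
    ``aligned_pairs`` lists (a_index, b_index) tuples; a gap is marked by
    -1 on the gapped side.  ``identity`` is matches / aligned (non-gap)
    columns, 0.0 for an empty alignment.
    """

    mode: str  # "local" | "global"
    score: float
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    aligned_pairs: tuple[tuple[int, int], ...]
    identity: float

    @property
    def a_length(self) -> int:
        return self.a_interval[1] - self.a_interval[0]

    @property
    def b_length(self) -> int:
        return self.b_interval[1] - self.b_interval[0]


def _traceback(end_i, end_j, end_state, pm, px, py, local):
    pairs = []
    i, j, state = end_i, end_j, end_state
    while True:
        if state == 1:
            nxt = pm[i, j]
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
            if local and nxt == 0:
                break
            state = nxt
        elif state == 2:
            nxt = px[i, j]
            pairs.append((i - 1, -1))
            i -= 1
            state = nxt
        elif state == 3:
            nxt = py[i, j]
            pairs.append((-1, j - 1))
            j -= 1
            state = nxt
        else:  # pragma: no cover - defensive
            break
        if not local and i == 0 and j == 0:
            break
    pairs.reverse()
    return pairs


def _finish(prof, b_codes, score, end_i, end_j, end_state, pm, px, py,
            local, a_codes: Optional[np.ndarray], profile_consensus=None):
    mode = "local" if local else "global"
    if local and score <= 0.0 and end_state == 0:
        return AlignmentResult(mode, 0.0, (0, 0), (0, 0), (), 0.0)
    pairs = _traceback(end_i, end_j, end_state, pm, px, py, local)
    a_idx = [p[0] for p in pairs if p[0] >= 0]
    b_idx = [p[1] for p in pairs if p[1] >= 0]
    a_iv = (min(a_idx), max(a_idx) + 1) if a_idx else (0, 0)
    b_iv = (min(b_idx), max(b_idx) + 1) if b_idx else (0, 0)
    both = [(i, j) for i, j in pairs if i >= 0 and j >= 0]
    if both:
        if a_codes is not None:
            matches = sum(1 for i, j in both if a_codes[i] == b_codes[j])
        else:
            matches = sum(1 for i, j in both if profile_consensus[i] == b_codes[j])
        identity = matches / len(both)
    else:
        identity = 0.0
    return AlignmentResult(mode, float(score), a_iv, b_iv, tuple(pairs), identity)


def _seq_profile(codes: np.ndarray, m: SubstitutionMatrix) -> np.ndarray:
    return np.ascontiguousarray(m.scores[codes.astype(np.intp), :])


def smith_waterman(a: str, b: str, m: Optional[SubstitutionMatrix] = None,
                   gap_open: float = GAP_OPEN_DEFAULT,
                   gap_extend: float = GAP_EXTEND_DEFAULT) -> AlignmentResult:
    """Optimal affine-gap local alignment of two residue-strings.

    Empty input yields the empty alignment with score 0.
    """
    m = m or blosum62()
    if not a or not b:
        return AlignmentResult("local", 0.0, (0, 0), (0, 0), (), 0.0)
    ac, bc = encode(a), encode(b)
    prof = _seq_profile(ac, m)
    res = _kernels.affine_dp(prof, bc, float(gap_open), float(gap_extend), True)
    return _finish(prof, bc, *res, True, ac)


def needleman_wunsch(a: str, b: str, m: Optional[SubstitutionMatrix] = None,
                     gap_open: float = GAP_OPEN_DEFAULT,
                     gap_extend: float = GAP_EXTEND_DEFAULT) -> AlignmentResult:
    """Optimal affine-gap global alignment; end gaps are penalized."""
    if not a or not b:
        raise ValueError("global alignment requires two non-empty sequences")
    m = m or blosum62()
    ac, bc = encode(a), encode(b)
    prof = _seq_profile(ac, m)
    res = _kernels.affine_dp(prof, bc, float(gap_open), float(gap_extend), False)
    return _finish(prof, bc, *res, False, ac)


def profile_align_local(p: np.ndarray, b: str,
                        gap_open: float = GAP_OPEN_DEFAULT,
                        gap_extend: float = GAP_EXTEND_DEFAULT) -> AlignmentResult:
    """Local alignment of a position-score table against a residue-string.

    Column i of ``p`` (shape width x alphabet) scores residue b[j] by
    table lookup; gaps behave exactly as in :func:`smith_waterman`.
    Identity is measured against each column's best-scoring residue.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] == 0:
        raise ValueError("profile must be a non-empty 2-D table")
    if p.shape[1] != ALPHABET_SIZE:
        raise ValueError(f"profile width {p.shape[1]} != alphabet size {ALPHABET_SIZE}")
    if not b:
        return AlignmentResult("local", 0.0, (0, 0), (0, 0), (), 0.0)
    bc = encode(b)
    prof = np.ascontiguousarray(p)
    res = _kernels.affine_dp(prof, bc, float(gap_open), float(gap_extend), True)
    consensus = np.argmax(prof, axis=1)
    return _finish(prof, bc, *res, True, None, profile_consensus=consensus)
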