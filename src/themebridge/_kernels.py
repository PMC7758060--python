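"""Numba kernels for affine-gap dynamic programming.

All kernels work on a position-score table ``prof`` of shape (n, A): row i
gives the score of placing position i of sequence/profile "a" against each
alphabet symbol.  A plain sequence is the degenerate profile obtained by
indexing the substitution matrix with its codes, so one set of kernels
serves both sequence-sequence and profile-sequence alignment.

Gap model: a gap of length L costs gap_open + L*gap_extend.  Direct
switches between a-gaps and b-gaps are allowed; each switch opens a new
gap (pays gap_open + gap_extend).

Traceback is deterministic: on ties the diagonal (match) state wins over
the a-gap ("up") state, which wins over the b-gap ("left") state; the
local endpoint is the best-scoring cell first reached in row-major order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30

# pointer codes: 0 = alignment start, 1 = from M, 2 = from Ix (up), 3 = from Iy (left)


@njit(cache=True)
def affine_dp(prof, b, gap_open, gap_ext, local):
    """Full DP with traceback pointers.

    Returns (score, end_i, end_j, end_state, pm, px, py) where end_i/end_j
    are 1-based cell indices of the alignment end and end_state is 1/2/3.
    """
    n = prof.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    pm = np.zeros((n + 1, m + 1), dtype=np.uint8)
    px = np.zeros((n + 1, m + 1), dtype=np.uint8)
    py = np.zeros((n + 1, m + 1), dtype=np.uint8)

    if not local:
        M[0, 0] = 0.0
        for i in range(1, n + 1):
            Ix[i, 0] = -(gap_open + gap_ext * i)
            px[i, 0] = 1 if i == 1 else 2
        for j in range(1, m + 1):
            Iy[0, j] = -(gap_open + gap_ext * j)
            py[0, j] = 1 if j == 1 else 3

    best = 0.0
    best_i = 0
    best_j = 0
    best_state = 0

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = prof[i - 1, b[j - 1]]
            # M: diagonal predecessor among states, optionally fresh start
            d = M[i - 1, j - 1]
            st = 1
            if Ix[i - 1, j - 1] > d:
                d = Ix[i - 1, j - 1]
                st = 2
            if Iy[i - 1, j - 1] > d:
                d = Iy[i - 1, j - 1]
                st = 3
            if local and d < 0.0:
                d = 0.0
                st = 0
            M[i, j] = d + s
            pm[i, j] = st

            # Ix: gap in b (consume a_i)
            v = M[i - 1, j] - gap_open - gap_ext
            st = 1
            if Ix[i - 1, j] - gap_ext > v:
                v = Ix[i - 1, j] - gap_ext
                st = 2
            if Iy[i - 1, j] - gap_open - gap_ext > v:
                v = Iy[i - 1, j] - gap_open - gap_ext
                st = 3
            Ix[i, j] = v
            px[i, j] = st

            # Iy: gap in a (consume b_j)
            v = M[i, j - 1] - gap_open - gap_ext
            st = 1
            if Ix[i, j - 1] - gap_open - gap_ext > v:
                v = Ix[i, j - 1] - gap_open - gap_ext
                st = 2
            if Iy[i, j - 1] - gap_ext > v:
                v = Iy[i, j - 1] - gap_ext
                st = 3
            Iy[i, j] = v
            py[i, j] = st

            if local and M[i, j] > best:
                best = M[i, j]
                best_i = i
                best_j = j
                best_state = 1

    if not local:
        best = M[n, m]
        best_state = 1
        if Ix[n, m] > best:
            best = Ix[n, m]
            best_state = 2
        if Iy[n, m] > best:
            best = Iy[n, m]
            best_state = 3
        best_i = n
        best_j = m

    return best, best_i, best_j, best_state, pm, px, py


@njit(cache=True)
def local_score(prof, b, gap_open, gap_ext):
    """Score-only local DP with rolling rows (used for null-score sampling)."""
    n = prof.shape[0]
    m = b.shape[0]
    M0 = np.full(m + 1, NEG)
    X0 = np.full(m + 1, NEG)
    Y0 = np.full(m + 1, NEG)
    M1 = np.full(m + 1, NEG)
    X1 = np.full(m + 1, NEG)
    Y1 = np.full(m + 1, NEG)
    best = 0.0
    for i in range(1, n + 1):
        M1[0] = NEG
        X1[0] = NEG
        Y1[0] = NEG
        for j in range(1, m + 1):
            s = prof[i - 1, b[j - 1]]
            d = M0[j - 1]
            if X0[j - 1] > d:
                d = X0[j - 1]
            if Y0[j - 1] > d:
                d = Y0[j - 1]
            if d < 0.0:
                d = 0.0
            M1[j] = d + s
            v = M0[j] - gap_open - gap_ext
            if X0[j] - gap_ext > v:
                v = X0[j] - gap_ext
            if Y0[j] - gap_open - gap_ext > v:
                v = Y0[j] - gap_open - gap_ext
            X1[j] = v
            v = M1[j - 1] - gap_open - gap_ext
            if X1[j - 1] - gap_open - gap_ext > v:
                v = X1[j - 1] - gap_open - gap_ext
            if Y1[j - 1] - gap_ext > v:
                v = Y1[j - 1] - gap_ext
            Y1[j] = v
            if M1[j] > best:
                best = M1[j]
        M0, M1 = M1, M0
        X0, X1 = X1, X0
        Y0, Y1 = Y1, Y0
    return best


@njit(cache=True)
def global_score(prof, b, gap_open, gap_ext):
    """Score-only global (end-gap penalized) DP with rolling rows."""
    n = prof.shape[0]
    m = b.shape[0]
    M0 = np.full(m + 1, NEG)
    X0 = np.full(m + 1, NEG)
    Y0 = np.full(m + 1, NEG)
    M1 = np.full(m + 1, NEG)
    X1 = np.full(m + 1, NEG)
    Y1 = np.full(m + 1, NEG)
    M0[0] = 0.0
    for j in range(1, m + 1):
        Y0[j] = -(gap_open + gap_ext * j)
    for i in range(1, n + 1):
        M1[0] = NEG
        X1[0] = -(gap_open + gap_ext * i)
        Y1[0] = NEG
        for j in range(1, m + 1):
            s = prof[i - 1, b[j - 1]]
            d = M0[j - 1]
            if X0[j - 1] > d:
                d = X0[j - 1]
            if Y0[j - 1] > d:
                d = Y0[j - 1]
            M1[j] = d + s
            v = M0[j] - gap_open - gap_ext
            if X0[j] - gap_ext > v:
                v = X0[j] - gap_ext
            if Y0[j] - gap_open - gap_ext > v:
                v = Y0[j] - gap_open - gap_ext
            X1[j] = v
            v = M1[j - 1] - gap_open - gap_ext
            if X1[j - 1] - gap_open - gap_ext > v:
                v = X1[j - 1] - gap_open - gap_ext
            if Y1[j - 1] - gap_ext > v:
                v = Y1[j - 1] - gap_ext
            Y1[j] = v
        M0, M1 = M1, M0
        X0, X1 = X1, X0
        Y0, Y1 = Y1, Y0
    best = M0[m]
    if X0[m] > best:
        best = X0[m]
    if Y0[m] > best:
        best = Y0[m]
    return best


@njit(cache=True)
def batch_scores(prof, segs, gap_open, gap_ext, local):
    """Alignment scores of one profile against each row of an int8 matrix."""
    out = np.empty(segs.shape[0])
    for k in range(segs.shape[0]):
        if local:
            out[k] = local_score(prof, segs[k], gap_open, gap_ext)
        else:
            out[k] = global_score(prof, segs[k], gap_open, gap_ext)
    return out
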