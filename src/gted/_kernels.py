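"""Numba kernels for affine-gap local alignment (Gotoh recurrences).

Gap convention: a gap of length k costs gap_open + (k-1) * gap_extend
(the first gapped base pays the open penalty).  Code 4 (N) never scores
as a match.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(1 << 28))


@njit(cache=True)
def local_dp_matrix(q, t, match, mismatch, gap_open, gap_extend):
    """Full H matrix of local alignment between encoded q and t."""
    m = q.shape[0]
    n = t.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    # F[j]: best alignment ending at (i, j) with a gap in the target
    # (consuming query bases); rolls across rows.  E rolls within a row.
    F = np.empty(n + 1, dtype=np.int32)
    for j in range(n + 1):
        F[j] = NEG
    for i in range(1, m + 1):
        qi = q[i - 1]
        e = NEG  # gap in query (consumes target bases)
        for j in range(1, n + 1):
            tj = t[j - 1]
            if qi == tj and qi < 4:
                s = match
            else:
                s = mismatch
            eo = H[i, j - 1] + gap_open
            e = e + gap_extend
            if eo > e:
                e = eo
            fo = H[i - 1, j] + gap_open
            fj = F[j] + gap_extend
            if fo > fj:
                fj = fo
            F[j] = fj
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if fj > h:
                h = fj
            if h < 0:
                h = 0
            H[i, j] = h
    return H


@njit(cache=True)
def _argmax_h(H):
    best = np.int32(0)
    bi = 0
    bj = 0
    m = H.shape[0]
    n = H.shape[1]
    for i in range(m):
        for j in range(n):
            if H[i, j] > best:
                best = H[i, j]
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def local_align_ends(q, t, match, mismatch, gap_open, gap_extend):
    """Best local alignment: (score, q_start, q_end, t_start, t_end).

    End cell is the first-encountered argmax of H (row-major); the start
    is recovered by running the same DP on the reversed prefixes, a
    standard trick that avoids traceback storage.  Among co-optimal
    starts, the shortest alignment is chosen.
    """
    H = local_dp_matrix(q, t, match, mismatch, gap_open, gap_extend)
    best, bi, bj = _argmax_h(H)
    if best <= 0:
        return 0, 0, 0, 0, 0
    qr = q[:bi][::-1].copy()
    tr = t[:bj][::-1].copy()
    Hr = local_dp_matrix(qr, tr, match, mismatch, gap_open, gap_extend)
    rbest, ri, rj = _argmax_h(Hr)
    return int(best), bi - ri, bi, bj - rj, bj


@njit(cache=True)
def second_best_distinct(H, bj, min_sep):
    """Max H over columns farther than min_sep from bj (distinct locus)."""
    best = np.int32(0)
    m = H.shape[0]
    n = H.shape[1]
    for j in range(n):
        d = j - bj
        if d < 0:
            d = -d
        if d <= min_sep:
            continue
        for i in range(m):
            if H[i, j] > best:
                best = H[i, j]
    return int(best)
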