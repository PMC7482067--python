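"""Shared local-alignment engine (Gotoh affine-gap dynamic programming).

All three alignment flavours in the pipeline — protein Smith-Waterman against
a substitution matrix, PSSM profile scanning, and nucleotide matching against
a genome window — reduce to the same recurrence over a precomputed cell-score
matrix ``S`` where ``S[i, j]`` scores pairing query position ``i`` with target
position ``j``. The inner loop is numba-compiled; traceback runs in Python and
reports the aligned spans and per-column operations.

Gap convention: a gap of length L costs ``gap_open + gap_extend * L`` (BLAST
existence/extension convention, so "11/1" means a 1-residue gap costs 12).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from numba import njit

_NEG = -1e30


@njit(cache=False)
def _gotoh_local(S, gap_open, gap_extend):  # pragma: no cover - numba kernel
    m, n = S.shape
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), _NEG)
    F = np.full((m + 1, n + 1), _NEG)
    ptrH = np.zeros((m + 1, n + 1), np.int8)  # 0 stop, 1 diag, 2 E, 3 F
    ptrE = np.zeros((m + 1, n + 1), np.int8)  # 0 open, 1 extend
    ptrF = np.zeros((m + 1, n + 1), np.int8)
    best = 0.0
    bi = 0
    bj = 0
    first_cost = gap_open + gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - first_cost
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            f_open = H[i - 1, j] - first_cost
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            h = 0.0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptrH, ptrE, ptrF


class LocalAlignment(NamedTuple):
    score: float
    q_start: int  # 0-based half-open span on the query
    q_end: int
    t_start: int  # span on the target
    t_end: int
    ops: list  # list of ('M'|'I'|'D', qi, tj); I consumes query, D target


def align_local(S: np.ndarray, gap_open: float,
                gap_extend: float) -> LocalAlignment:
    """Best local alignment over cell-score matrix ``S`` with affine gaps.

    Returns a zero-score empty alignment when no positive-scoring cell exists.
    """
    if S.size == 0:
        return LocalAlignment(0.0, 0, 0, 0, 0, [])
    best, bi, bj, ptrH, ptrE, ptrF = _gotoh_local(
        np.ascontiguousarray(S, dtype=np.float64),
        float(gap_open), float(gap_extend))
    if best <= 0.0:
        return LocalAlignment(0.0, 0, 0, 0, 0, [])
    ops: list[tuple[str, int, int]] = []
    i, j = bi, bj
    state = 0  # 0 = H
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                ops.append(("M", i - 1, j - 1))
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:  # E: gap in query, consumes target
            ext = ptrE[i, j]
            ops.append(("D", i, j - 1))
            j -= 1
            if ext == 0:
                state = 0
        else:  # F: gap in target, consumes query
            ext = ptrF[i, j]
            ops.append(("I", i - 1, j))
            i -= 1
            if ext == 0:
                state = 0
    ops.reverse()
    return LocalAlignment(float(best), i, bi, j, bj, ops)
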