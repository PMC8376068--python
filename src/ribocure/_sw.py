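"""Numba kernel for exact affine-gap Smith-Waterman with traceback.

Gap of length k costs gap_open + k * gap_extend. Base code 4 is N and never
scores as a match. The best cell is chosen deterministically: highest score,
then smallest query end, then smallest reference end; traceback prefers
diagonal moves, giving one well-defined alignment among co-optimal ones.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = np.int32(-(10**9) // 2)

# pointer codes for the H matrix
_STOP = 0
_DIAG = 1
_FROM_E = 2
_FROM_F = 3


# column op codes (in the returned path)
OP_MATCH = 0
OP_MISMATCH = 1
OP_INS = 2  # gap in reference, consumes query
OP_DEL = 3  # gap in query, consumes reference


@njit(cache=True)
def sw_align(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover - numba
    """Return (score, q_start, q_end, r_start, r_end, matches, columns, path).

    q, r: uint8 code arrays (A=0 C=1 G=2 T=3 N=4). ``path`` holds one op
    code per alignment column in traceback order (alignment end -> start).
    Returns score 0 with empty spans when no positive-scoring local
    alignment exists.
    """
    n = q.shape[0]
    m = r.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG_INF, np.int32)  # gap in query (consumes ref)
    F = np.full((n + 1, m + 1), NEG_INF, np.int32)  # gap in ref (consumes query)
    ptrH = np.zeros((n + 1, m + 1), np.uint8)
    ptrE = np.zeros((n + 1, m + 1), np.uint8)  # 1 = extend from E, 0 = open from H
    ptrF = np.zeros((n + 1, m + 1), np.uint8)

    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[i, j - 1] - gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_open
                ptrE[i, j] = 0

            f_open = H[i - 1, j] - gap_open - gap_extend
            f_ext = F[i - 1, j] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
                ptrF[i, j] = 0

            rj = r[j - 1]
            if qi == rj and qi < 4:
                diag = H[i - 1, j - 1] + match
            else:
                diag = H[i - 1, j - 1] - mismatch

            h = np.int32(0)
            p = _STOP
            if diag > h:
                h = diag
                p = _DIAG
            if E[i, j] > h:
                h = E[i, j]
                p = _FROM_E
            if F[i, j] > h:
                h = F[i, j]
                p = _FROM_F
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j

    path = np.empty(n + m, np.uint8)
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0, path[:0]

    # traceback from (bi, bj), state H
    i = bi
    j = bj
    matches = 0
    columns = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == _STOP:
                break
            if p == _DIAG:
                if q[i - 1] == r[j - 1] and q[i - 1] < 4:
                    matches += 1
                    path[columns] = OP_MATCH
                else:
                    path[columns] = OP_MISMATCH
                columns += 1
                i -= 1
                j -= 1
            elif p == _FROM_E:
                state = 1
            else:
                state = 2
        elif state == 1:
            path[columns] = OP_DEL
            columns += 1
            ext = ptrE[i, j]
            j -= 1
            if ext == 0:
                state = 0
        else:
            path[columns] = OP_INS
            columns += 1
            ext = ptrF[i, j]
            i -= 1
            if ext == 0:
                state = 0

    return int(best), i, bi, j, bj, matches, columns, path[:columns]
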