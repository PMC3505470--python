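"""Numba kernels for banded affine-gap sequence alignment.

One kernel serves three alignment flavours used across the package:

* ``local``   -- Smith-Waterman (scores floored at zero, best cell anywhere),
* ``overlap`` -- dovetail/containment alignment (free start on either
  sequence's first row/column, best cell on either last row/column),
* ``glocal``  -- first sequence aligned end-to-end against a window of the
  second (free start/end only on the second sequence).

The band is expressed in diagonals ``d = j - i`` with ``d in [lo, hi]``.
Scores are affine: a gap run of length L costs ``gap_open + L * gap_extend``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e18

# traceback op codes emitted by the kernel
OP_DIAG = 0   # consume one base of each sequence
OP_GAP_B = 1  # consume a only (gap in b)
OP_GAP_A = 2  # consume b only (gap in a)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def banded_align(a, b, lo, hi, match, mismatch, gap_open, gap_extend,
                 local, a_end_only, ops_buf):
    """Banded affine-gap DP with traceback.

    Returns ``(score, i0, j0, i1, j1, n_ops, n_ident)``; the alignment
    consumes ``a[i0:i1]`` and ``b[j0:j1]`` and its column operations are
    written *reversed* into ``ops_buf[:n_ops]``.
    """
    n = a.shape[0]
    m = b.shape[0]
    if lo < -n:
        lo = -n
    if hi > m:
        hi = m
    W = hi - lo + 1
    if W <= 0:
        return (NEG, 0, 0, 0, 0, 0, 0)

    H_prev = np.full(W, NEG)
    H_cur = np.full(W, NEG)
    E_cur = np.full(W, NEG)
    F_prev = np.full(W, NEG)
    F_cur = np.full(W, NEG)
    # bits 0-1: H source (0 start, 1 diag, 2 E, 3 F); bit 2: E extends; bit 3: F extends
    ptr = np.zeros((n + 1, W), dtype=np.uint8)

    best = NEG
    bi = -1
    bw = -1

    for i in range(0, n + 1):
        for w in range(W):
            H_cur[w] = NEG
            E_cur[w] = NEG
            F_cur[w] = NEG
        for w in range(W):
            j = i + lo + w
            if j < 0 or j > m:
                continue
            code = np.uint8(0)
            if i == 0 or j == 0:
                # free starts: always for local; for non-local modes the
                # first row/column of the full matrix is free.
                h = 0.0
                ptr[i, w] = 0
                H_cur[w] = h
            else:
                e = NEG
                eext = False
                if w - 1 >= 0:
                    eo = H_cur[w - 1] + gap_open + gap_extend
                    ee = E_cur[w - 1] + gap_extend
                    if ee > eo:
                        e = ee
                        eext = True
                    else:
                        e = eo
                f = NEG
                fext = False
                if w + 1 < W:
                    fo = H_prev[w + 1] + gap_open + gap_extend
                    fe = F_prev[w + 1] + gap_extend
                    if fe > fo:
                        f = fe
                        fext = True
                    else:
                        f = fo
                E_cur[w] = e
                F_cur[w] = f
                d = NEG
                if H_prev[w] > NEG / 2:
                    if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                        d = H_prev[w] + match
                    else:
                        d = H_prev[w] + mismatch
                h = d
                code = np.uint8(1)
                if e > h:
                    h = e
                    code = np.uint8(2)
                if f > h:
                    h = f
                    code = np.uint8(3)
                if local and h < 0.0:
                    h = 0.0
                    code = np.uint8(0)
                if h < NEG / 2:
                    code = np.uint8(0)
                if eext:
                    code |= np.uint8(4)
                if fext:
                    code |= np.uint8(8)
                ptr[i, w] = code
                H_cur[w] = h

            if h > NEG / 2:
                if local:
                    if h > best:
                        best = h
                        bi = i
                        bw = w
                else:
                    if i == n or ((not a_end_only) and j == m):
                        if h > best:
                            best = h
                            bi = i
                            bw = w
        tmp = H_prev
        H_prev = H_cur
        H_cur = tmp
        tmp = F_prev
        F_prev = F_cur
        F_cur = tmp

    if bi < 0:
        return (NEG, 0, 0, 0, 0, 0, 0)

    # traceback
    i = bi
    w = bw
    i1 = bi
    j1 = bi + lo + bw
    n_ops = 0
    n_ident = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        code = ptr[i, w]
        if state == 0:
            src = code & np.uint8(3)
            if src == 0:
                break
            if src == 1:
                j = i + lo + w
                ops_buf[n_ops] = OP_DIAG
                n_ops += 1
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    n_ident += 1
                i -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops_buf[n_ops] = OP_GAP_A
            n_ops += 1
            ext = (code & np.uint8(4)) != 0
            w -= 1
            if not ext:
                state = 0
        else:
            ops_buf[n_ops] = OP_GAP_B
            n_ops += 1
            ext = (code & np.uint8(8)) != 0
            i -= 1
            w += 1
            if not ext:
                state = 0
    i0 = i
    j0 = i + lo + w
    return (best, i0, j0, i1, j1, n_ops, n_ident)
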