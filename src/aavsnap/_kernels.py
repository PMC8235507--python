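"""Numba DP kernels for affine-gap local alignment.

Two kernels: a score-only full Smith–Waterman (linear memory) used to locate
the optimum when no seed information is available, and a banded affine local
DP with full traceback, parameterized by an inclusive diagonal range
``[dlo, dhi]`` where ``d = j - i`` (ref index minus query index). Running the
banded kernel with ``dlo = -(m-1)`` and ``dhi = n-1`` reproduces the full DP.

Gap scoring convention: the first gapped base scores ``gap_open`` and each
further base in the same run scores ``gap_extend``.
"""
from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(10 ** 9))


@njit(cache=True)
def sw_best(q, r, match, mismatch, gap_open, gap_extend):
    """Full local-alignment DP, returning (best score, end_i, end_j) only.

    Ties resolve to the first-encountered cell in row-major order, which makes
    the result deterministic.
    """
    m = q.size
    n = r.size
    Hp = np.zeros(n + 1, np.int32)
    Hc = np.zeros(n + 1, np.int32)
    F = np.full(n + 1, NEG, np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        e = NEG
        Hc[0] = 0
        qi = q[i - 1]
        for j in range(1, n + 1):
            a = Hc[j - 1] + gap_open
            b = e + gap_extend
            e = a if a >= b else b
            a = Hp[j] + gap_open
            b = F[j] + gap_extend
            f = a if a >= b else b
            F[j] = f
            s = match if (qi == r[j - 1] and qi < 4) else mismatch
            h = Hp[j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Hc[j] = h
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = Hp
        Hp = Hc
        Hc = tmp
    return best, bi, bj


@njit(cache=True)
def banded_affine_local(q, r, dlo, dhi, match, mismatch, gap_open, gap_extend):
    """Banded affine local DP with traceback.

    Returns (score, qend, rend, qstart, rstart, n_ops, ops) where ops holds the
    alignment path from END to START: 0 diagonal match, 1 diagonal mismatch,
    2 gap consuming reference, 3 gap consuming query.
    """
    m = q.size
    n = r.size
    W = dhi - dlo + 1
    H = np.zeros((m + 1, W), np.int32)
    E = np.full((m + 1, W), NEG, np.int32)
    F = np.full((m + 1, W), NEG, np.int32)
    hp = np.zeros((m + 1, W), np.uint8)
    ep = np.zeros((m + 1, W), np.uint8)
    fp = np.zeros((m + 1, W), np.uint8)
    best = np.int32(0)
    bi = 0
    bk = 0
    for i in range(m + 1):
        for kk in range(W):
            j = i + dlo + kk
            if j < 0 or j > n:
                continue
            if i == 0 or j == 0:
                continue  # H stays 0, E/F stay NEG
            # E: gap consuming reference, from (i, j-1) = band cell kk-1
            e = NEG
            if kk - 1 >= 0:
                a = H[i, kk - 1] + gap_open
                b = E[i, kk - 1] + gap_extend
                if a >= b:
                    e = a
                    ep[i, kk] = 0
                else:
                    e = b
                    ep[i, kk] = 1
            E[i, kk] = e
            # F: gap consuming query, from (i-1, j) = row i-1, band cell kk+1
            f = NEG
            if kk + 1 < W:
                a = H[i - 1, kk + 1] + gap_open
                b = F[i - 1, kk + 1] + gap_extend
                if a >= b:
                    f = a
                    fp[i, kk] = 0
                else:
                    f = b
                    fp[i, kk] = 1
            F[i, kk] = f
            qi = q[i - 1]
            s = match if (qi == r[j - 1] and qi < 4) else mismatch
            d = H[i - 1, kk] + s
            h = np.int32(0)
            ptr = np.uint8(0)
            if d > h:
                h = d
                ptr = 1
            if e > h:
                h = e
                ptr = 2
            if f > h:
                h = f
                ptr = 3
            H[i, kk] = h
            hp[i, kk] = ptr
            if h > best:
                best = h
                bi = i
                bk = kk
    # traceback (ops recorded end -> start)
    ops = np.empty(m + n + 2, np.uint8)
    t = 0
    i = bi
    kk = bk
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            ptr = hp[i, kk]
            if ptr == 0:
                break
            if ptr == 1:
                j = i + dlo + kk
                qi = q[i - 1]
                ops[t] = 0 if (qi == r[j - 1] and qi < 4) else 1
                t += 1
                i -= 1
            elif ptr == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[t] = 2
            t += 1
            frm = ep[i, kk]
            kk -= 1
            state = 1 if frm == 1 else 0
        else:
            ops[t] = 3
            t += 1
            frm = fp[i, kk]
            i -= 1
            kk += 1
            state = 2 if frm == 1 else 0
    qstart = i
    rstart = i + dlo + kk
    qend = bi
    rend = bi + dlo + bk
    return best, qend, rend, qstart, rstart, t, ops
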