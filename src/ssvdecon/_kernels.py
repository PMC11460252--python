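"""Numba kernels for sequence alignment primitives.

All sequences are uint8 arrays over the encoding A=0, C=1, G=2, T=3, N=4.
An N never matches anything, including another N, so masked reference bases
can only hurt an alignment score.
"""

from __future__ import annotations

import numba as nb
import numpy as np

NEG_INF = -(10**6)


@nb.njit(cache=False)
def kmer_codes(arr, k):
    """2-bit pack every k-mer of ``arr``.

    Returns (codes, valid); ``valid[i]`` is False when the window starting at
    i contains an N (its code is meaningless).
    """
    n = arr.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, np.bool_)
    codes = np.empty(n, np.int64)
    valid = np.empty(n, np.bool_)
    mask = (np.int64(1) << (2 * k)) - 1
    code = np.int64(0)
    last_n = -1
    for i in range(arr.shape[0]):
        b = arr[i]
        if b > 3:
            last_n = i
            b = 0
        code = ((code << 2) | b) & mask
        j = i - k + 1
        if j >= 0:
            codes[j] = code
            valid[j] = last_n < j
    return codes, valid


@nb.njit(cache=False)
def diag_best_window(read, ref, diag, match, mismatch):
    """Best-scoring ungapped window of ``read`` laid on ``ref`` at offset ``diag``.

    Kadane scan over per-base scores (+match / -mismatch; out-of-bounds and N
    columns score as mismatches). Returns (score, read_start, read_end,
    matches) of the single best window; (0, 0, 0, 0) if nothing positive.
    """
    n = read.shape[0]
    m = ref.shape[0]
    best = 0
    bs = 0
    be = 0
    cur = 0
    cs = 0
    for i in range(n):
        r = diag + i
        if 0 <= r < m and read[i] <= 3 and read[i] == ref[r]:
            s = match
        else:
            s = mismatch
        cur += s
        if cur <= 0:
            cur = 0
            cs = i + 1
        elif cur > best:
            best = cur
            bs = cs
            be = i + 1
    matches = 0
    for i in range(bs, be):
        r = diag + i
        if 0 <= r < m and read[i] <= 3 and read[i] == ref[r]:
            matches += 1
    return best, bs, be, matches


@nb.njit(cache=False)
def diag_all_windows(a, b, diag, match, mismatch, min_len, out):
    """All disjoint positive-score windows of ``a`` against ``b`` at ``diag``.

    Windows are found by resetting the Kadane scan whenever the running score
    drops to zero and emitting the best window of each stretch. ``out`` is an
    (N, 3) int64 buffer receiving (start, end, matches) rows in a-coordinates;
    the number of rows written is returned. Only windows of length >= min_len
    are emitted.
    """
    n = a.shape[0]
    m = b.shape[0]
    lo = max(0, -diag)
    hi = min(n, m - diag)
    nout = 0
    best = 0
    bs = 0
    be = 0
    cur = 0
    cs = lo
    for i in range(lo, hi + 1):
        if i < hi:
            s = match if (a[i] <= 3 and a[i] == b[diag + i]) else mismatch
        else:
            s = NEG_INF  # flush at end of diagonal
        cur += s
        if cur <= 0:
            if best > 0 and be - bs >= min_len and nout < out.shape[0]:
                matches = 0
                for j in range(bs, be):
                    if a[j] <= 3 and a[j] == b[diag + j]:
                        matches += 1
                out[nout, 0] = bs
                out[nout, 1] = be
                out[nout, 2] = matches
                nout += 1
            cur = 0
            cs = i + 1
            best = 0
        elif cur > best:
            best = cur
            bs = cs
            be = i + 1
    return nout


@nb.njit(cache=False)
def sw_locate(read, query, match, mismatch, gap):
    """Linear-gap Smith-Waterman of ``query`` within ``read``.

    Returns (best_score, read_start, read_end) of the best local alignment;
    start/end are coordinates on ``read``. Used for adapter location.
    """
    n = read.shape[0]
    m = query.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    S = np.zeros((n + 1, m + 1), np.int32)
    best = 0
    b_end = 0
    b_start = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if (read[i - 1] <= 3 and read[i - 1] == query[j - 1]) else mismatch
            h = H[i - 1, j - 1] + sub
            st = S[i - 1, j - 1] if H[i - 1, j - 1] > 0 else i - 1
            u = H[i - 1, j] + gap
            if u > h:
                h = u
                st = S[i - 1, j] if H[i - 1, j] > 0 else i - 1
            l = H[i, j - 1] + gap
            if l > h:
                h = l
                st = S[i, j - 1] if H[i, j - 1] > 0 else i
            if h < 0:
                h = 0
            H[i, j] = h
            S[i, j] = st
            if h > best:
                best = h
                b_end = i
                b_start = st
    return best, b_start, b_end


@nb.njit(cache=False)
def gotoh_local(a, b, match, mismatch, gap_open, gap_ext):
    """Affine-gap local alignment (Gotoh) of ``a`` against ``b`` with traceback.

    A gap of length L costs gap_open + L * gap_ext. Returns
    (score, a_start, a_end, b_start, b_end, matches, aln_len) where aln_len is
    the number of alignment columns and matches the identical ones.
    """
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG_INF, np.int32)  # gap in a (consumes b)
    F = np.full((n + 1, m + 1), NEG_INF, np.int32)  # gap in b (consumes a)
    # pointers: 0 stop, 1 diag, 2 from E, 3 from F
    PH = np.zeros((n + 1, m + 1), np.uint8)
    PE = np.zeros((n + 1, m + 1), np.uint8)  # 1 opened from H
    PF = np.zeros((n + 1, m + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open + gap_ext
            e_ext = E[i, j - 1] + gap_ext
            if e_open >= e_ext:
                E[i, j] = e_open
                PE[i, j] = 1
            else:
                E[i, j] = e_ext
                PE[i, j] = 0
            f_open = H[i - 1, j] + gap_open + gap_ext
            f_ext = F[i - 1, j] + gap_ext
            if f_open >= f_ext:
                F[i, j] = f_open
                PF[i, j] = 1
            else:
                F[i, j] = f_ext
                PF[i, j] = 0
            sub = match if (a[i - 1] <= 3 and a[i - 1] == b[j - 1]) else mismatch
            h = H[i - 1, j - 1] + sub
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            PH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    i = bi
    j = bj
    matches = 0
    aln_len = 0
    state = 0  # 0 in H, 2 in E, 3 in F
    while i > 0 and j > 0:
        if state == 0:
            p = PH[i, j]
            if p == 0:
                break
            if p == 1:
                aln_len += 1
                if a[i - 1] <= 3 and a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            aln_len += 1
            opened = PE[i, j]
            j -= 1
            if opened == 1:
                state = 0
        else:
            aln_len += 1
            opened = PF[i, j]
            i -= 1
            if opened == 1:
                state = 0
    return best, i, bi, j, bj, matches, aln_len
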