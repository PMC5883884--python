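"""Numba-jitted hot loops: seed hashing and banded semi-global alignment.

All kernels operate on uint8 code arrays (A=0 C=1 G=2 T=3, N>=4).  Seeds are
packed 2 bits/base into uint64 keys, which caps usable seed lengths at 32 bp.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1 << 30

# backtrace op codes
OP_M = 0  # diagonal, equal bases
OP_X = 1  # diagonal, substitution
OP_I = 2  # consume query only (insertion in read)
OP_D = 3  # consume target only (deletion from read)


@njit(cache=True)
def genome_seed_scan(codes, k):
    """Rolling 2-bit pack of every k-mer of *codes*.

    Returns (keys, valid): ``keys[p]`` is the packed k-mer starting at p,
    ``valid[p]`` is False when the window contains an N (code >= 4).
    """
    n = codes.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, np.uint64), np.empty(0, np.bool_)
    keys = np.empty(m, np.uint64)
    valid = np.empty(m, np.bool_)
    mask = np.uint64((1 << (2 * k)) - 1)
    key = np.uint64(0)
    last_n = -1
    for i in range(n):
        c = codes[i]
        if c > 3:
            last_n = i
            c = 0
        key = ((key << np.uint64(2)) | np.uint64(c)) & mask
        j = i - k + 1
        if j >= 0:
            keys[j] = key
            valid[j] = last_n < j
    return keys, valid


@njit(cache=True)
def read_seed_keys(codes, k, stride):
    """Seed offsets and packed keys for one read.

    Offsets are 0, stride, 2*stride, ... plus a flush-right seed ending at
    the last base.  Seeds containing N are dropped.
    """
    n = codes.size
    offsets = np.empty(0, np.int64)
    keys = np.empty(0, np.uint64)
    if n < k:
        return offsets, keys
    last = n - k
    n_reg = last // stride + 1
    extra = 1 if (last % stride) != 0 else 0
    offsets = np.empty(n_reg + extra, np.int64)
    for i in range(n_reg):
        offsets[i] = i * stride
    if extra:
        offsets[n_reg] = last
    keys = np.empty(offsets.size, np.uint64)
    ok = np.empty(offsets.size, np.bool_)
    for s in range(offsets.size):
        off = offsets[s]
        key = np.uint64(0)
        good = True
        for i in range(off, off + k):
            c = codes[i]
            if c > 3:
                good = False
                break
            key = (key << np.uint64(2)) | np.uint64(c)
        keys[s] = key
        ok[s] = good
    return offsets[ok], keys[ok]


@njit(cache=True)
def semiglobal_distance(q, t, max_d):
    """Banded edit distance of query *q* end-to-end against a substring of *t*.

    Leading and trailing target bases are free; within the alignment the
    band restricts ``j - i`` to ``[-max_d, (len(t)-len(q)) + max_d]``.  Rows
    whose minimum exceeds max_d abort early (Ukkonen cutoff).

    Returns (distance, j_end); (INF, -1) when the distance exceeds max_d.
    """
    n = q.size
    m = t.size
    if n == 0:
        return 0, 0
    s_lo = -max_d
    s_hi = (m - n) + max_d
    if s_hi < s_lo:
        return INF, -1
    width = s_hi - s_lo + 1
    prev = np.full(width, INF, np.int64)
    cur = np.full(width, INF, np.int64)
    for col in range(width):
        j = col + s_lo
        if 0 <= j <= m:
            prev[col] = 0
    for i in range(1, n + 1):
        rowmin = INF
        qi = q[i - 1]
        base = i + s_lo
        for col in range(width):
            j = base + col
            v = INF
            if 0 <= j <= m:
                if j >= 1 and prev[col] < INF:
                    v = prev[col] + (0 if t[j - 1] == qi else 1)
                if col + 1 < width and prev[col + 1] < INF:
                    c = prev[col + 1] + 1
                    if c < v:
                        v = c
                if col >= 1 and j >= 1 and cur[col - 1] < INF:
                    c = cur[col - 1] + 1
                    if c < v:
                        v = c
            cur[col] = v
            if v < rowmin:
                rowmin = v
        if rowmin > max_d:
            return INF, -1
        tmp = prev
        prev = cur
        cur = tmp
    best = INF
    best_j = -1
    for col in range(width):
        j = n + s_lo + col
        if 0 <= j <= m and prev[col] < best:
            best = prev[col]
            best_j = j
    if best > max_d:
        return INF, -1
    return best, best_j


@njit(cache=True)
def semiglobal_backtrace(q, t, max_d):
    """Full banded DP with backtrace.

    Returns (distance, j_start, j_end, ops) where ops is an int8 array of
    OP_* codes in query order; distance INF yields empty ops and j=-1.
    Backtrace ties prefer diagonal, then insertion, then deletion.
    """
    n = q.size
    m = t.size
    empty = np.empty(0, np.int8)
    if n == 0:
        return 0, 0, 0, empty
    s_lo = -max_d
    s_hi = (m - n) + max_d
    if s_hi < s_lo:
        return INF, -1, -1, empty
    width = s_hi - s_lo + 1
    D = np.full((n + 1, width), INF, np.int64)
    for col in range(width):
        j = col + s_lo
        if 0 <= j <= m:
            D[0, col] = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        base = i + s_lo
        for col in range(width):
            j = base + col
            if j < 0 or j > m:
                continue
            v = INF
            if j >= 1 and D[i - 1, col] < INF:
                v = D[i - 1, col] + (0 if t[j - 1] == qi else 1)
            if col + 1 < width and D[i - 1, col + 1] < INF:
                c = D[i - 1, col + 1] + 1
                if c < v:
                    v = c
            if col >= 1 and j >= 1 and D[i, col - 1] < INF:
                c = D[i, col - 1] + 1
                if c < v:
                    v = c
            D[i, col] = v
    best = INF
    best_col = -1
    for col in range(width):
        j = n + s_lo + col
        if 0 <= j <= m and D[n, col] < best:
            best = D[n, col]
            best_col = col
    if best > max_d:
        return INF, -1, -1, empty
    # walk back
    ops = np.empty(n + m + 1, np.int8)
    nops = 0
    i = n
    col = best_col
    j_end = n + s_lo + best_col
    while i > 0:
        j = i + s_lo + col
        v = D[i, col]
        qi = q[i - 1]
        moved = False
        if j >= 1 and D[i - 1, col] < INF:
            sub = 0 if t[j - 1] == qi else 1
            if D[i - 1, col] + sub == v:
                ops[nops] = OP_M if sub == 0 else OP_X
                nops += 1
                i -= 1
                moved = True
        if not moved and col + 1 < width and D[i - 1, col + 1] < INF and D[i - 1, col + 1] + 1 == v:
            ops[nops] = OP_I
            nops += 1
            i -= 1
            col += 1
            moved = True
        if not moved:
            # left move: deletion from read
            ops[nops] = OP_D
            nops += 1
            col -= 1
    j_start = i + s_lo + col
    out = np.empty(nops, np.int8)
    for a in range(nops):
        out[a] = ops[nops - 1 - a]
    return best, j_start, j_end, out
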