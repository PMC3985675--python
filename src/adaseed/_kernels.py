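"""Numba kernels for the alignment hot paths.

Everything here operates on numeric code arrays: bases are uint8 codes
(A=0, C=1, G=2, T=3, N=4) and pattern position classes are small uint8
values with 0 reserved as the terminator (N / past-the-end), so that
terminated suffixes sort first.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**15)


@njit(cache=True)
def _class_at(refcode, classmap, period, s, j, ref_len):
    pos = s + j
    if pos >= ref_len:
        return np.uint8(0)
    return classmap[j % period, refcode[pos]]


@njit(cache=True)
def _lower_bound(sa, refcode, classmap, period, j, cls, lo, hi, ref_len):
    # first index in [lo, hi) whose class at depth j is >= cls
    while lo < hi:
        mid = (lo + hi) // 2
        if _class_at(refcode, classmap, period, sa[mid], j, ref_len) < cls:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def _upper_bound(sa, refcode, classmap, period, j, cls, lo, hi, ref_len):
    # first index in [lo, hi) whose class at depth j is > cls
    while lo < hi:
        mid = (lo + hi) // 2
        if _class_at(refcode, classmap, period, sa[mid], j, ref_len) <= cls:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def seed_search(
    qcode, sa, refcode, classmap, period, m, k, max_depth,
    out_q, out_r, out_len, count_only,
):
    """Adaptive seeds: minimal-length pattern-prefix matches with count <= m.

    Returns the number of emitted (query_pos, ref_pos, length) seeds;
    fills the out arrays unless count_only.  Starts are every k-th query
    position; a start emits nothing if its count never drops to <= m
    before the query ends, an N is hit, or max_depth is reached.
    """
    n_out = 0
    q_len = qcode.size
    n_sa = sa.size
    ref_len = refcode.size
    for q in range(0, q_len, k):
        lo = 0
        hi = n_sa
        j = 0
        while True:
            if q + j >= q_len or j >= max_depth:
                break
            cls = classmap[j % period, qcode[q + j]]
            if cls == 0:
                break
            lo = _lower_bound(sa, refcode, classmap, period, j, cls, lo, hi, ref_len)
            hi = _upper_bound(sa, refcode, classmap, period, j, cls, lo, hi, ref_len)
            if lo >= hi:
                break
            if hi - lo <= m:
                if count_only:
                    n_out += hi - lo
                else:
                    for t in range(lo, hi):
                        out_q[n_out] = q
                        out_r[n_out] = sa[t]
                        out_len[n_out] = j + 1
                        n_out += 1
                break
            j += 1
    return n_out


@njit(cache=True)
def gapless_extend_batch(qpos, rpos, slen, qcode, rcode, submat, y, out):
    """X-drop gapless extension of each seed, trimmed to its best core.

    For each seed: extend left of the seed span and right of it, each
    direction stopping when the running score drops more than y below
    its running maximum; then take the maximal-score contiguous
    subsegment (leftmost on ties) of the extended span.  out[i] =
    (q_start, q_end, r_start, r_end, score, anchor_offset) where
    anchor_offset is the column (relative to q_start) achieving the
    maximal prefix score, leftmost on ties.
    """
    n = qpos.size
    q_len = qcode.size
    r_len = rcode.size
    for i in range(n):
        q0 = qpos[i]
        r0 = rpos[i]
        diag = r0 - q0
        e0 = q0 + slen[i]  # query end of the seed span

        # left extension
        best = 0
        bestk = 0
        run = 0
        kk = 1
        while q0 - kk >= 0 and r0 - kk >= 0:
            run += submat[qcode[q0 - kk], rcode[r0 - kk]]
            if run > best:
                best = run
                bestk = kk
            elif best - run > y:
                break
            kk += 1
        left = bestk

        # right extension beyond the seed span
        best = 0
        bestk = 0
        run = 0
        kk = 0
        while e0 + kk < q_len and diag + e0 + kk < r_len:
            run += submat[qcode[e0 + kk], rcode[diag + e0 + kk]]
            if run > best:
                best = run
                bestk = kk + 1
            elif best - run > y:
                break
            kk += 1
        right = bestk

        # maximal-score contiguous subsegment (leftmost tie-break)
        span_start = q0 - left
        span_len = (e0 + right) - span_start
        best_sum = NEG
        best_s = 0
        best_e = 0
        cur = 0
        cur_s = 0
        for t in range(span_len):
            sc = submat[qcode[span_start + t], rcode[diag + span_start + t]]
            if cur <= 0:
                cur = sc
                cur_s = t
            else:
                cur += sc
            if cur > best_sum:
                best_sum = cur
                best_s = cur_s
                best_e = t + 1
        # anchor: leftmost column achieving the maximal running prefix
        run = 0
        pbest = NEG
        anchor = 0
        for t in range(best_s, best_e):
            run += submat[qcode[span_start + t], rcode[diag + span_start + t]]
            if run > pbest:
                pbest = run
                anchor = t - best_s
        out[i, 0] = span_start + best_s
        out[i, 1] = span_start + best_e
        out[i, 2] = diag + span_start + best_s
        out[i, 3] = diag + span_start + best_e
        out[i, 4] = best_sum
        out[i, 5] = anchor


@njit(cache=True)
def xdrop_affine(qs, rs, submat, gap_exist, gap_extend, ydrop, width, tb, jlo_arr):
    """One-directional affine-gap X-drop extension from the origin.

    Aligns a prefix of qs (rows) against a prefix of rs (columns),
    starting from an implicit score-0 state at (0, 0).  Back-to-back
    insertions and deletions are permitted; a gap of length g costs
    gap_exist + gap_extend * g.  Cells whose best state falls more than
    ydrop below the running maximum are pruned; each row keeps a
    contiguous live window of at most `width` columns.  tb (rows x
    width traceback bytes) and jlo_arr (window start per row) are
    caller-allocated.

    Returns (best_score, best_i, best_j, overflow).  The best is
    tracked over match states only: with positive gap costs an optimal
    extension never ends in a gap.  overflow=1 means the window cap was
    hit while live cells remained; retry with a larger width.

    Traceback byte: bits 0-1 = predecessor state of M, bits 2-3 of D
    (query-consuming, gap in reference text), bits 4-5 of I
    (reference-consuming, gap in query text); codes 0=M, 1=D, 2=I,
    3=origin/none.
    """
    lq = qs.size
    lr = rs.size
    M_prev = np.full(width, NEG, dtype=np.int64)
    D_prev = np.full(width, NEG, dtype=np.int64)
    I_prev = np.full(width, NEG, dtype=np.int64)
    M_cur = np.full(width, NEG, dtype=np.int64)
    D_cur = np.full(width, NEG, dtype=np.int64)
    I_cur = np.full(width, NEG, dtype=np.int64)

    best = 0
    best_i = 0
    best_j = 0

    # row 0: origin at j=0, then a run of reference-consuming gaps
    lo = 0
    hi = 1
    M_prev[0] = 0
    jlo_arr[0] = 0
    tb[0, 0] = 3 | (3 << 2) | (3 << 4)
    j = 1
    while j <= lr:
        if j >= width:
            if -(gap_exist + gap_extend * j) >= best - ydrop:
                return best, best_i, best_j, 1
            break
        sc = -(gap_exist + gap_extend * j)
        if best - sc > ydrop:
            break
        I_prev[j] = sc
        pred = 3 if j == 1 else 2
        tb[0, j] = 3 | (3 << 2) | (pred << 4)
        hi = j + 1
        j += 1

    for i in range(1, lq + 1):
        new_lo = lo
        for t in range(width):
            M_cur[t] = NEG
            D_cur[t] = NEG
            I_cur[t] = NEG
        jlo_arr[i] = new_lo
        first_live = -1
        last_live = -1
        j = new_lo
        while j <= lr:
            off = j - new_lo
            if off >= width:
                # live frontier may continue beyond the cap
                if last_live >= 0 and (
                    M_cur[off - 1] > NEG // 2
                    or I_cur[off - 1] > NEG // 2
                    or D_cur[off - 1] > NEG // 2
                    or (lo <= j < hi)
                    or (lo <= j - 1 < hi)
                ):
                    return best, best_i, best_j, 1
                break
            # D: from row i-1, same column
            d_val = NEG
            d_pred = 3
            if lo <= j < hi:
                po = j - lo
                v = M_prev[po] - gap_exist - gap_extend
                d_val = v
                d_pred = 0
                v = D_prev[po] - gap_extend
                if v > d_val:
                    d_val = v
                    d_pred = 1
                v = I_prev[po] - gap_exist - gap_extend
                if v > d_val:
                    d_val = v
                    d_pred = 2
            # M: from row i-1, column j-1
            m_val = NEG
            m_pred = 3
            if j >= 1 and lo <= j - 1 < hi:
                po = j - 1 - lo
                bb = M_prev[po]
                m_pred = 0
                if D_prev[po] > bb:
                    bb = D_prev[po]
                    m_pred = 1
                if I_prev[po] > bb:
                    bb = I_prev[po]
                    m_pred = 2
                if bb > NEG // 2:
                    m_val = bb + submat[qs[i - 1], rs[j - 1]]
            # I: from the same row, column j-1
            i_val = NEG
            i_pred = 3
            if j - 1 >= new_lo:
                po = j - 1 - new_lo
                v = M_cur[po] - gap_exist - gap_extend
                i_val = v
                i_pred = 0
                v = I_cur[po] - gap_extend
                if v > i_val:
                    i_val = v
                    i_pred = 2  # state code of I
                v = D_cur[po] - gap_exist - gap_extend
                if v > i_val:
                    i_val = v
                    i_pred = 1  # state code of D

            cell = m_val
            if d_val > cell:
                cell = d_val
            if i_val > cell:
                cell = i_val
            if cell > NEG // 2 and cell >= best - ydrop:
                M_cur[off] = m_val if m_val >= best - ydrop else NEG
                D_cur[off] = d_val if d_val >= best - ydrop else NEG
                I_cur[off] = i_val if i_val >= best - ydrop else NEG
                tb[i, off] = m_pred | (d_pred << 2) | (i_pred << 4)
                if M_cur[off] > best:
                    best = M_cur[off]
                    best_i = i
                    best_j = j
                if first_live < 0:
                    first_live = j
                last_live = j
            else:
                # past all previous-row influence and no live I-chain:
                # nothing further right can come alive
                if j >= hi and (j - 1 < new_lo or (
                    M_cur[j - 1 - new_lo] <= NEG // 2
                    and I_cur[j - 1 - new_lo] <= NEG // 2
                    and D_cur[j - 1 - new_lo] <= NEG // 2
                )):
                    break
            j += 1

        if first_live < 0:
            break
        if first_live > new_lo:
            shift = first_live - new_lo
            n_keep = last_live + 1 - first_live
            for t in range(n_keep):
                M_cur[t] = M_cur[t + shift]
                D_cur[t] = D_cur[t + shift]
                I_cur[t] = I_cur[t + shift]
                tb[i, t] = tb[i, t + shift]
            for t in range(n_keep, width):
                M_cur[t] = NEG
                D_cur[t] = NEG
                I_cur[t] = NEG
            jlo_arr[i] = first_live
        lo = first_live
        hi = last_live + 1
        tmp = M_prev
        M_prev = M_cur
        M_cur = tmp
        tmp = D_prev
        D_prev = D_cur
        D_cur = tmp
        tmp = I_prev
        I_prev = I_cur
        I_cur = tmp

    return best, best_i, best_j, 0


@njit(cache=True)
def smith_waterman_score(qc, rc, submat, gap_exist, gap_extend):
    """Full affine-gap local alignment score (Gotoh recursion)."""
    lq = qc.size
    lr = rc.size
    M = np.zeros(lr + 1, dtype=np.int64)
    D = np.full(lr + 1, NEG, dtype=np.int64)
    best = 0
    for i in range(1, lq + 1):
        prev_diag = M[0]
        I_run = NEG
        for j in range(1, lr + 1):
            d_open = M[j] - gap_exist - gap_extend
            d_ext = D[j] - gap_extend
            D[j] = d_open if d_open > d_ext else d_ext
            i_open = M[j - 1] - gap_exist - gap_extend
            i_ext = I_run - gap_extend
            I_run = i_open if i_open > i_ext else i_ext
            m_val = prev_diag + submat[qc[i - 1], rc[j - 1]]
            cell = m_val
            if D[j] > cell:
                cell = D[j]
            if I_run > cell:
                cell = I_run
            if cell < 0:
                cell = 0
            prev_diag = M[j]
            M[j] = cell
            if cell > best:
                best = cell
    return best
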