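"""Banded global/extension alignment kernel.

A single numba DP kernel serves three uses inside the assembler:

* GLOBAL  — end-to-end alignment of two short segments (gap filling
            between chained anchors).
* EXTEND  — alignment anchored at (0,0) that may stop anywhere, used to
            extend an overlap from its outermost anchors toward the read
            ends (dovetail extension).
* GLOCAL  — the full first sequence against a window of the second with
            free leading/trailing gaps in the window (read-to-backbone
            alignment during consensus).

Affine gap cost: a gap of length g costs open + (g-1)*extend.  The band is
|j - center(i)| <= band, where center follows the (0,0)-(la,lb) diagonal
for GLOBAL and the unit diagonal (optionally offset) otherwise.  The kernel
reports whether the optimal path touched the band boundary so callers can
retry with a doubled band.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
from numba import njit

MODE_GLOBAL = 0
MODE_EXTEND = 1
MODE_GLOCAL = 2
MODE_EXTEND_FULL = 3  # anchored at (0,0), must reach the end of a or of b

NEG = -(1 << 28)

_OPS = "=XDI"

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def encode_seq(seq: str) -> np.ndarray:
    """DNA text to int8 codes (A=0..T=3, anything else 4 = never matches)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _dp(a, b, band, mode, diag0, smatch, smis, sopen, sext):  # pragma: no cover
    la = a.shape[0]
    lb = b.shape[0]
    W = 2 * band + 1
    lo = np.zeros(la + 1, np.int64)
    hi = np.zeros(la + 1, np.int64)
    tbM = np.zeros((la + 1, W), np.uint8)  # 0 fromM, 1 fromX, 2 fromY, 9 start
    tbX = np.zeros((la + 1, W), np.uint8)  # 0 fromM, 1 fromX
    tbY = np.zeros((la + 1, W), np.uint8)  # 0 fromM, 1 fromY
    Mprev = np.full(W, NEG, np.int64)
    Xprev = np.full(W, NEG, np.int64)
    Yprev = np.full(W, NEG, np.int64)
    Mcur = np.full(W, NEG, np.int64)
    Xcur = np.full(W, NEG, np.int64)
    Ycur = np.full(W, NEG, np.int64)

    best = NEG if mode == MODE_GLOCAL else 0
    bi = 0
    bj = 0
    bstate = 0
    gbest = 0  # global max (any cell), tracked for EXTEND_FULL z-drop
    gi = 0
    gj = 0
    gstate = 0
    completed = -1

    for i in range(la + 1):
        if mode == MODE_GLOBAL:
            center = (i * lb + la // 2) // la if la > 0 else 0
        else:
            center = i + diag0
        l = center - band
        if l < 0:
            l = 0
        h = center + band
        if h > lb:
            h = lb
        if l > h:
            # band ran off the end of b; modes with a free right boundary
            # just stop here, a global alignment cannot be completed
            if mode != MODE_GLOBAL:
                break
            return NEG, 0, 0, 0, True, tbM, tbX, tbY, lo, hi, gbest, gi, gj, gstate
        lo[i] = l
        hi[i] = h
        completed = i
        if i == 0:
            for j in range(l, h + 1):
                idx = j - l
                Mcur[idx] = NEG
                Xcur[idx] = NEG
                Ycur[idx] = NEG
                if mode == MODE_GLOCAL:
                    Mcur[idx] = 0
                    tbM[0, idx] = 9
                elif j == 0:
                    Mcur[idx] = 0
                    tbM[0, idx] = 9
                else:
                    Ycur[idx] = sopen + (j - 1) * sext
                    tbY[0, idx] = 0 if j == 1 else 1
        else:
            pl = lo[i - 1]
            ph = hi[i - 1]
            for j in range(l, h + 1):
                idx = j - l
                # X: consume a only, from (i-1, j)
                xv = NEG
                xt = 0
                if pl <= j <= ph:
                    p = j - pl
                    v1 = Mprev[p] + sopen
                    v2 = Xprev[p] + sext
                    if v2 > v1:
                        xv = v2
                        xt = 1
                    else:
                        xv = v1
                        xt = 0
                    if xv < NEG:
                        xv = NEG
                Xcur[idx] = xv
                tbX[i, idx] = xt
                # M: diagonal from (i-1, j-1)
                mv = NEG
                mt = 0
                if j >= 1 and pl <= j - 1 <= ph:
                    p = j - 1 - pl
                    pv = Mprev[p]
                    mt = 0
                    if Xprev[p] > pv:
                        pv = Xprev[p]
                        mt = 1
                    if Yprev[p] > pv:
                        pv = Yprev[p]
                        mt = 2
                    if pv > NEG:
                        ca = a[i - 1]
                        cb = b[j - 1]
                        if ca == cb and ca < 4:
                            mv = pv + smatch
                        else:
                            mv = pv + smis
                if mode == MODE_GLOCAL and j == 0 and mv < 0:
                    # free start mid-read: the prefix overhangs the window
                    mv = 0
                    mt = 9
                Mcur[idx] = mv
                tbM[i, idx] = mt
                # Y: consume b only, from (i, j-1)
                yv = NEG
                yt = 0
                if j - 1 >= l:
                    v1 = Mcur[idx - 1] + sopen
                    v2 = Ycur[idx - 1] + sext
                    if v2 > v1:
                        yv = v2
                        yt = 1
                    else:
                        yv = v1
                        yt = 0
                    if yv < NEG:
                        yv = NEG
                Ycur[idx] = yv
                tbY[i, idx] = yt

                if mode == MODE_EXTEND:
                    v = Mcur[idx]
                    st = 0
                    if Xcur[idx] > v:
                        v = Xcur[idx]
                        st = 1
                    if Ycur[idx] > v:
                        v = Ycur[idx]
                        st = 2
                    if v > best:
                        best = v
                        bi = i
                        bj = j
                        bstate = st
                elif mode == MODE_GLOCAL and j == lb and i < la:
                    # free end mid-read: the suffix overhangs the window
                    v = Mcur[idx]
                    st = 0
                    if Xcur[idx] > v:
                        v = Xcur[idx]
                        st = 1
                    if v > best:
                        best = v
                        bi = i
                        bj = j
                        bstate = st
                elif mode == MODE_EXTEND_FULL:
                    v = Mcur[idx]
                    st = 0
                    if Xcur[idx] > v:
                        v = Xcur[idx]
                        st = 1
                    if Ycur[idx] > v:
                        v = Ycur[idx]
                        st = 2
                    if i == la or j == lb:
                        if v > NEG // 2 and (v > best or bi == 0):
                            best = v
                            bi = i
                            bj = j
                            bstate = st
                    if v > gbest:
                        gbest = v
                        gi = i
                        gj = j
                        gstate = st
        Mprev, Mcur = Mcur, Mprev
        Xprev, Xcur = Xcur, Xprev
        Yprev, Ycur = Ycur, Yprev

    # pick endpoint
    if mode == MODE_GLOBAL:
        if not (lo[la] <= lb <= hi[la]):
            return NEG, la, lb, 0, True, tbM, tbX, tbY, lo, hi, gbest, gi, gj, gstate
        idx = lb - lo[la]
        v = Mprev[idx]
        st = 0
        if Xprev[idx] > v:
            v = Xprev[idx]
            st = 1
        if Yprev[idx] > v:
            v = Yprev[idx]
            st = 2
        return v, la, lb, st, False, tbM, tbX, tbY, lo, hi, gbest, gi, gj, gstate
    elif mode == MODE_GLOCAL:
        bv = best
        bii = bi
        bjj = bj
        bst = bstate
        if completed == la:
            for j in range(lo[la], hi[la] + 1):
                idx = j - lo[la]
                v = Mprev[idx]
                st = 0
                if Xprev[idx] > v:
                    v = Xprev[idx]
                    st = 1
                if v > bv:
                    bv = v
                    bii = la
                    bjj = j
                    bst = st
        if bv <= NEG:
            return NEG, 0, 0, 0, True, tbM, tbX, tbY, lo, hi, gbest, gi, gj, gstate
        return bv, bii, bjj, bst, False, tbM, tbX, tbY, lo, hi, gbest, gi, gj, gstate
    else:
        return best, bi, bj, bstate, False, tbM, tbX, tbY, lo, hi, gbest, gi, gj, gstate


@njit(cache=True)
def _traceback(a, b, ei, ej, state, tbM, tbX, tbY, lo, hi, lb):  # pragma: no cover
    ops = np.empty(ei + ej + 1, np.int8)
    n = 0
    touched = False
    si = ei
    sj = ej
    while True:
        if (ej == lo[ei] and lo[ei] > 0) or (ej == hi[ei] and hi[ei] < lb):
            touched = True
        idx = ej - lo[ei]
        if state == 0:
            t = tbM[ei, idx]
            if t == 9:
                si = ei
                sj = ej
                break
            if a[ei - 1] == b[ej - 1] and a[ei - 1] < 4:
                ops[n] = 0
            else:
                ops[n] = 1
            n += 1
            ei -= 1
            ej -= 1
            state = t
        elif state == 1:
            ops[n] = 2
            n += 1
            state = tbX[ei, idx]
            ei -= 1
        else:
            ops[n] = 3
            n += 1
            state = tbY[ei, idx] * 2  # 0 fromM, 1 fromY -> state 2
            ej -= 1
    return ops[:n][::-1], si, sj, touched


def _runs_from_ops(ops: np.ndarray) -> List[Tuple[int, str]]:
    runs: List[Tuple[int, str]] = []
    for op in ops:
        ch = _OPS[op]
        if runs and runs[-1][1] == ch:
            runs[-1] = (runs[-1][0] + 1, ch)
        else:
            runs.append((1, ch))
    return runs


def runs_to_script(runs) -> str:
    return "".join(f"{n}{op}" for n, op in runs)


class Scoring:
    """Alignment scoring: match/mismatch and affine gaps.

    gap of length g costs open + (g-1)*ext (both negative).
    """

    __slots__ = ("match", "mismatch", "gap_open", "gap_ext")

    def __init__(self, match: int = 2, mismatch: int = -4,
                 gap_open: int = -4, gap_ext: int = -2):
        self.match = match
        self.mismatch = mismatch
        self.gap_open = gap_open
        self.gap_ext = gap_ext

    def score_runs(self, runs) -> int:
        s = 0
        for n, op in runs:
            if op == "=":
                s += n * self.match
            elif op == "X":
                s += n * self.mismatch
            else:
                s += self.gap_open + (n - 1) * self.gap_ext
        return s


DEFAULT_SCORING = Scoring()


def _align(a: str, b: str, band: int, mode: int, diag0: int,
           scoring: Scoring, zdrop: int = None):
    """Run the kernel on text; returns (score, runs, si, sj, ei, ej, touched)."""
    ea = encode_seq(a)
    eb = encode_seq(b)
    la, lb = len(ea), len(eb)
    if la == 0 and lb == 0:
        return 0, [], 0, 0, 0, 0, False
    if la == 0:
        if mode in (MODE_EXTEND, MODE_EXTEND_FULL):
            return 0, [], 0, 0, 0, 0, False
        if mode == MODE_GLOCAL:
            return 0, [], 0, lb, 0, lb, False
        s = scoring.gap_open + (lb - 1) * scoring.gap_ext
        return s, [(lb, "I")], 0, 0, 0, lb, False
    if lb == 0:
        if mode in (MODE_EXTEND, MODE_EXTEND_FULL):
            return 0, [], 0, 0, 0, 0, False
        s = scoring.gap_open + (la - 1) * scoring.gap_ext
        return s, [(la, "D")], 0, 0, la, 0, False
    score, ei, ej, state, failed, tbM, tbX, tbY, lo, hi, gbest, gi, gj, gstate = _dp(
        ea, eb, band, mode, diag0,
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_ext,
    )
    if failed:
        return NEG, [], 0, 0, la, lb, True
    if mode == MODE_EXTEND_FULL and zdrop is not None and \
            gbest - score > zdrop and (gi, gj) != (ei, ej):
        # the alignment collapsed between the best point and the boundary
        # (e.g. a chimeric junction): stop at the best point instead
        score, ei, ej, state = gbest, gi, gj, gstate
    if mode in (MODE_EXTEND, MODE_EXTEND_FULL) and ei == 0 and ej == 0:
        return 0, [], 0, 0, 0, 0, False
    ops, si, sj, touched = _traceback(ea, eb, ei, ej, state, tbM, tbX, tbY, lo, hi, lb)
    return int(score), _runs_from_ops(ops), int(si), int(sj), int(ei), int(ej), bool(touched)


def global_align(a: str, b: str, band: int,
                 scoring: Scoring = DEFAULT_SCORING):
    """Banded end-to-end alignment; (score, runs, touched)."""
    score, runs, _, _, _, _, touched = _align(a, b, band, MODE_GLOBAL, 0, scoring)
    return score, runs, touched


def global_align_sched(a: str, b: str, min_band: int, max_band: int,
                       scoring: Scoring = DEFAULT_SCORING):
    """Global alignment with the doubling band schedule.

    Starts at min_band (raised immediately past the length difference,
    which no narrower band can accommodate) and doubles whenever the
    optimal path touches the band boundary, capped at max_band or the
    longer sequence length.
    """
    need = abs(len(a) - len(b)) + 1
    band = min_band
    while band < need and band < max_band:
        band *= 2
    limit = max(len(a), len(b))
    while True:
        score, runs, touched = global_align(a, b, band, scoring)
        if not touched or band >= max_band or band >= limit:
            return score, runs
        band = min(2 * band, max_band)


def extend_align(a: str, b: str, band: int,
                 scoring: Scoring = DEFAULT_SCORING):
    """Extension from (0,0): best-scoring prefix-vs-prefix alignment.

    Returns (score, runs, a_used, b_used).
    """
    score, runs, _, _, ei, ej, _ = _align(a, b, band, MODE_EXTEND, 0, scoring)
    if score <= 0:
        return 0, [], 0, 0
    return score, runs, ei, ej


def extend_align_full(a: str, b: str, band: int,
                      scoring: Scoring = DEFAULT_SCORING,
                      zdrop: int = 200):
    """Extension from (0,0) to the end of `a` or of `b`, with z-drop.

    Used for dovetail end extension: the overlap alignment runs all the
    way to the nearer read end however noisy the tail is, so the
    unaligned remainder sits entirely on one read — unless the score
    collapses more than `zdrop` below its running maximum before the
    boundary (the signature of a chimeric junction), in which case the
    extension stops at the maximum.  Returns (score, runs, a_used,
    b_used).
    """
    score, runs, _, _, ei, ej, _ = _align(a, b, band, MODE_EXTEND_FULL, 0,
                                          scoring, zdrop=zdrop)
    if ei == 0 and ej == 0:
        return 0, [], 0, 0
    return score, runs, ei, ej


def glocal_align(a: str, b: str, band: int, diag0: int = 0,
                 scoring: Scoring = DEFAULT_SCORING):
    """`a` against a free-ends window `b`.

    The window's unaligned flanks are free; if the window is shorter
    than `a` requires, `a` may overhang its boundaries, leaving a
    prefix/suffix of `a` unaligned.  Returns
    (score, runs, a_start, a_end, b_start, b_end).
    """
    score, runs, si, sj, ei, ej, _ = _align(a, b, band, MODE_GLOCAL, diag0,
                                            scoring)
    return score, runs, si, ei, sj, ej
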