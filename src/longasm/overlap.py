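"""Pairwise overlap detection for noisy long reads.

Given candidate read pairs from the k-mer index, this module anchors them
with short exact z-mer matches in HPC space, chains the anchors into
collinear blocks inside sliding query windows using the recurrence

    S_{i+1} = S_i + L_{i+1} - Distance_{i,i+1}

(resetting whenever the running score falls below the incoming anchor
length), down-weights repeat-heavy candidates by seed depth, and finally
produces a base-level alignment in four steps: anchors are decompressed to
raw space and emitted as matches, gaps between anchors inside a window are
closed by banded global alignment, adjacent windows are joined the same way
with a dynamically doubling band, and the two ends are extended toward the
read ends with a wide fixed band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._align import (
    DEFAULT_SCORING,
    Scoring,
    extend_align,
    extend_align_full,
    global_align,
    global_align_sched,
    runs_to_script,
)
from .hpc_index import (
    CandidateHit,
    HPCRead,
    KmerIndex,
    build_index,
    find_candidates,
    hpc_compress,
    hpc_to_raw,
    _kmer_codes,
)
from .io_formats import OverlapRecord, Read, revcomp


@dataclass
class OverlapParams:
    """All overlapper knobs."""

    k: int = 16  # HPC k-mer size (-k)
    max_kmer_count: int = 500  # occurrence cap (-K)
    subsample_denominator: int = 4  # hash subsample fraction
    min_coverage: int = 300  # candidate seed coverage (-d)
    max_candidates: int = 500  # top candidates per query (-A)
    window_size: int = 800  # query window for z-mer chaining (-y)
    z: int = 10  # z-mer size (-z)
    min_window_match: int = 200  # raw matched-length window pre-filter
    min_window_block: int = 100  # chained-block coverage to keep a window
    min_total: int = 300  # total chained coverage to keep a candidate
    low_depth: int = 10  # depth at which repeat weight starts dropping (-q)
    high_depth: int = 100  # depth at which repeat weight reaches 0
    max_diag_drift: int = 100  # window anchor deviation from dominant diagonal
    min_band: int = 50  # dynamic band range (-w)
    max_band: int = 3200
    end_band: int = 800  # fixed band for end extension
    end_drop: int = 200  # z-drop: stop extension if score falls this far
    min_identity: float = 0.65  # floor for emitting an overlap
    scoring: Scoring = field(default_factory=Scoring)


@dataclass
class Anchor:
    """A maximal exact HPC match of length >= z between query and target."""

    qpos: int
    tpos: int
    length: int
    strand: str = "+"

    @property
    def qend(self) -> int:
        return self.qpos + self.length

    @property
    def tend(self) -> int:
        return self.tpos + self.length


@dataclass
class ChainBlock:
    """A syntenic block: collinear anchors scored by the chaining recurrence."""

    anchors: List[Anchor]
    S: int
    q_span: Tuple[int, int]
    t_span: Tuple[int, int]


def extract_anchors(
    query: HPCRead,
    target: HPCRead,
    strand: str = "+",
    z: int = 10,
    _qcodes=None,
    _tcodes=None,
) -> List[Anchor]:
    """All maximal exact z-mer runs between query and oriented target.

    For strand '-', `target` must already be the reverse-complemented HPC
    read.  Runs are maximal common substrings of length >= z, reported
    once, sorted by (qpos, tpos).  Precomputed z-mer code arrays can be
    passed to avoid recomputation in all-vs-all loops.
    """
    if _qcodes is None:
        _qcodes = _kmer_codes(query.hseq, z)
    if _tcodes is None:
        _tcodes = _kmer_codes(target.hseq, z)
    qcodes, qvalid = _qcodes
    tcodes, tvalid = _tcodes
    qpos = np.flatnonzero(qvalid)
    qc = qcodes[qvalid]
    tpos_all = np.flatnonzero(tvalid)
    tc = tcodes[tvalid]
    if len(qc) == 0 or len(tc) == 0:
        return []
    torder = np.argsort(tc, kind="stable")
    tsorted = tc[torder]
    left = np.searchsorted(tsorted, qc, side="left")
    right = np.searchsorted(tsorted, qc, side="right")
    counts = right - left
    nz = np.flatnonzero(counts)
    if len(nz) == 0:
        return []
    cnz = counts[nz]
    qs = np.repeat(qpos[nz], cnz)
    # grouped arange: for each nz entry the slice left[i]:right[i]
    starts = np.cumsum(cnz) - cnz
    flat = np.repeat(left[nz] - starts, cnz) + np.arange(int(cnz.sum()))
    ts = tpos_all[torder[flat]]
    diag = qs - ts
    order = np.lexsort((qs, diag))
    qs, ts, diag = qs[order], ts[order], diag[order]
    breaks = np.flatnonzero(
        np.concatenate(([True], (diag[1:] != diag[:-1]) | (qs[1:] != qs[:-1] + 1)))
    )
    ends = np.concatenate((breaks[1:], [len(qs)]))
    anchors = [
        Anchor(int(qs[a]), int(ts[a]), int(qs[b - 1] - qs[a]) + z, strand)
        for a, b in zip(breaks, ends)
    ]
    anchors.sort(key=lambda an: (an.qpos, an.tpos))
    return anchors


def _anchor_distance(prev: Anchor, nxt: Anchor) -> int:
    """Chaining distance between adjacent (qpos-ordered) anchors.

    The distance is the diagonal drift — how far the candidate-side gap
    deviates from the query-side gap.  Collinear anchors separated only
    by mismatches cost ~0 however sparse they are; an anchor jumping to
    an unrelated candidate position (repeat hit, random match) is
    charged the full displacement, resetting the recurrence.
    """
    qgap = nxt.qpos - prev.qend
    tgap = nxt.tpos - prev.tend
    return abs(tgap - qgap)


def chain_window(anchors: Sequence[Anchor]) -> Optional[ChainBlock]:
    """Greedy syntenic-block chaining over qpos-sorted anchors.

    A running score starts at the first anchor's length and accumulates
    S + L - Distance; whenever the incoming score would fall below the new
    anchor's own length the score recovers to that length and a new block
    begins.  The block returned ends at the anchor where S peaked (ties:
    earliest), so a trailing decay never dilutes the result; this equals
    an exhaustive search over contiguous anchor runs under the same
    recurrence.
    """
    if not anchors:
        return None
    best: Optional[Tuple[int, int, int]] = None  # (S, start, end-inclusive)
    start = 0
    S = anchors[0].length
    if best is None or S > best[0]:
        best = (S, start, 0)
    for i in range(1, len(anchors)):
        nxt = anchors[i]
        S_new = S + nxt.length - _anchor_distance(anchors[i - 1], nxt)
        if S_new < nxt.length:
            start = i
            S = nxt.length
        else:
            S = S_new
        if S > best[0]:
            best = (S, start, i)
    S, a, b = best
    block = list(anchors[a : b + 1])
    return ChainBlock(
        anchors=block,
        S=S,
        q_span=(block[0].qpos, max(x.qend for x in block)),
        t_span=(min(x.tpos for x in block), max(x.tend for x in block)),
    )


def _dominant_diagonal(anchors: List[Anchor], max_drift: int) -> List[Anchor]:
    """Keep the window's anchors on its heaviest diagonal band.

    Random z-mer collisions scatter across all diagonals and can
    outnumber the true collinear anchors, which cluster within the indel
    drift of one diagonal.  A two-pointer sweep over the sorted
    diagonals finds the band of width 2*max_drift carrying the most
    matched bases; anchors outside it are dropped before chaining.
    """
    if len(anchors) <= 1:
        return anchors
    diags = np.array([a.qpos - a.tpos for a in anchors], dtype=np.int64)
    lens = np.array([a.length for a in anchors], dtype=np.int64)
    order = np.argsort(diags, kind="stable")
    d_sorted = diags[order]
    l_sorted = lens[order]
    best_w = -1
    best_lo = d_sorted[0]
    j = 0
    w = 0
    for i in range(len(d_sorted)):
        if j < i:
            j = i
            w = 0
        while j < len(d_sorted) and d_sorted[j] - d_sorted[i] <= 2 * max_drift:
            w += int(l_sorted[j])
            j += 1
        if w > best_w:
            best_w = w
            best_lo = int(d_sorted[i])
        w -= int(l_sorted[i])
    lo, hi = best_lo, best_lo + 2 * max_drift
    kept = [a for a, d in zip(anchors, diags) if lo <= int(d) <= hi]
    return kept if kept else anchors


def _covered(anchors: Sequence[Anchor]) -> int:
    """Union length of anchor intervals on the query."""
    cov = 0
    end = -1
    for a in sorted(anchors, key=lambda x: x.qpos):
        s, e = a.qpos, a.qend
        if s > end:
            cov += e - s
            end = e
        elif e > end:
            cov += e - end
            end = e
    return cov


@dataclass
class WindowChain:
    """The selected collinear window blocks for one candidate pair."""

    blocks: List[ChainBlock]
    total_coverage: int
    strand: str


def chain_query(
    query: HPCRead,
    target: HPCRead,
    strand: str,
    params: OverlapParams = None,
    anchors: Optional[List[Anchor]] = None,
) -> Optional[WindowChain]:
    """Window-level chaining of a candidate pair; None if it fails filters.

    The query is tiled into sliding windows of window_size HPC bases
    stepping by half a window.  Windows whose raw z-mer matched length
    falls short of min_window_match are dropped outright; surviving
    windows are chained internally (on their dominant diagonal band),
    kept if their best block covers more than min_window_block query
    bases, then the window blocks themselves are chained with the same
    recurrence.  The winning window chain must cover more than
    min_total distinct query bases in all.
    """
    if params is None:
        params = OverlapParams()
    if anchors is None:
        anchors = extract_anchors(query, target, strand, params.z)
    if not anchors:
        return None
    y = params.window_size
    step = max(1, y // 2)
    windows: Dict[int, List[Anchor]] = {}
    for a in anchors:
        w_hi = a.qpos // step
        for w in (w_hi - 1, w_hi):
            if w >= 0 and w * step <= a.qpos < w * step + y:
                windows.setdefault(w, []).append(a)
    win_blocks: List[Tuple[int, ChainBlock, int]] = []
    for w in sorted(windows):
        ws = windows[w]
        if _covered(ws) < params.min_window_match:
            continue
        ws = _dominant_diagonal(ws, params.max_diag_drift)
        block = chain_window(ws)
        if block is None:
            continue
        cov = _covered(block.anchors)
        if cov > params.min_window_block:
            win_blocks.append((w, block, cov))
    if not win_blocks:
        return None
    # chain the surviving windows as super-anchors with L = block coverage
    supers = [
        Anchor(qpos=b.q_span[0], tpos=b.t_span[0],
               length=cov, strand=strand)
        for _, b, cov in win_blocks
    ]
    # distances between window blocks = diagonal drift of their spans
    best = (supers[0].length, 0, 0)  # (S, start, end-inclusive)
    start = 0
    S = supers[0].length
    for i in range(1, len(supers)):
        prev_b = win_blocks[i - 1][1]
        next_b = win_blocks[i][1]
        qgap = next_b.q_span[0] - prev_b.q_span[1]
        tgap = next_b.t_span[0] - prev_b.t_span[1]
        dist = abs(tgap - qgap)
        S_new = S + supers[i].length - dist
        if S_new < supers[i].length:
            start = i
            S = supers[i].length
        else:
            S = S_new
        if S > best[0]:
            best = (S, start, i)
    _, a, b = best
    chosen = win_blocks[a : b + 1]
    # overlapping windows share anchors; count distinct covered bases
    total = _covered([an for _, blk, _ in chosen for an in blk.anchors])
    if total <= params.min_total:
        return None
    return WindowChain(blocks=[blk for _, blk, _ in chosen],
                       total_coverage=total, strand=strand)


# ---------------------------------------------------------------------------
# Repeat-depth weighting
# ---------------------------------------------------------------------------

@dataclass
class DepthWeights:
    """Per-query-base repeat weights derived from candidate seed depth."""

    weights: np.ndarray
    low_depth: int = 10
    high_depth: int = 100


def depth_weight(depth, low: int = 10, high: int = 100):
    """Weight 1 at depth <= low, 0 at depth >= high, linear between."""
    d = np.asarray(depth, dtype=np.float64)
    w = (high - d) / (high - low)
    return np.clip(w, 0.0, 1.0)


def compute_depth_weights(
    query: HPCRead,
    hits: Sequence[CandidateHit],
    low_depth: int = 10,
    high_depth: int = 100,
) -> DepthWeights:
    """Per-base depth = number of candidates whose seeds cover the base."""
    n = len(query.hseq)
    diff = np.zeros(n + 1, dtype=np.int64)
    for h in hits:
        for s, e in h.intervals:
            diff[s] += 1
            diff[min(e, n)] -= 1
    depth = np.cumsum(diff[:n])
    return DepthWeights(depth_weight(depth, low_depth, high_depth),
                        low_depth, high_depth)


def weighted_coverage(hit: CandidateHit, weights: DepthWeights) -> float:
    return float(sum(weights.weights[s:e].sum() for s, e in hit.intervals))


# ---------------------------------------------------------------------------
# Alignment of a chained pair
# ---------------------------------------------------------------------------

def banded_global_align(
    a: str, b: str, band: int, scoring: Scoring = DEFAULT_SCORING
) -> Tuple[int, str]:
    """Banded end-to-end alignment of two sequences; (score, edit script).

    The band constrains |i - j - diag| around the (0,0)-(len a, len b)
    diagonal; with band >= max(len a, len b) the result equals unbanded
    global DP.  Ops: '='/'X' consume both, 'D' consumes `a`, 'I' consumes
    `b`.
    """
    score, runs, _ = global_align(a, b, band, scoring)
    return score, runs_to_script(runs)


def _monotone_anchors(blocks: Sequence[ChainBlock]) -> List[Anchor]:
    """Flatten window blocks into a strictly collinear anchor list.

    Later anchors are trimmed from the front where they overlap the
    previous anchor on either coordinate (exact matches stay exact under
    equal trimming); anchors made empty or stepping backwards are dropped.
    """
    out: List[Anchor] = []
    for blk in blocks:
        for a in blk.anchors:
            if not out:
                out.append(replace(a))
                continue
            prev = out[-1]
            if a.qpos < prev.qpos or a.tpos < prev.tpos:
                continue
            delta = max(0, prev.qend - a.qpos, prev.tend - a.tpos)
            if delta >= a.length:
                continue
            out.append(Anchor(a.qpos + delta, a.tpos + delta,
                              a.length - delta, a.strand))
    return out


def _merge_runs(parts: List[List[Tuple[int, str]]]) -> List[Tuple[int, str]]:
    merged: List[Tuple[int, str]] = []
    for runs in parts:
        for n, op in runs:
            if n <= 0:
                continue
            if merged and merged[-1][1] == op:
                merged[-1] = (merged[-1][0] + n, op)
            else:
                merged.append((n, op))
    return merged


_OP_CHARS = np.array(["=", "D", "I"])


def _anchor_runs(qh: HPCRead, th: HPCRead, a: Anchor) -> List[Tuple[int, str]]:
    """Decompress an HPC anchor into raw-space runs.

    HPC-equal positions may have different raw run lengths; each position
    contributes min(run_q, run_t) matches plus the surplus as a gap.
    """
    rq = qh.runs[a.qpos : a.qend]
    rt = th.runs[a.tpos : a.tend]
    m = np.minimum(rq, rt)
    cnt = np.empty(3 * len(m), dtype=np.int64)
    cnt[0::3] = m
    cnt[1::3] = rq - m
    cnt[2::3] = rt - m
    ops = np.empty(3 * len(m), dtype=np.int8)
    ops[0::3] = 0
    ops[1::3] = 1
    ops[2::3] = 2
    keep = cnt > 0
    cnt = cnt[keep]
    ops = ops[keep]
    if len(cnt) == 0:
        return []
    # merge adjacent equal ops (consecutive '=' runs in the common case)
    brk = np.flatnonzero(np.concatenate(([True], ops[1:] != ops[:-1])))
    sums = np.add.reduceat(cnt, brk)
    return list(zip(sums.tolist(), _OP_CHARS[ops[brk]].tolist()))


def _identity(runs: Sequence[Tuple[int, str]]) -> float:
    match = sum(n for n, op in runs if op == "=")
    total = sum(n for n, op in runs)
    return match / total if total else 0.0


def align_pair(
    qread: Read,
    qh: HPCRead,
    tread: Read,
    th_oriented: HPCRead,
    traw_oriented: str,
    chain: WindowChain,
    params: OverlapParams = None,
) -> Optional[OverlapRecord]:
    """Turn a window chain into a base-level OverlapRecord (or None).

    `th_oriented`/`traw_oriented` are the target in the chain's
    orientation; output coordinates are converted back to the target's
    forward strand.  Returns None when the stitched identity falls below
    the emission floor.
    """
    if params is None:
        params = OverlapParams()
    if chain is None:
        return None
    anchors = _monotone_anchors(chain.blocks)
    if not anchors:
        return None
    sc = params.scoring
    parts: List[List[Tuple[int, str]]] = []
    # anchors + gap fills
    prev_qe = prev_te = None
    first_qs, first_ts = hpc_to_raw(qh, anchors[0].qpos, anchors[0].qpos)[0], None
    for i, a in enumerate(anchors):
        qs, qe = hpc_to_raw(qh, a.qpos, a.qend)
        ts, te = hpc_to_raw(th_oriented, a.tpos, a.tend)
        if i == 0:
            first_qs, first_ts = qs, ts
        else:
            qgap = qread.seq[prev_qe:qs]
            tgap = traw_oriented[prev_te:ts]
            if qgap or tgap:
                if not qgap:
                    parts.append([(len(tgap), "I")])
                elif not tgap:
                    parts.append([(len(qgap), "D")])
                else:
                    _, runs = global_align_sched(
                        qgap, tgap, params.min_band, params.max_band, sc)
                    parts.append(runs)
        parts.append(_anchor_runs(qh, th_oriented, a))
        prev_qe, prev_te = qe, te
    # end extensions to the nearer read end (band fixed at end_band)
    _, lruns, qu, tu = extend_align_full(
        qread.seq[:first_qs][::-1], traw_oriented[:first_ts][::-1],
        params.end_band, sc, zdrop=params.end_drop)
    lqs, lts = first_qs - qu, first_ts - tu
    left = [(n, op) for n, op in reversed(lruns)]
    _, rruns, qv, tv = extend_align_full(
        qread.seq[prev_qe:], traw_oriented[prev_te:], params.end_band, sc,
        zdrop=params.end_drop)
    rqe, rte = prev_qe + qv, prev_te + tv
    runs = _merge_runs([left] + parts + [rruns])
    # an alignment must not start or end in an indel (HPC anchors cut at a
    # read boundary mid-homopolymer can leave one)
    while runs and runs[0][1] != "=":
        n, op = runs.pop(0)
        if op in "=XD":
            lqs += n
        if op in "=XI":
            lts += n
    while runs and runs[-1][1] != "=":
        n, op = runs.pop()
        if op in "=XD":
            rqe -= n
        if op in "=XI":
            rte -= n
    if not runs:
        return None
    identity = _identity(runs)
    if identity < params.min_identity:
        return None
    score = sc.score_runs(runs)
    tlen = len(traw_oriented)
    if chain.strand == "+":
        tstart, tend = lts, rte
    else:
        tstart, tend = tlen - rte, tlen - lts
    rec = OverlapRecord(
        qid=qread.read_id, tid=th_oriented.read_id, strand=chain.strand,
        qstart=lqs, qend=rqe, tstart=tstart, tend=tend,
        qlen=qread.length, tlen=tlen,
        score=score, identity=identity,
        edit_script=runs_to_script(runs),
    )
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# All-vs-all driver
# ---------------------------------------------------------------------------

class _ReadCache:
    """Lazily computed per-read oriented HPC structures and z-mer codes."""

    def __init__(self, reads: Sequence[Read], z: int):
        self.reads = reads
        self.z = z
        self._hpc: Dict[int, HPCRead] = {}
        self._hpc_rc: Dict[int, HPCRead] = {}
        self._raw_rc: Dict[int, str] = {}
        self._zcodes: Dict[Tuple[int, str], tuple] = {}

    def hpc(self, rid: int) -> HPCRead:
        if rid not in self._hpc:
            self._hpc[rid] = hpc_compress(self.reads[rid].seq, rid)
        return self._hpc[rid]

    def raw_rc(self, rid: int) -> str:
        if rid not in self._raw_rc:
            self._raw_rc[rid] = revcomp(self.reads[rid].seq)
        return self._raw_rc[rid]

    def hpc_rc(self, rid: int) -> HPCRead:
        if rid not in self._hpc_rc:
            self._hpc_rc[rid] = hpc_compress(self.raw_rc(rid), rid)
        return self._hpc_rc[rid]

    def zcodes(self, rid: int, strand: str):
        key = (rid, strand)
        if key not in self._zcodes:
            h = self.hpc(rid) if strand == "+" else self.hpc_rc(rid)
            self._zcodes[key] = _kmer_codes(h.hseq, self.z)
        return self._zcodes[key]


def overlap_all(
    reads: Sequence[Read],
    params: OverlapParams = None,
    index: Optional[KmerIndex] = None,
) -> List[OverlapRecord]:
    """All-vs-all overlap detection over a read set.

    Every read serves as a query against the shared index; candidates are
    ranked by repeat-weighted seed coverage before the top-A cut, chained,
    and aligned.  Each unordered pair is reported at most once (qid < tid;
    if both strands yield records the higher-scoring one wins).
    """
    if params is None:
        params = OverlapParams()
    cache = _ReadCache(reads, params.z)
    hreads = [cache.hpc(r.read_id) for r in reads]
    if index is None:
        index = build_index(hreads, params.k, params.max_kmer_count,
                            params.subsample_denominator)
    results: Dict[Tuple[int, int], OverlapRecord] = {}
    for q in reads:
        qh = cache.hpc(q.read_id)
        hits = find_candidates(index, qh, params.min_coverage,
                               max_candidates=len(reads) * 2)
        if not hits:
            continue
        weights = compute_depth_weights(qh, hits, params.low_depth,
                                        params.high_depth)
        scored = [(weighted_coverage(h, weights), h) for h in hits]
        scored = [(w, h) for w, h in scored if w > 0]
        scored.sort(key=lambda x: (-x[0], x[1].tid, x[1].strand))
        for _, hit in scored[: params.max_candidates]:
            if (min(q.read_id, hit.tid), max(q.read_id, hit.tid)) in results:
                continue  # already found from the other side
            strand = hit.strand
            th = cache.hpc(hit.tid) if strand == "+" else cache.hpc_rc(hit.tid)
            anchors = extract_anchors(
                qh, th, strand, params.z,
                _qcodes=cache.zcodes(q.read_id, "+"),
                _tcodes=cache.zcodes(hit.tid, strand),
            )
            chain = chain_query(qh, th, strand, params, anchors=anchors)
            if chain is None:
                continue
            traw = reads[hit.tid].seq if strand == "+" else cache.raw_rc(hit.tid)
            rec = align_pair(q, qh, reads[hit.tid], th, traw, chain, params)
            if rec is None:
                continue
            if rec.qid > rec.tid:
                rec = _mirror_record(rec)
            key = (rec.qid, rec.tid)
            old = results.get(key)
            if old is None or rec.score > old.score:
                results[key] = rec
    return [results[k] for k in sorted(results)]


def _mirror_record(rec: OverlapRecord) -> OverlapRecord:
    """Swap query/target roles so qid < tid in the emitted record."""
    runs = [(n, {"=": "=", "X": "X", "D": "I", "I": "D"}[op])
            for n, op in _parse_runs(rec.edit_script)]
    if rec.strand == "-":
        runs = runs[::-1]
    return OverlapRecord(
        qid=rec.tid, tid=rec.qid, strand=rec.strand,
        qstart=rec.tstart, qend=rec.tend, tstart=rec.qstart, tend=rec.qend,
        qlen=rec.tlen, tlen=rec.qlen,
        score=rec.score, identity=rec.identity,
        edit_script=runs_to_script(runs),
    )


def _parse_runs(script: str):
    from .io_formats import parse_script
    return parse_script(script)
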