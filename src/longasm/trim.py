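"""Read trimming and chimera removal from overlap pileups.

Each read is treated as a reference and every overlap touching it is tiled
onto it.  Low-support ends are clipped away; internal alignment termini
("spurs") are classified as chimeric junctions or sequencing error using
three depth rules; reads bridging two otherwise-disconnected clusters of
the overlap graph are discarded as chimeras; surviving overlaps are
re-projected onto the kept intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .io_formats import OverlapRecord, Read, parse_script, ValidationError


@dataclass
class TrimParams:
    # a base is kept when at least one valid overlap covers it: the kept
    # interval is the extent of the read's valid overlaps.  Requiring
    # depth 2 instead discards every genome region that only one read
    # pair spans — at 30x with 5-kb reads that is ~300 bases at each
    # genome end, a structural coverage loss.
    min_depth: int = 1  # minimum pileup depth kept after end clipping
    spur_margin: int = 50  # alignment end this far from both read ends = spur
    spur_window: int = 50  # +- window for counting partial alignments at a spur
    min_clipped_span: int = 300  # overlaps shorter than this after clipping drop
    end_exclusion: int = 50  # ignore spurs this close to the kept-interval edge
    min_spur_support: int = 3  # partial alignments needed to call a spur site
    min_side_reads: int = 3  # component size on each side for graph chimeras


@dataclass
class Pileup:
    """Depth profile and internal alignment termini of one read."""

    read_id: int
    length: int
    depth: np.ndarray
    spurs: List[int] = field(default_factory=list)


@dataclass
class TrimResult:
    read_id: int
    kept: Optional[Tuple[int, int]]
    chimeric: bool
    reason: str  # clean | clipped | spur_chimera | graph_chimera | discarded_low_support


def _interval_on(rec: OverlapRecord, rid: int) -> Tuple[int, int]:
    """The overlap interval on read rid (forward coordinates)."""
    if rec.qid == rid:
        return rec.qstart, rec.qend
    if rec.tid == rid:
        return rec.tstart, rec.tend
    raise ValueError(f"overlap ({rec.qid},{rec.tid}) does not touch read {rid}")


def _spur_termini(rec: OverlapRecord, rid: int, margin: int) -> List[int]:
    """Alignment termini on read rid that are internal on BOTH reads.

    In a genuine tiling every overlap terminus coincides with one read's
    physical end; a terminus sitting mid-read on both partners means the
    alignment broke off — the signature of a chimeric junction or a local
    error.
    """
    if rec.qid == rid:
        mine = (rec.qstart, rec.qend)
        mylen = rec.qlen
        theirs = (rec.tstart, rec.tend) if rec.strand == "+" \
            else (rec.tend, rec.tstart)
        theirlen = rec.tlen
    else:
        mine = (rec.tstart, rec.tend) if rec.strand == "+" \
            else (rec.tend, rec.tstart)
        mylen = rec.tlen
        theirs = (rec.qstart, rec.qend)
        theirlen = rec.qlen
    out = []
    for p, q in zip(mine, theirs):
        if margin < p < mylen - margin and margin < q < theirlen - margin:
            out.append(p)
    return out


def build_pileup(read: Read, overlaps: Sequence[OverlapRecord],
                 spur_margin: int = 50) -> Pileup:
    """Tile overlap intervals onto the read; record spur termini.

    Depth at base x counts the overlap intervals containing x.  A spur is
    an alignment terminus more than spur_margin bases from the ends of
    both reads involved (see _spur_termini).
    """
    n = read.length
    diff = np.zeros(n + 1, dtype=np.int64)
    spurs: List[int] = []
    for rec in overlaps:
        s, e = _interval_on(rec, read.read_id)
        diff[s] += 1
        diff[e] -= 1
        spurs.extend(_spur_termini(rec, read.read_id, spur_margin))
    return Pileup(read.read_id, n, np.cumsum(diff[:n]), sorted(spurs))


def clip_ends(pileup: Pileup, min_depth: int = 1) -> Optional[Tuple[int, int]]:
    """Longest contiguous interval with depth >= min_depth; None if empty."""
    ok = pileup.depth >= min_depth
    if not ok.any():
        return None
    edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    i = int(np.argmax(ends - starts))
    return int(starts[i]), int(ends[i])


def classify_spur(m: int, n: int, avg_depth: float) -> str:
    """Chimera call at a spur from crossing depth m and partial count n.

    Chimeric iff m < avg/2, or n > avg, or n > m/2; otherwise the spur is
    attributed to sequencing error.
    """
    if m < avg_depth / 2 or n > avg_depth or n > m / 2:
        return "chimeric"
    return "sequencing_error"


def _spur_counts(pileup: Pileup, overlaps: Sequence[OverlapRecord],
                 rid: int, pos: int, window: int,
                 margin: int = 50) -> Tuple[int, int]:
    """(m, n) at a spur position.

    m = overlaps whose interval strictly contains the position (reads
    crossing it); n = spur-type termini within +-window of it (partial
    alignments stopping there).
    """
    m = n = 0
    for rec in overlaps:
        s, e = _interval_on(rec, rid)
        if s < pos < e:
            m += 1
        for p in _spur_termini(rec, rid, margin):
            if abs(p - pos) <= window:
                n += 1
                break
    return m, n


def overlap_graph(read_ids: Sequence[int],
                  overlaps: Sequence[OverlapRecord]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(read_ids)
    keep = set(read_ids)
    for rec in overlaps:
        if rec.qid in keep and rec.tid in keep:
            g.add_edge(rec.qid, rec.tid)
    return g


def graph_chimera_check(read_ids: Sequence[int],
                        overlaps: Sequence[OverlapRecord],
                        min_side_reads: int = 3,
                        margin: int = 50) -> Set[int]:
    """Reads bridging two otherwise-disconnected clusters through
    disjoint arms.

    A read is flagged iff it is a cut vertex of the overlap graph whose
    removal leaves at least two components each holding >=
    min_side_reads reads (protecting interiors of short genuine tilings)
    AND the overlap intervals its two neighbor groups occupy on the read
    are disjoint — the two clusters touch different parts of the read,
    the physical signature of a chimeric join.  A cut vertex by
    construction has no alternative bypass path.
    """
    g = overlap_graph(read_ids, overlaps)
    by_read: Dict[int, List[OverlapRecord]] = {}
    for rec in overlaps:
        by_read.setdefault(rec.qid, []).append(rec)
        by_read.setdefault(rec.tid, []).append(rec)
    flagged: Set[int] = set()
    for v in nx.articulation_points(g):
        h = g.copy()
        h.remove_node(v)
        comps = [c for c in nx.connected_components(h)
                 if c & set(g.neighbors(v))]
        big = [c for c in comps if len(c) >= min_side_reads]
        if len(big) < 2:
            continue
        spans = []
        for c in big:
            ivs = [_interval_on(rec, v) for rec in by_read.get(v, [])
                   if (rec.qid in c) or (rec.tid in c)]
            if ivs:
                spans.append((min(s for s, _ in ivs), max(e for _, e in ivs)))
        disjoint = any(
            a[1] <= b[0] + margin or b[1] <= a[0] + margin
            for i, a in enumerate(spans) for b in spans[i + 1:]
        )
        if disjoint:
            flagged.add(v)
    return flagged


# ---------------------------------------------------------------------------
# Overlap re-projection onto kept intervals
# ---------------------------------------------------------------------------

def _clip_record_query(rec: OverlapRecord, lo: int, hi: int) -> Optional[OverlapRecord]:
    """Restrict a record's query interval to [lo, hi), walking the script.

    The result starts and ends on aligned columns (leading/trailing indel
    runs are stripped); target coordinates follow from the script walk.
    """
    lo = max(lo, rec.qstart)
    hi = min(hi, rec.qend)
    if hi <= lo:
        return None
    runs = parse_script(rec.edit_script)
    q = rec.qstart
    t = 0  # offset into the (oriented) target span
    out: List[Tuple[int, str]] = []
    q_lo = q_hi = t_lo = t_hi = None
    for n, op in runs:
        dq = n if op in "=XD" else 0
        dt = n if op in "=XI" else 0
        if op in "=X":
            s = max(q, lo)
            e = min(q + dq, hi)
            if e > s:
                if q_lo is None:
                    q_lo = s
                    t_lo = t + (s - q)
                q_hi = e
                t_hi = t + (e - q)
                out.append((e - s, op))
        elif op == "D":
            s = max(q, lo)
            e = min(q + dq, hi)
            if e > s and q_lo is not None:
                out.append((e - s, op))
        else:  # I
            if q_lo is not None and q < hi:
                out.append((n, op))
        q += dq
        t += dt
        if q >= hi:
            break
    if not out or q_lo is None:
        return None
    # strip trailing indels (they do not move the kept column bounds)
    while out and out[-1][1] in "ID":
        out.pop()
    if not out or q_hi <= q_lo or t_hi <= t_lo:
        return None
    if rec.strand == "+":
        ts, te = rec.tstart + t_lo, rec.tstart + t_hi
    else:
        ts, te = rec.tend - t_hi, rec.tend - t_lo
    from ._align import runs_to_script
    match = sum(n for n, op in out if op == "=")
    total = sum(n for n, op in out)
    return OverlapRecord(
        qid=rec.qid, tid=rec.tid, strand=rec.strand,
        qstart=q_lo, qend=q_hi, tstart=ts, tend=te,
        qlen=rec.qlen, tlen=rec.tlen,
        score=rec.score, identity=match / total,
        edit_script=runs_to_script(out),
    )


def _swap_record(rec: OverlapRecord) -> OverlapRecord:
    """Mirror a record so query and target roles are exchanged."""
    runs = parse_script(rec.edit_script)
    swapped = [(n, {"=": "=", "X": "X", "D": "I", "I": "D"}[op]) for n, op in runs]
    if rec.strand == "-":
        swapped = swapped[::-1]
    from ._align import runs_to_script
    return OverlapRecord(
        qid=rec.tid, tid=rec.qid, strand=rec.strand,
        qstart=rec.tstart, qend=rec.tend,
        tstart=rec.qstart, tend=rec.qend,
        qlen=rec.tlen, tlen=rec.qlen,
        score=rec.score, identity=rec.identity,
        edit_script=runs_to_script(swapped),
    )


def clip_overlap(rec: OverlapRecord,
                 kept: Dict[int, Optional[Tuple[int, int]]],
                 min_span: int = 300) -> Optional[OverlapRecord]:
    """Project a record onto both reads' kept intervals; None if too short."""
    kq = kept.get(rec.qid)
    kt = kept.get(rec.tid)
    if kq is None or kt is None:
        return None
    out = _clip_record_query(rec, kq[0], kq[1])
    if out is None:
        return None
    sw = _clip_record_query(_swap_record(out), kt[0], kt[1])
    if sw is None:
        return None
    out = _swap_record(sw)
    if out.qend - out.qstart < min_span or out.tend - out.tstart < min_span:
        return None
    try:
        out.validate()
    except ValidationError:
        return None
    return out


def trim_all(
    reads: Sequence[Read],
    overlaps: Sequence[OverlapRecord],
    params: TrimParams = None,
) -> Tuple[List[TrimResult], List[OverlapRecord]]:
    """Full trimming pipeline; returns per-read results + clipped overlaps.

    Order: end clipping by pileup depth, spur classification (average
    depth taken over the read's connected component), graph chimera
    check, then re-projection of surviving overlaps onto kept intervals.
    """
    if params is None:
        params = TrimParams()
    by_read: Dict[int, List[OverlapRecord]] = {r.read_id: [] for r in reads}
    for rec in overlaps:
        by_read[rec.qid].append(rec)
        by_read[rec.tid].append(rec)
    pileups = {r.read_id: build_pileup(r, by_read[r.read_id], params.spur_margin)
               for r in reads}
    # component-wise average depth
    g = overlap_graph([r.read_id for r in reads], overlaps)
    comp_avg: Dict[int, float] = {}
    for comp in nx.connected_components(g):
        means = [float(pileups[rid].depth.mean()) for rid in comp
                 if pileups[rid].length > 0]
        avg = float(np.mean(means)) if means else 0.0
        for rid in comp:
            comp_avg[rid] = avg
    results: Dict[int, TrimResult] = {}
    for r in reads:
        pile = pileups[r.read_id]
        kept = clip_ends(pile, params.min_depth)
        if kept is None:
            results[r.read_id] = TrimResult(r.read_id, None, False,
                                            "discarded_low_support")
            continue
        avg = comp_avg.get(r.read_id, 0.0)
        chimeric = False
        if avg > 0:
            for pos in pile.spurs:
                # noisy alignments stop a few hundred bases short of the
                # read ends; termini near the kept boundary are trimming
                # artifacts, not junction evidence
                if not (kept[0] + params.end_exclusion < pos
                        < kept[1] - params.end_exclusion):
                    continue
                m, n = _spur_counts(pile, by_read[r.read_id], r.read_id,
                                    pos, params.spur_window,
                                    params.spur_margin)
                # a junction forces every spanning alignment to stop; a
                # lone terminus is a local alignment hiccup, not a site
                if n < params.min_spur_support:
                    continue
                if classify_spur(m, n, avg) == "chimeric":
                    chimeric = True
                    break
        if chimeric:
            results[r.read_id] = TrimResult(r.read_id, None, True, "spur_chimera")
        else:
            reason = "clean" if kept == (0, r.length) else "clipped"
            results[r.read_id] = TrimResult(r.read_id, kept, False, reason)
    survivors = [rid for rid, t in results.items() if t.kept is not None]
    flagged = graph_chimera_check(survivors, overlaps, params.min_side_reads)
    for rid in flagged:
        results[rid] = TrimResult(rid, None, True, "graph_chimera")
    kept_map = {rid: t.kept for rid, t in results.items()}
    clipped: List[OverlapRecord] = []
    for rec in overlaps:
        out = clip_overlap(rec, kept_map, params.min_clipped_span)
        if out is not None:
            clipped.append(out)
    ordered = [results[r.read_id] for r in reads]
    return ordered, clipped
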