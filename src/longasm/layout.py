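"""Best-Overlap-Graph layout of trimmed reads into unitigs.

Overlaps are first classified by geometry (dovetail / contained /
containing / internal) against the reads' kept intervals.  For each read
end only near-best dovetail edges compete — candidates within ratio r of
the end's best alignment score — and the longest overlap among them is
selected; an edge survives only if selected from both of its endpoints.
Since every read end then carries at most one edge, the graph decomposes
into simple paths (and rare cycles), which become unitigs.  Unitigs whose
reads are largely cross-linked to a longer unitig are filtered out as
redundant; contained reads are re-inserted into their container's tiling
for consensus depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .io_formats import (
    LayoutEntry,
    LayoutFile,
    LayoutUnitig,
    OverlapRecord,
    Read,
    ValidationError,
)


@dataclass
class LayoutParams:
    slack: int = 100  # dovetail unaligned-end tolerance (-w)
    near_best_ratio: float = 0.95  # candidate-set score ratio (-r)
    max_shared: float = 0.40  # redundant-unitig overlap fraction


def classify_overlap(
    rec: OverlapRecord,
    q_bounds: Tuple[int, int],
    t_bounds: Tuple[int, int],
    slack: int = 100,
) -> str:
    """Geometry class of an overlap relative to the reads' kept intervals.

    Overhangs are measured in the query-oriented frame; 'contained' means
    the query is spanned by the target, 'containing' the reverse; a
    dovetail joins compatible ends (query right to target left or query
    left to target right) with at most `slack` unaligned bases on each;
    anything else is 'internal'.
    """
    ql = rec.qstart - q_bounds[0]
    qr = q_bounds[1] - rec.qend
    if rec.strand == "+":
        tl = rec.tstart - t_bounds[0]
        tr = t_bounds[1] - rec.tend
    else:
        # in query orientation, the target's left overhang is its right end
        tl = t_bounds[1] - rec.tend
        tr = rec.tstart - t_bounds[0]
    q_full = ql <= slack and qr <= slack
    t_full = tl <= slack and tr <= slack
    if q_full and t_full:
        return "contained" if rec.qlen <= rec.tlen else "containing"
    if q_full:
        return "contained"
    if t_full:
        return "containing"
    if (qr <= slack and tl <= slack) or (ql <= slack and tr <= slack):
        return "dovetail"
    return "internal"


@dataclass
class BogEdge:
    """A dovetail edge joining two read ends.

    Ends are 'L' (kept-interval start) or 'R' in each read's forward
    frame; length is the mean aligned span of the two sides.
    """

    a_id: int
    a_end: str
    b_id: int
    b_end: str
    overlap: OverlapRecord
    score: int
    length: int

    def end_of(self, rid: int) -> str:
        return self.a_end if rid == self.a_id else self.b_end

    def other(self, rid: int) -> int:
        return self.b_id if rid == self.a_id else self.a_id


def _dovetail_ends(rec: OverlapRecord,
                   q_bounds: Tuple[int, int],
                   t_bounds: Tuple[int, int],
                   slack: int) -> Optional[Tuple[str, str]]:
    """Which end of each read the dovetail joins, in forward frames."""
    ql = rec.qstart - q_bounds[0]
    qr = q_bounds[1] - rec.qend
    if rec.strand == "+":
        tl = rec.tstart - t_bounds[0]
        tr = t_bounds[1] - rec.tend
    else:
        tl = t_bounds[1] - rec.tend
        tr = rec.tstart - t_bounds[0]
    # prefer the junction with the smaller total overhang
    right = qr + tl  # query suffix joins target prefix (query-oriented)
    left = ql + tr
    use_right = (qr <= slack and tl <= slack) and (
        not (ql <= slack and tr <= slack) or right <= left)
    if use_right:
        q_end = "R"
        t_end_oriented = "L"
    elif ql <= slack and tr <= slack:
        q_end = "L"
        t_end_oriented = "R"
    else:
        return None
    if rec.strand == "-":
        t_end = "R" if t_end_oriented == "L" else "L"
    else:
        t_end = t_end_oriented
    return q_end, t_end


def build_bog(
    overlaps: Sequence[OverlapRecord],
    bounds: Dict[int, Tuple[int, int]],
    params: LayoutParams = None,
) -> Tuple[List[BogEdge], Dict[int, int]]:
    """Select at most one mutual near-best dovetail edge per read end.

    Returns (selected edges, containment map
    contained_read -> (container, overlap record)).
    Candidates at an end are edges with score >= r * best score there;
    among candidates the longest overlap wins (ties: higher score, then
    smaller partner read id).
    """
    if params is None:
        params = LayoutParams()
    contained: Dict[int, Tuple[int, OverlapRecord]] = {}
    edges: List[BogEdge] = []
    for rec in overlaps:
        if rec.qid not in bounds or rec.tid not in bounds:
            continue
        cls = classify_overlap(rec, bounds[rec.qid], bounds[rec.tid],
                               params.slack)
        if cls == "contained":
            contained.setdefault(rec.qid, (rec.tid, rec))
        elif cls == "containing":
            contained.setdefault(rec.tid, (rec.qid, rec))
        elif cls == "dovetail":
            ends = _dovetail_ends(rec, bounds[rec.qid], bounds[rec.tid],
                                  params.slack)
            if ends is None:
                continue
            edges.append(BogEdge(
                a_id=rec.qid, a_end=ends[0], b_id=rec.tid, b_end=ends[1],
                overlap=rec, score=rec.score,
                length=(rec.qspan + rec.tspan) // 2,
            ))
    # drop edges touching contained reads (they are placed, not path nodes)
    edges = [e for e in edges
             if e.a_id not in contained and e.b_id not in contained]
    per_end: Dict[Tuple[int, str], List[BogEdge]] = {}
    for e in edges:
        per_end.setdefault((e.a_id, e.a_end), []).append(e)
        per_end.setdefault((e.b_id, e.b_end), []).append(e)
    # iterated mutual-best: each round, every still-free end nominates its
    # longest near-best edge among edges whose other end is also free, and
    # reciprocal nominations are fixed.  The first round is the strict
    # mutual-best rule; later rounds pair up ends whose first choice was
    # claimed elsewhere, which would otherwise fragment the graph.
    used: set = set()
    mutual: List[BogEdge] = []
    while True:
        selected: Dict[Tuple[int, str], BogEdge] = {}
        for key, cand in per_end.items():
            if key in used:
                continue
            pool = [e for e in cand
                    if (e.a_id, e.a_end) not in used
                    and (e.b_id, e.b_end) not in used]
            if not pool:
                continue
            best_score = max(e.score for e in pool)
            rid = key[0]
            pool = [e for e in pool
                    if e.score >= params.near_best_ratio * best_score]
            pool.sort(key=lambda e: (-e.length, -e.score, e.other(rid)))
            selected[key] = pool[0]
        added = False
        for key in sorted(selected):
            e = selected[key]
            ka = (e.a_id, e.a_end)
            kb = (e.b_id, e.b_end)
            if ka in used or kb in used:
                continue
            if selected.get(ka) is e and selected.get(kb) is e:
                mutual.append(e)
                used.add(ka)
                used.add(kb)
                added = True
        if not added:
            break
    return mutual, contained


@dataclass
class Unitig:
    """An ordered, oriented read tiling.

    tiling rows are (read_id, strand, offset, role) with role 'path' for
    backbone-defining reads and 'contained' for placed contained reads.
    """

    unitig_id: str
    tiling: List[Tuple[int, str, int, str]] = field(default_factory=list)
    length: int = 0


def _advance(edge: BogEdge, rid: int, bounds) -> int:
    """Offset step from read rid to its partner along this edge."""
    rec = edge.overlap
    span_on_rid = rec.qspan if rid == rec.qid else rec.tspan
    lo, hi = bounds[rid]
    return max(1, (hi - lo) - span_on_rid)


def build_unitigs(
    edges: Sequence[BogEdge],
    bounds: Dict[int, Tuple[int, int]],
    contained: Optional[Dict[int, Tuple[int, OverlapRecord]]] = None,
) -> List[Unitig]:
    """Walk the degree-<=2 selected-edge graph into unitigs.

    Components are simple paths (cycles are broken at the smallest read
    id).  Orientation: a read entered through its 'L' end keeps '+',
    through its 'R' end becomes '-'; offsets accumulate each step by the
    read span minus the overlap span.  Contained reads are then placed
    inside their container using the containment record's coordinates,
    without altering the path.
    """
    if contained is None:
        contained = {}
    by_end: Dict[Tuple[int, str], BogEdge] = {}
    nodes: Set[int] = set(bounds) - set(contained)
    for e in edges:
        by_end[(e.a_id, e.a_end)] = e
        by_end[(e.b_id, e.b_end)] = e
    visited: Set[int] = set()
    unitigs: List[Unitig] = []

    def walk(start: int, first_end: str) -> List[Tuple[int, str]]:
        """Follow edges from `start`, leaving through `first_end` first."""
        path = []
        rid = start
        out_end = first_end
        strand = "+" if first_end == "R" else "-"
        path.append((rid, strand))
        visited.add(rid)
        while True:
            e = by_end.get((rid, out_end))
            if e is None:
                break
            nxt = e.other(rid)
            if nxt in visited:
                break
            enter = e.end_of(nxt)
            strand = "+" if enter == "L" else "-"
            path.append((nxt, strand))
            visited.add(nxt)
            rid = nxt
            out_end = "R" if enter == "L" else "L"
        return path

    for start in sorted(nodes):
        if start in visited:
            continue
        has_l = (start, "L") in by_end
        has_r = (start, "R") in by_end
        if has_l and has_r:
            continue  # interior or cycle node; handled from a terminal / later
        first = "R" if not has_l else "L"
        # orient terminals so traversal leaves through the edged end
        path = walk(start, "R" if has_r or not has_l else "L")
        unitigs.append(_path_to_unitig(path, by_end, bounds, len(unitigs)))
    # cycles: every remaining node has degree 2
    for start in sorted(nodes):
        if start in visited:
            continue
        path = walk(start, "R")
        unitigs.append(_path_to_unitig(path, by_end, bounds, len(unitigs)))
    # place contained reads inside their containers
    placement: Dict[int, Tuple[int, str, int]] = {}  # read -> (utg idx, strand, offset)
    for ui, u in enumerate(unitigs):
        for rid, strand, off, _ in u.tiling:
            placement[rid] = (ui, strand, off)
    pending = dict(contained)
    progress = True
    while pending and progress:
        progress = False
        for crid in sorted(pending):
            container, rec = pending[crid]
            if container not in placement:
                continue  # container itself contained; wait for its placement
            ui, c_strand, c_off = placement[container]
            pos = _place_contained(crid, container, rec, c_strand, c_off,
                                   bounds)
            if pos is not None:
                strand_c, off_c = pos
                unitigs[ui].tiling.append((crid, strand_c, off_c, "contained"))
                placement[crid] = (ui, strand_c, off_c)
            del pending[crid]
            progress = True
    for u in unitigs:
        u.tiling.sort(key=lambda t: (t[2], t[0]))
        u.length = max(
            off + (bounds[rid][1] - bounds[rid][0])
            for rid, _, off, _ in u.tiling
        )
    return unitigs


def _place_contained(crid: int, container: int, rec: OverlapRecord,
                     c_strand: str, c_off: int,
                     bounds) -> Optional[Tuple[str, int]]:
    """Unitig strand and offset of a contained read from its record."""
    if rec.qid == crid:
        my_iv = (rec.qstart, rec.qend)
        their_iv = (rec.tstart, rec.tend)
    else:
        my_iv = (rec.tstart, rec.tend)
        their_iv = (rec.qstart, rec.qend)
    lo_c, hi_c = bounds.get(container, (None, None))
    if lo_c is None or crid not in bounds:
        return None
    # start of the aligned region on the container, in unitig coordinates
    if c_strand == "+":
        u_pos = c_off + (their_iv[0] - lo_c)
    else:
        u_pos = c_off + (hi_c - their_iv[1])
    strand = c_strand if rec.strand == "+" else ("-" if c_strand == "+" else "+")
    # back off by the contained read's own unaligned margin
    my_lo, my_hi = bounds[crid]
    prefix = (my_iv[0] - my_lo) if strand == "+" else (my_hi - my_iv[1])
    return strand, max(0, u_pos - max(0, prefix))


def _path_to_unitig(path, by_end, bounds, idx) -> Unitig:
    tiling: List[Tuple[int, str, int, str]] = []
    off = 0
    prev = None
    for rid, strand in path:
        if prev is not None:
            p_rid, _ = prev
            # the edge between prev and rid
            e = None
            for end in ("L", "R"):
                cand = by_end.get((p_rid, end))
                if cand is not None and cand.other(p_rid) == rid:
                    e = cand
                    break
            off += _advance(e, p_rid, bounds)
        tiling.append((rid, strand, off, "path"))
        prev = (rid, strand)
    return Unitig(unitig_id=f"utg{idx:06d}", tiling=tiling)


def filter_redundant_unitigs(
    unitigs: Sequence[Unitig],
    overlaps: Sequence[OverlapRecord],
    bounds: Dict[int, Tuple[int, int]],
    max_shared: float = 0.40,
) -> List[Unitig]:
    """Drop unitigs largely cross-linked to a longer unitig.

    Sharing of A (the shorter) with B = fraction of A's tiled length
    contributed by reads of A having at least one overlap record to a
    read of B.  Processed in descending length; A is dropped when the
    fraction exceeds max_shared against any kept B.
    """
    partners: Dict[int, Set[int]] = {}
    for rec in overlaps:
        partners.setdefault(rec.qid, set()).add(rec.tid)
        partners.setdefault(rec.tid, set()).add(rec.qid)
    member: Dict[int, Set[int]] = {}
    for i, u in enumerate(unitigs):
        for rid, _, _, _ in u.tiling:
            member.setdefault(rid, set()).add(i)
    order = sorted(range(len(unitigs)),
                   key=lambda i: (-unitigs[i].length, unitigs[i].unitig_id))
    kept: List[int] = []
    for i in order:
        u = unitigs[i]
        total = sum(bounds[rid][1] - bounds[rid][0] for rid, _, _, _ in u.tiling)
        drop = False
        for j in kept:
            shared = 0
            for rid, _, _, _ in u.tiling:
                linked = j in member.get(rid, ()) or any(
                    j in member.get(p, ()) for p in partners.get(rid, ()))
                if linked:
                    shared += bounds[rid][1] - bounds[rid][0]
            if total and shared / total > max_shared:
                drop = True
                break
        if not drop:
            kept.append(i)
    kept_set = set(kept)
    return [u for i, u in enumerate(unitigs) if i in kept_set]


def emit_layout(
    unitigs: Sequence[Unitig],
    reads: Sequence[Read],
    bounds: Dict[int, Tuple[int, int]],
) -> LayoutFile:
    """Materialize unitigs as a validated LayoutFile."""
    by_id = {r.read_id: r for r in reads}
    layout = LayoutFile()
    for u in unitigs:
        entry_list = []
        for rid, strand, off, role in u.tiling:
            if rid not in by_id or rid not in bounds:
                raise ValidationError(f"unitig {u.unitig_id} references "
                                      f"unknown read {rid}")
            lo, hi = bounds[rid]
            entry_list.append(LayoutEntry(
                read_id=rid, strand=strand, offset=off,
                kept_start=lo, kept_end=hi, role=role,
            ))
        layout.unitigs.append(LayoutUnitig(unitig_id=u.unitig_id,
                                           entries=entry_list))
    layout.validate(reads)
    return layout


def layout_all(
    reads: Sequence[Read],
    clipped_overlaps: Sequence[OverlapRecord],
    kept: Dict[int, Optional[Tuple[int, int]]],
    params: LayoutParams = None,
) -> LayoutFile:
    """Full layout stage: BOG, unitigs, redundancy filter, layout file."""
    if params is None:
        params = LayoutParams()
    bounds = {rid: b for rid, b in kept.items() if b is not None}
    edges, contained = build_bog(clipped_overlaps, bounds, params)
    unitigs = build_unitigs(edges, bounds, contained)
    unitigs = filter_redundant_unitigs(unitigs, clipped_overlaps, bounds,
                                       params.max_shared)
    return emit_layout(unitigs, reads, bounds)
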