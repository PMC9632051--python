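"""DAG consensus polishing of unitig backbones.

Each unitig gets an uncorrected backbone stitched from its tiling reads;
every member read is realigned to its hinted backbone region with the
banded aligner and threaded through a backbone-anchored DAG whose nodes
are (backbone position, base) plus inserted-base nodes, with read-support
weights and per-column coverage.  The consensus is the heaviest
majority-margin path from the first to the last backbone column —
every base, insertion and deletion call is a plurality vote among the
reads spanning its column — repeated for a few rounds against the
previous call so indel votes consolidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._align import Scoring, glocal_align, runs_to_script
from .io_formats import (
    LayoutFile,
    LayoutUnitig,
    Read,
    parse_script,
    revcomp,
)


@dataclass
class ConsensusParams:
    band: int = 800  # alignment band and window slack around layout hints
    # random sequence pairs reach ~0.50 script identity under gap-cheap
    # scoring (the common-subsequence density of DNA), while genuinely
    # placed reads sit above ~0.7 even at 20% error; 0.6 separates them
    min_identity: float = 0.6  # reads below this vs their region are dropped
    rounds: int = 3  # realign reads to the previous round's consensus
    # indel-dominant error model: gaps cost little, mismatches a lot, so a
    # read's extra/missing base is always represented as the same indel
    # rather than sometimes as a mismatch, keeping votes on one DAG node
    scoring: Scoring = field(
        default_factory=lambda: Scoring(match=2, mismatch=-6,
                                        gap_open=-2, gap_ext=-2))


def backbone_of(unitig: LayoutUnitig, reads: Sequence[Read],
                junction_flank: int = 500,
                scoring: Scoring = None) -> str:
    """Stitch the unitig's uncorrected backbone from its tiling reads.

    Reads are taken in offset order; each contributes the part of its
    kept interval extending past the current backbone end (contained
    reads contribute nothing).  The layout offsets only approximate how
    much of the incoming read is already covered — pairwise indel noise
    shifts each junction by up to a few hundred bases, and a duplicated
    or missing chunk there becomes a near-repeat that consensus votes
    cannot cleanly remove.  Each junction is therefore refined by
    aligning the current backbone tail against the incoming read's
    prefix and cutting at the aligned endpoint; the offset arithmetic
    remains the fallback when the flank alignment is poor.
    """
    if not unitig.entries:
        raise ValueError("cannot build a backbone for an empty unitig")
    if scoring is None:
        scoring = Scoring()
    by_id = {r.read_id: r for r in reads}
    pieces: List[str] = []
    end = 0  # current backbone length in unitig coordinates
    tail = ""  # last bases of the stitched backbone
    entries = [e for e in unitig.entries if e.role == "path"] or unitig.entries
    for e in sorted(entries, key=lambda x: x.offset):
        r = by_id[e.read_id]
        seq = r.seq[e.kept_start : e.kept_end]
        if e.strand == "-":
            seq = revcomp(seq)
        span = len(seq)
        if e.offset + span <= end:
            continue
        start_in_read = max(0, end - e.offset)
        if 0 < start_in_read < span and tail:
            flank = tail[-junction_flank:]
            window_end = min(span, start_in_read + len(flank) + 400)
            prefix = seq[:window_end]
            score, runs, _, _, _, b_end = glocal_align(
                flank, prefix, 400, max(0, start_in_read - len(flank)),
                scoring)
            aligned = sum(n for n, op in runs if op in "=X")
            if aligned >= 0.5 * len(flank) and 0 < b_end < span:
                start_in_read = b_end
        pieces.append(seq[start_in_read:])
        tail = (tail + seq[start_in_read:])[-junction_flank:]
        end = e.offset + span if e.offset + span > end else end
    return "".join(pieces)


def align_to_backbone(
    read_seq: str,
    backbone: str,
    offset_hint: int,
    params: ConsensusParams = None,
) -> Optional[Tuple[int, int, int, str]]:
    """Align an oriented read interval to its hinted backbone region.

    Returns (backbone start, read start, read end, edit script); the
    script's query side is read_seq[read start:read end] — a read
    overhanging the backbone boundary keeps its overhang unaligned.
    The window spans offset_hint +- band, clipped to the backbone;
    alignment is banded with free window ends.
    """
    if params is None:
        params = ConsensusParams()
    b = params.band
    wstart = max(0, offset_hint - b)
    wend = min(len(backbone), offset_hint + len(read_seq) + b)
    window = backbone[wstart:wend]
    if not window or not read_seq:
        return None
    diag0 = offset_hint - wstart
    _, runs, a_start, a_end, b_start, _ = glocal_align(
        read_seq, window, b, diag0, params.scoring)
    if not runs or a_end <= a_start:
        return None
    return wstart + b_start, a_start, a_end, runs_to_script(runs)


def left_align_indels(read_seq: str, backbone: str, b_start: int,
                      script: str) -> str:
    """Canonicalize indel placement in a read-vs-backbone edit script.

    Equivalent alignments place an indel anywhere within a homopolymer
    or short repeat; reads voting the same variant at different columns
    split the majority.  Every gap is shifted to its leftmost equivalent
    position (the standard variant-normalization rule), so identical
    indels from different reads land on the same DAG nodes.
    """
    ops: List[str] = []
    for n, op in parse_script(script):
        ops.extend(op * n)
    # column -> consumed positions
    out = list(ops)
    i = 0
    a = 0  # read position
    b = b_start  # backbone position
    # precompute per-column read/backbone positions
    apos = [0] * (len(out) + 1)
    bpos = [0] * (len(out) + 1)
    for idx, op in enumerate(out):
        apos[idx] = a
        bpos[idx] = b
        if op in "=XD":
            a += 1
        if op in "=XI":
            b += 1
    apos[len(out)] = a
    bpos[len(out)] = b
    changed = True
    while changed:
        changed = False
        idx = 0
        while idx < len(out):
            op = out[idx]
            if op not in "DI":
                idx += 1
                continue
            # find the run [idx, j)
            j = idx
            while j < len(out) and out[j] == op:
                j += 1
            # bubble the run left past preceding '=' columns
            while idx > 0 and out[idx - 1] == "=":
                if op == "D":
                    ok = read_seq[apos[j - 1]] == read_seq[apos[idx - 1]]
                else:
                    ok = backbone[bpos[j - 1]] == backbone[bpos[idx - 1]]
                if not ok:
                    break
                # rotate: '=' at idx-1 moves to position j-1
                out[idx - 1 : j] = out[idx:j] + ["="]
                # recompute consumed positions across the rotated span
                a0, b0 = apos[idx - 1], bpos[idx - 1]
                for t in range(idx - 1, j):
                    apos[t] = a0
                    bpos[t] = b0
                    if out[t] in "=XD":
                        a0 += 1
                    if out[t] in "=XI":
                        b0 += 1
                idx -= 1
                j -= 1
                changed = True
            idx = j if j > idx else idx + 1
    # re-encode runs
    runs: List[Tuple[int, str]] = []
    for op in out:
        if runs and runs[-1][1] == op:
            runs[-1] = (runs[-1][0] + 1, op)
        else:
            runs.append((1, op))
    return runs_to_script(runs)


@dataclass
class ConsensusDag:
    """Backbone-anchored alignment DAG with read-support weights.

    Nodes are keyed (position, insertion offset, base); offset 0 is the
    backbone column itself, offsets >= 1 are bases inserted after it.
    Node weights count supporting reads; edges record observed read
    transitions (deletions jump columns); cov[p] counts the alignments
    (backbone included) spanning column p, giving each column's local
    coverage for the majority vote.  The backbone thread itself is added
    once at construction.
    """

    backbone: str
    node_weight: Dict[Tuple[int, int, str], int] = field(default_factory=dict)
    edge_weight: Dict[Tuple[Tuple[int, int, str], Tuple[int, int, str]], int] = \
        field(default_factory=dict)
    cov: np.ndarray = None
    n_alignments: int = 0

    def __post_init__(self):
        self.cov = np.ones(max(len(self.backbone), 1), dtype=np.int64)
        prev = None
        for p, base in enumerate(self.backbone):
            node = (p, 0, base)
            self.node_weight[node] = self.node_weight.get(node, 0) + 1
            if prev is not None:
                self.edge_weight[(prev, node)] = \
                    self.edge_weight.get((prev, node), 0) + 1
            prev = node

    @property
    def total_node_weight(self) -> int:
        return sum(self.node_weight.values())


def add_alignment(dag: ConsensusDag, read_seq: str, b_start: int,
                  script: str) -> None:
    """Thread one read alignment through the DAG.

    Matches and mismatches weight (position, 0, base) nodes; insertions
    create (position, k, base) nodes hanging after the last consumed
    column; deletions simply skip columns, the jump being recorded on
    the connecting edge.
    """
    runs = parse_script(script)
    span = sum(n for n, op in runs if op in "=XI")
    end = min(b_start + span, len(dag.cov))
    if end > b_start:
        dag.cov[b_start:end] += 1
    p = b_start
    i = 0
    prev: Optional[Tuple[int, int, str]] = None
    ins_off = 0
    nw = dag.node_weight
    ew = dag.edge_weight
    for n, op in runs:
        if op in "=X":
            for _ in range(n):
                node = (p, 0, read_seq[i])
                nw[node] = nw.get(node, 0) + 1
                if prev is not None:
                    ew[(prev, node)] = ew.get((prev, node), 0) + 1
                prev = node
                p += 1
                i += 1
            ins_off = 0
        elif op == "I":  # read consumes nothing; backbone base deleted
            p += n
        else:  # 'D': inserted bases relative to the backbone
            for _ in range(n):
                ins_off += 1
                node = (p - 1, ins_off, read_seq[i]) if p > 0 else (
                    -1, ins_off, read_seq[i])
                nw[node] = nw.get(node, 0) + 1
                if prev is not None:
                    ew[(prev, node)] = ew.get((prev, node), 0) + 1
                prev = node
                i += 1
    dag.n_alignments += 1


@dataclass
class Contig:
    unitig_id: str
    seq: str
    support: List[int]
    # consensus coordinate of each backbone column (deleted columns map to
    # the preceding kept one); lets callers carry positions across rounds
    backbone_map: Optional[np.ndarray] = None


def call_consensus(dag: ConsensusDag, unitig_id: str = "utg") -> Contig:
    """Majority-margin heaviest path from backbone start to backbone end.

    Each node scores 2*support - coverage at its column (positive iff a
    majority of the reads spanning the column agrees with it), and the
    consensus is the path from the first to the last backbone column
    maximizing the summed margin over the edges reads actually took.
    Inserting a base therefore pays off exactly when most reads carry
    it, a minority backbone base is out-voted by its mismatch node, and
    a column most reads delete is skipped.  Ties prefer the backbone
    base, keeping the call deterministic.
    """
    backbone = dag.backbone
    if not backbone:
        return Contig(unitig_id, "", [])
    nodes = sorted(dag.node_weight, key=lambda nd: (nd[0], nd[1], nd[2]))
    order_index = {nd: i for i, nd in enumerate(nodes)}
    incoming: Dict[Tuple[int, int, str], List[Tuple[int, int, str]]] = \
        {nd: [] for nd in nodes}
    for (u, v) in dag.edge_weight:
        if u in order_index and v in order_index and order_index[u] < order_index[v]:
            incoming[v].append(u)
    NEG = float("-inf")
    best: Dict[Tuple[int, int, str], float] = {}
    back: Dict[Tuple[int, int, str], Optional[Tuple[int, int, str]]] = {}
    last_p = len(backbone) - 1

    # votes for "some base" per column; the remainder of the coverage at a
    # column implicitly voted to delete it
    base_sum = np.zeros(len(backbone), dtype=np.int64)
    ins_sum: Dict[Tuple[int, int], int] = {}  # (junction, offset) -> reads
    for (p, off, _b), w in dag.node_weight.items():
        if off == 0 and 0 <= p < len(backbone):
            base_sum[p] += w
        elif off >= 1:
            ins_sum[(p, off)] = ins_sum.get((p, off), 0) + w
    del_margin = dag.cov - 2 * base_sum  # 2*del_votes - cov per column
    del_prefix = np.concatenate(([0], np.cumsum(del_margin)))

    def _alive(p: int, k: int) -> float:
        """Reads facing the level-k insertion decision at junction p."""
        if k <= 1:
            pc = min(max(p, 0), len(backbone) - 1)
            return float(dag.cov[pc])
        return float(ins_sum.get((p, k - 1), 0))

    def stop_gain(p: int, k: int) -> float:
        """Margin for declining a (k+1)-th inserted base at junction p.

        The decision is a vote among the reads still alive at that
        level: those that stop versus those that insert deeper.  With no
        insertion nodes at the junction the term vanishes, so plain
        columns are unaffected.
        """
        if k == 0 and (p, 1) not in ins_sum:
            return 0.0
        alive = _alive(p, k + 1)
        cont = float(ins_sum.get((p, k + 1), 0))
        return 2.0 * (alive - cont) - alive

    # every path crosses every junction exactly once (insertion chains
    # close theirs via stop_gain at their level); prefix-summing the
    # level-0 terms lets deletion edges collect the junctions they skip,
    # so keeping or deleting a column compares fairly
    stop0 = np.zeros(len(backbone) + 1)
    for p in {p for (p, k) in ins_sum if k == 1 and 0 <= p < len(backbone)}:
        stop0[p] = stop_gain(p, 0)
    stop0_prefix = np.concatenate(([0.0], np.cumsum(stop0)))

    def junction_terms(u, v) -> float:
        ju, ku = u[0], u[1]
        jv, kv = v[0], v[1]
        if ku >= 1 and kv >= 1 and ju == jv:
            return 0.0  # continuing the same insertion chain
        t = 0.0
        if ku >= 1:
            t += stop_gain(ju, ku)
            lo = ju + 1
        else:
            lo = ju
        hi = jv  # junction jv belongs to v (entered chain or not yet crossed)
        lo = max(lo, 0)
        if hi > lo:
            t += float(stop0_prefix[hi] - stop0_prefix[lo])
        return t

    def tie_rank(nd):
        p, off, base = nd
        on_backbone = off == 0 and 0 <= p < len(backbone) and backbone[p] == base
        return (0 if on_backbone else 1, base)

    def margin(nd):
        if nd[1] >= 1:
            return 2.0 * dag.node_weight[nd] - _alive(nd[0], nd[1])
        p = min(max(nd[0], 0), len(backbone) - 1)
        return 2.0 * dag.node_weight[nd] - float(dag.cov[p])

    for nd in nodes:
        bval = NEG
        bprev = None
        if nd[0] <= 0:  # first backbone column or pre-backbone insertion
            bval = 0.0
        for u in incoming[nd]:
            if best[u] == NEG:
                continue
            # columns jumped over by this edge carry their deletion margin
            skip_lo = u[0] + 1
            skip_hi = nd[0] if nd[1] == 0 else nd[0] + 1
            gain = best[u]
            if skip_hi > skip_lo >= 0:
                gain += float(del_prefix[skip_hi] - del_prefix[skip_lo])
            gain += junction_terms(u, nd)
            if gain > bval or (gain == bval and (
                    bprev is None or tie_rank(u) < tie_rank(bprev))):
                bval = gain
                bprev = u
        best[nd] = NEG if bval == NEG else bval + margin(nd)
        back[nd] = bprev
    ends = [nd for nd in nodes if nd[0] == last_p and best[nd] > NEG]
    if not ends:
        return Contig(unitig_id, backbone, [1] * len(backbone))
    endv = max(best[nd] for nd in ends)
    tail = min((nd for nd in ends if best[nd] == endv), key=tie_rank)
    path = []
    nd: Optional[Tuple[int, int, str]] = tail
    while nd is not None:
        path.append(nd)
        nd = back[nd]
    path.reverse()
    seq = "".join(nd[2] for nd in path)
    support = [dag.node_weight[nd] for nd in path]
    bmap = np.zeros(len(backbone) + 1, dtype=np.int64)
    prev_p = -1
    for i, nd in enumerate(path):
        p = nd[0]
        if nd[1] == 0 and 0 <= p < len(backbone):
            bmap[prev_p + 1 : p + 1] = i
            prev_p = p
    bmap[prev_p + 1 :] = len(seq)
    return Contig(unitig_id, seq, support, bmap)


def consensus_unitig(
    unitig: LayoutUnitig,
    reads: Sequence[Read],
    params: ConsensusParams = None,
) -> Contig:
    """Backbone + member realignment + DAG call for one unitig.

    The call is repeated `rounds` times, each round realigning the
    member reads against the previous round's consensus: against the
    raw backbone, indel placement is ambiguous enough that many correct
    insertions sit at the majority boundary, and a cleaner backbone
    consolidates those votes.
    """
    if params is None:
        params = ConsensusParams()
    backbone = backbone_of(unitig, reads)
    by_id = {r.read_id: r for r in reads}
    entries = sorted(unitig.entries, key=lambda x: x.offset)
    hints = {e.read_id: e.offset for e in entries}
    contig = Contig(unitig.unitig_id, backbone, [1] * len(backbone))
    for _ in range(max(1, params.rounds)):
        dag = ConsensusDag(backbone)
        next_hints = dict(hints)
        for e in entries:
            r = by_id[e.read_id]
            seq = r.seq[e.kept_start : e.kept_end]
            if e.strand == "-":
                seq = revcomp(seq)
            res = align_to_backbone(seq, backbone, hints[e.read_id], params)
            if res is None:
                continue
            b_start, a_start, a_end, script = res
            match = total = 0
            for n, op in parse_script(script):
                total += n
                if op == "=":
                    match += n
            if total == 0 or match / total < params.min_identity:
                continue
            next_hints[e.read_id] = b_start
            part = seq[a_start:a_end]
            script = left_align_indels(part, backbone, b_start, script)
            add_alignment(dag, part, b_start, script)
        contig = call_consensus(dag, unitig.unitig_id)
        if not contig.seq:
            break
        if contig.backbone_map is not None:
            bmap = contig.backbone_map
            last = len(bmap) - 1
            next_hints = {rid: int(bmap[min(max(h, 0), last)])
                          for rid, h in next_hints.items()}
        backbone = contig.seq
        hints = next_hints
    return contig


def consensus_all(
    layout: LayoutFile,
    reads: Sequence[Read],
    params: ConsensusParams = None,
) -> List[Contig]:
    """One consensus contig per layout unitig."""
    return [consensus_unitig(u, reads, params) for u in layout.unitigs
            if u.entries]
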