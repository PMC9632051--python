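"""Homopolymer compression and canonical k-mer seed indexing.

Long single-molecule reads carry frequent homopolymer-length errors.
Collapsing every run of identical bases to a single base (the HPC string)
makes exact k-mer seeding far more tolerant of those errors; seeds and
candidate selection therefore live entirely in HPC coordinate space, with a
monotone map back to raw coordinates for alignment.

The index is a canonical-k-mer hashtable over the HPC strings of all reads,
built in two passes (count, then fill a seed array), with two memory
controls: only the lexicographically smaller of k-mer/reverse-complement is
keyed, and k-mers are subsampled by hash code (a quarter kept by default).
k-mers seen more than max_count times (default 500) are dropped as
repeat-derived noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i

DEFAULT_K = 16
DEFAULT_MAX_COUNT = 500
DEFAULT_SUBSAMPLE = 4
DEFAULT_MIN_COVERAGE = 300
DEFAULT_MAX_CANDIDATES = 500


@dataclass
class HPCRead:
    """A homopolymer-compressed read with its coordinate map.

    hseq has no two adjacent equal characters.  runs[i] is the raw run
    length behind HPC position i and offsets[i] its raw start, so
    offsets[i] + runs[i] == offsets[i+1] and sum(runs) == raw length.
    """

    read_id: int
    hseq: str
    runs: np.ndarray
    offsets: np.ndarray

    def __len__(self) -> int:
        return len(self.hseq)

    @property
    def raw_length(self) -> int:
        return int(self.runs.sum())


def hpc_compress(seq: str, read_id: int = -1) -> HPCRead:
    """Collapse homopolymer runs; idempotent on already-compressed input."""
    if not seq:
        return HPCRead(read_id, "", np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64))
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    starts = np.flatnonzero(np.concatenate(([True], arr[1:] != arr[:-1])))
    runs = np.diff(np.concatenate((starts, [len(arr)])))
    hseq = arr[starts].tobytes().decode("ascii")
    return HPCRead(read_id, hseq, runs.astype(np.int64), starts.astype(np.int64))


def hpc_expand(h: HPCRead) -> str:
    """Inverse of hpc_compress (used as its round-trip check)."""
    return "".join(c * int(n) for c, n in zip(h.hseq, h.runs))


def hpc_to_raw(h: HPCRead, start: int, end: int) -> Tuple[int, int]:
    """Map an HPC interval [start, end) to the raw interval it expands to."""
    if not (0 <= start <= end <= len(h.hseq)):
        raise IndexError(f"HPC interval [{start},{end}) outside [0,{len(h.hseq)})")
    raw_len = h.raw_length
    s = int(h.offsets[start]) if start < len(h.hseq) else raw_len
    e = int(h.offsets[end]) if end < len(h.hseq) else raw_len
    return s, e


# ---------------------------------------------------------------------------
# 2-bit k-mer encoding
# ---------------------------------------------------------------------------

def encode_kmer(kmer: str) -> int:
    """2-bit encode (A=0,C=1,G=2,T=3); raises on N or bad base."""
    code = 0
    for ch in kmer:
        v = _BASE_CODE[ord(ch)]
        if v < 0:
            raise ValueError(f"cannot encode base {ch!r}")
        code = (code << 2) | int(v)
    return code


def revcomp_code(code: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def canonical_kmer(code: int, k: int) -> Tuple[int, bool]:
    """The smaller of a k-mer code and its reverse complement.

    flipped is True iff the reverse complement was chosen; palindromes are
    not flipped.
    """
    rc = revcomp_code(code, k)
    if rc < code:
        return rc, True
    return code, False


def mix64(x: np.ndarray | int):
    """splitmix64 finalizer; the fixed hash used for k-mer subsampling."""
    x = np.uint64(x) if np.isscalar(x) else x.astype(np.uint64)
    with np.errstate(over="ignore"):
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D9F36BCB25E9C6)
        x = x ^ (x >> np.uint64(31))
    return x


def _kmer_codes(hseq: str, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """All k-mer codes of an HPC string, vectorized.

    Returns (codes uint64, valid bool); windows containing N are invalid.
    """
    n = len(hseq) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=bool)
    vals = _BASE_CODE[np.frombuffer(hseq.encode("ascii"), dtype=np.uint8)]
    win = np.lib.stride_tricks.sliding_window_view(vals, k)
    valid = (win >= 0).all(axis=1)
    shifts = np.uint64(2) * np.arange(k - 1, -1, -1, dtype=np.uint64)
    codes = (win.astype(np.uint64) << shifts).sum(axis=1, dtype=np.uint64)
    return codes, valid


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = (rc << np.uint64(2)) | (np.uint64(3) - (tmp & np.uint64(3)))
        tmp = tmp >> np.uint64(2)
    return rc


def canonical_codes(hseq: str, k: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(canonical codes, flipped flags, HPC positions) for all valid k-mers."""
    codes, valid = _kmer_codes(hseq, k)
    pos = np.flatnonzero(valid).astype(np.int64)
    codes = codes[valid]
    rc = _revcomp_codes(codes, k)
    flipped = rc < codes
    canon = np.where(flipped, rc, codes)
    return canon, flipped, pos


@dataclass
class KmerIndex:
    """Seed index: sorted canonical codes with a parallel seed array.

    Lookup is by binary search into `codes_sorted`; `starts[i]:starts[i+1]`
    slices the seed arrays for the i-th distinct code.
    """

    k: int
    max_count: int
    subsample_denominator: int
    codes_sorted: np.ndarray  # distinct canonical codes, ascending
    starts: np.ndarray  # len = len(codes_sorted)+1, slice bounds
    seed_read: np.ndarray  # read_id per seed
    seed_flip: np.ndarray  # bool, k-mer stored flipped relative to canonical
    seed_pos: np.ndarray  # HPC position per seed

    def lookup(self, canon: int) -> slice:
        i = np.searchsorted(self.codes_sorted, np.uint64(canon))
        if i < len(self.codes_sorted) and self.codes_sorted[i] == np.uint64(canon):
            return slice(int(self.starts[i]), int(self.starts[i + 1]))
        return slice(0, 0)

    @property
    def n_seeds(self) -> int:
        return len(self.seed_read)


def build_index(
    hreads: Sequence[HPCRead],
    k: int = DEFAULT_K,
    max_count: int = DEFAULT_MAX_COUNT,
    subsample_denominator: int = DEFAULT_SUBSAMPLE,
) -> KmerIndex:
    """Two-pass canonical-k-mer index build over HPC reads.

    Pass 1 gathers every valid canonical k-mer with its (read, flip, pos)
    seed; k-mers failing the hash subsample or occurring more than
    max_count times across all reads are dropped before the seed array is
    materialized.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    all_codes, all_reads, all_flips, all_pos = [], [], [], []
    for h in hreads:
        canon, flipped, pos = canonical_codes(h.hseq, k)
        if subsample_denominator > 1 and len(canon):
            keep = mix64(canon) % np.uint64(subsample_denominator) == 0
            canon, flipped, pos = canon[keep], flipped[keep], pos[keep]
        all_codes.append(canon)
        all_reads.append(np.full(len(canon), h.read_id, dtype=np.int64))
        all_flips.append(flipped)
        all_pos.append(pos)
    if not all_codes or sum(len(c) for c in all_codes) == 0:
        z = np.zeros(0, dtype=np.uint64)
        return KmerIndex(k, max_count, subsample_denominator, z,
                         np.zeros(1, dtype=np.int64),
                         np.zeros(0, dtype=np.int64),
                         np.zeros(0, dtype=bool),
                         np.zeros(0, dtype=np.int64))
    codes = np.concatenate(all_codes)
    reads = np.concatenate(all_reads)
    flips = np.concatenate(all_flips)
    pos = np.concatenate(all_pos)
    order = np.argsort(codes, kind="stable")
    codes, reads, flips, pos = codes[order], reads[order], flips[order], pos[order]
    distinct, first, counts = np.unique(codes, return_index=True, return_counts=True)
    keep = counts <= max_count
    distinct, first, counts = distinct[keep], first[keep], counts[keep]
    # rebuild the seed array holding only surviving codes, preserving order
    segs = [np.arange(f, f + c) for f, c in zip(first, counts)]
    sel = np.concatenate(segs) if segs else np.zeros(0, dtype=np.int64)
    starts = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
    return KmerIndex(
        k, max_count, subsample_denominator,
        distinct, starts, reads[sel], flips[sel], pos[sel],
    )


@dataclass
class CandidateHit:
    """A candidate overlap partner found by shared seeds.

    coverage is the seed-supported extent of the overlap on the query
    (first shared seed start to last shared seed end, HPC bases) — at
    10-20% error exact k-mer hits are sparse, so the extent, not the
    union of seed bases, measures how much of the query the putative
    overlap covers.  intervals holds the union of the seed intervals
    themselves (used later for repeat-depth weighting).
    """

    qid: int
    tid: int
    strand: str
    coverage: int
    intervals: List[Tuple[int, int]] = field(default_factory=list)


def _union_intervals(starts: np.ndarray, k: int) -> List[Tuple[int, int]]:
    """Union of [s, s+k) intervals from sorted starts."""
    out: List[Tuple[int, int]] = []
    for s in starts:
        s = int(s)
        if out and s <= out[-1][1]:
            if s + k > out[-1][1]:
                out[-1] = (out[-1][0], s + k)
        else:
            out.append((s, s + k))
    return out


def find_candidates(
    index: KmerIndex,
    query: HPCRead,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
) -> List[CandidateHit]:
    """Candidate partners of a query, ranked by seed coverage.

    For each (target, strand) pair the coverage is the extent of the
    query spanned by shared seeds; hits with coverage strictly greater
    than min_coverage survive, ordered by coverage descending (ties:
    target id ascending, '+' before '-'), truncated to max_candidates.
    """
    canon, qflip, qpos = canonical_codes(query.hseq, index.k)
    if index.subsample_denominator > 1 and len(canon):
        keep = mix64(canon) % np.uint64(index.subsample_denominator) == 0
        canon, qflip, qpos = canon[keep], qflip[keep], qpos[keep]
    tids, strands, qstarts = [], [], []
    for c, fl, p in zip(canon, qflip, qpos):
        sl = index.lookup(int(c))
        if sl.stop == sl.start:
            continue
        t = index.seed_read[sl]
        same = index.seed_flip[sl] == fl
        n = sl.stop - sl.start
        tids.append(t)
        strands.append(same)
        qstarts.append(np.full(n, p, dtype=np.int64))
    if not tids:
        return []
    tids = np.concatenate(tids)
    strands = np.concatenate(strands)
    qstarts = np.concatenate(qstarts)
    mask = tids != query.read_id
    tids, strands, qstarts = tids[mask], strands[mask], qstarts[mask]
    if len(tids) == 0:
        return []
    order = np.lexsort((qstarts, strands, tids))
    tids, strands, qstarts = tids[order], strands[order], qstarts[order]
    boundary = np.flatnonzero(
        np.concatenate(([True], (tids[1:] != tids[:-1]) | (strands[1:] != strands[:-1])))
    )
    bounds = np.concatenate((boundary, [len(tids)]))
    hits: List[CandidateHit] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        intervals = _union_intervals(qstarts[a:b], index.k)
        cov = int(qstarts[b - 1]) + index.k - int(qstarts[a])
        if cov > min_coverage:
            hits.append(CandidateHit(
                qid=query.read_id, tid=int(tids[a]),
                strand="+" if strands[a] else "-",
                coverage=cov, intervals=intervals,
            ))
    hits.sort(key=lambda h: (-h.coverage, h.tid, h.strand))
    return hits[:max_candidates]
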