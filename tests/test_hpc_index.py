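"""Homopolymer compression, canonical k-mers, index build, candidates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from longasm.hpc_index import (
    HPCRead,
    build_index,
    canonical_codes,
    canonical_kmer,
    encode_kmer,
    find_candidates,
    hpc_compress,
    hpc_expand,
    hpc_to_raw,
    revcomp_code,
)
from longasm.io_formats import revcomp

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)


class TestHpcCompress:
    def test_known_example(self):
        h = hpc_compress("AAATTGGC")
        assert h.hseq == "ATGC"
        assert h.runs.tolist() == [3, 2, 2, 1]
        assert h.offsets.tolist() == [0, 3, 5, 7]

    def test_fixed_point(self):
        h = hpc_compress("ACGT")
        assert h.hseq == "ACGT" and h.runs.tolist() == [1, 1, 1, 1]

    def test_empty(self):
        h = hpc_compress("")
        assert h.hseq == "" and len(h.runs) == 0

    @settings(max_examples=200, deadline=None)
    @given(dna)
    def test_round_trip_and_invariants(self, s):
        h = hpc_compress(s)
        assert hpc_expand(h) == s
        assert all(a != b for a, b in zip(h.hseq, h.hseq[1:]))
        assert int(h.runs.sum()) == len(s)
        if len(h.hseq) > 1:
            assert (np.diff(h.offsets) == h.runs[:-1]).all()

    def test_idempotent(self):
        h = hpc_compress("AAATTGGC")
        h2 = hpc_compress(h.hseq)
        assert h2.hseq == h.hseq and h2.runs.tolist() == [1] * len(h.hseq)


class TestHpcToRaw:
    def test_interval_from_runs(self):
        h = hpc_compress("AAATTGGC")
        assert hpc_to_raw(h, 1, 3) == (3, 7)

    def test_full_range(self):
        h = hpc_compress("AAATTGGC")
        assert hpc_to_raw(h, 0, 4) == (0, 8)

    def test_empty_interval(self):
        h = hpc_compress("AAATTGGC")
        s, e = hpc_to_raw(h, 2, 2)
        assert s == e == int(h.offsets[2])

    def test_out_of_range(self):
        h = hpc_compress("ACGT")
        with pytest.raises(IndexError):
            hpc_to_raw(h, 0, 5)

    @settings(max_examples=100, deadline=None)
    @given(dna.filter(lambda s: len(s) > 0), st.data())
    def test_monotone(self, s, data):
        h = hpc_compress(s)
        n = len(h.hseq)
        a = data.draw(st.integers(0, n))
        b = data.draw(st.integers(a, n))
        c = data.draw(st.integers(b, n))
        s1, e1 = hpc_to_raw(h, a, b)
        s2, e2 = hpc_to_raw(h, b, c)
        assert s1 <= e1 == s2 <= e2
        assert (e1 - s1) == int(h.runs[a:b].sum())


class TestCanonicalKmer:
    def test_forward_smaller(self):
        code = encode_kmer("AAAC")
        canon, flipped = canonical_kmer(code, 4)
        assert canon == code and not flipped

    def test_revcomp_smaller(self):
        code = encode_kmer("TTTT")
        canon, flipped = canonical_kmer(code, 4)
        assert canon == encode_kmer("AAAA") and flipped

    def test_palindrome_not_flipped(self):
        code = encode_kmer("ACGT")
        canon, flipped = canonical_kmer(code, 4)
        assert canon == code and not flipped

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=4, max_size=16))
    def test_vectorized_matches_scalar(self, s):
        k = min(8, len(s))
        canon, flipped, pos = canonical_codes(s, k)
        # scalar reference on first window without adjacent repeats removed
        for c, f, p in zip(canon[:3], flipped[:3], pos[:3]):
            code = encode_kmer(s[p : p + k])
            c2, f2 = canonical_kmer(code, k)
            assert int(c) == c2 and bool(f) == f2

    def test_revcomp_code_involution(self):
        code = encode_kmer("ACGGTA")
        assert revcomp_code(revcomp_code(code, 6), 6) == code


def _hreads(seqs):
    return [hpc_compress(s, i) for i, s in enumerate(seqs)]


class TestBuildIndex:
    def test_count_filter_boundary(self):
        # one k-mer occurring exactly max_count times stays; +1 drops it
        kmer = "ACGTACGTAC"  # k=10, no adjacent repeats
        reads = _hreads(["TT" + kmer + "GG"] * 5)
        idx = build_index(reads, k=10, max_count=5, subsample_denominator=1)
        canon, _ = canonical_kmer(encode_kmer(kmer), 10)
        sl = idx.lookup(canon)
        assert sl.stop - sl.start == 5
        idx2 = build_index(reads, k=10, max_count=4, subsample_denominator=1)
        sl2 = idx2.lookup(canon)
        assert sl2.stop == sl2.start

    def test_no_subsampling_indexes_every_kmer(self):
        rng = np.random.default_rng(0)
        s = "".join(rng.choice(list("ACGT"), 300))
        h = hpc_compress(s, 0)
        idx = build_index([h], k=12, subsample_denominator=1)
        assert idx.n_seeds == len(h.hseq) - 12 + 1

    def test_subsampling_reduces_seed_count(self):
        rng = np.random.default_rng(1)
        s = "".join(rng.choice(list("ACGT"), 2000))
        h = hpc_compress(s, 0)
        full = build_index([h], k=12, subsample_denominator=1).n_seeds
        quarter = build_index([h], k=12, subsample_denominator=4).n_seeds
        assert 0.15 * full < quarter < 0.35 * full

    def test_n_kmers_not_indexed(self):
        h = hpc_compress("ACGTN" * 20, 0)
        idx = build_index([h], k=10, subsample_denominator=1)
        assert idx.n_seeds == 0  # every 10-mer crosses an N


class TestFindCandidates:
    def test_shared_stretch_coverage(self):
        rng = np.random.default_rng(3)
        shared = "".join(rng.choice(list("ACGT"), 500))
        a = "".join(rng.choice(list("ACGT"), 300)) + shared
        b = shared + "".join(rng.choice(list("ACGT"), 300))
        ha, hb = hpc_compress(a, 0), hpc_compress(b, 1)
        idx = build_index([ha, hb], k=16, subsample_denominator=1)
        hits = find_candidates(idx, ha, min_coverage=300)
        hit = [h for h in hits if h.tid == 1]
        assert hit and hit[0].strand == "+"
        # the shared stretch compresses to at least ~70% of its raw length
        assert hit[0].coverage >= len(hpc_compress(shared).hseq) - 16
        assert all(h.tid != 0 for h in hits)  # no self hits

    def test_no_shared_kmer_empty(self):
        a = hpc_compress("ACGT" * 30, 0)
        b = hpc_compress("AGTC" * 17 + "AT", 1)
        idx = build_index([a, b], k=16, subsample_denominator=1)
        assert all(h.tid != 1 or h.coverage <= 300
                   for h in find_candidates(idx, a, 300))

    def test_top_candidates_truncation(self):
        rng = np.random.default_rng(4)
        q = "".join(rng.choice(list("ACGT"), 600))
        targets = [q[: 400 + 20 * (i % 10)] for i in range(30)]
        hr = _hreads([q] + targets)
        idx = build_index(hr, k=16, max_count=100, subsample_denominator=1)
        hits = find_candidates(idx, hr[0], min_coverage=100, max_candidates=10)
        assert len(hits) == 10
        all_hits = find_candidates(idx, hr[0], min_coverage=100,
                                   max_candidates=1000)
        assert [h.coverage for h in hits] == \
            sorted((h.coverage for h in all_hits), reverse=True)[:10]

    def test_strand_symmetry(self):
        rng = np.random.default_rng(5)
        q = "".join(rng.choice(list("ACGT"), 800))
        t = q[100:700]
        hq, ht = hpc_compress(q, 0), hpc_compress(t, 1)
        idx = build_index([hq, ht], k=16, subsample_denominator=1)
        fwd = find_candidates(idx, hq, 300)
        hq_rc = hpc_compress(revcomp(q), 0)
        rev = find_candidates(idx, hq_rc, 300)
        assert {(h.tid, h.strand, h.coverage) for h in fwd} == \
            {(h.tid, "+" if h.strand == "-" else "-", h.coverage)
             for h in rev}
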