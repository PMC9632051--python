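# Methods

`longasm` is an overlap–layout–consensus (OLC) assembler for uncorrected
long reads with 5–20% error dominated by insertions and deletions
(PacBio CLR / Oxford Nanopore style). This note documents the model each
stage implements, the parameters that matter, the numerical choices, and
what the bundled simulator does and does not emulate.

## Overlapping

**Homopolymer compression.** Every read is compressed by collapsing each
run of identical bases to a single base (the HPC string), with a monotone
coordinate map back to raw coordinates. Homopolymer-length errors — a
large fraction of single-molecule indels — vanish in HPC space, so exact
k-mer seeding becomes usable at high error rates. All seeding and
chaining happen in HPC coordinates; alignment decompresses back to raw
space.

**Seed index.** A two-pass canonical-k-mer index over all HPC reads
(k = 16): count k-mers, drop those occurring more than 500 times
(repeat filter), then fill a seed array of (read, strand, position)
entries. Memory controls: only the smaller of k-mer/reverse-complement
under the 2-bit encoding (A=0<C=1<G=2<T=3, palindromic ties not flipped)
is keyed, and k-mers are subsampled by a fixed splitmix64 hash
(one quarter kept by default).

**Candidates.** For each query, shared seeds are grouped by (target,
strand); a candidate is kept when the seed-supported extent on the query
exceeds 300 HPC bases. The extent — first shared seed start to last
shared seed end — rather than the union of seed bases is the right
measure at this error regime: exact 16-mers shared by two 12%-error
reads are only a few percent dense, but they still delimit the
overlapping region. Candidates in repetitive regions are down-ranked by
a per-base weight of the query's candidate depth (weight 1 at depth ≤ 10,
0 at depth ≥ 100, linear between); the top 500 candidates by weighted
coverage are retained.

**Chaining.** Short z-mers (z = 10, also HPC) anchor each candidate
pair. Maximal exact matches are chained inside sliding query windows
(800 HPC bases, stepping half a window) with the recurrence

    S(i+1) = S(i) + L(i+1) − D(i,i+1)

where L is anchor length and D the *diagonal drift* between adjacent
anchors, |target gap − query gap|: collinear anchors cost nothing
however sparse they are, spurious jumps reset the score. Before
chaining, each window keeps only anchors on its heaviest diagonal band
(width 200), found by a two-pointer sweep — random z-mer collisions can
outnumber true anchors and would otherwise break every block. A window
must carry ≥ 200 matched bases to be considered and its best block must
cover > 100 bases to survive; surviving window blocks are chained again
with the same recurrence, and a candidate is kept when the chosen chain
covers > 300 distinct query bases.

**Alignment.** Four steps, all through one banded affine-gap kernel
(match +2, mismatch −4, gap open −4, extend −2; a length-g gap costs
open + (g−1)·ext): (1) anchors are decompressed to raw space, each HPC
position emitting min(run_q, run_t) matches plus the run-length surplus
as a gap; (2) gaps between anchors are closed by banded global
alignment, starting at band 50 and doubling whenever the optimal path
touches the band boundary, capped at 3200; (3) the same applies between
adjacent windows; (4) the two ends are extended to the nearer read end
with a fixed band of 800 and a z-drop of 200 — if the score collapses
more than 200 below its running maximum before reaching the boundary
(the signature of a chimeric junction), the extension stops at the
maximum instead. Without the forced extension, noisy dovetails end a
few hundred bases short of the read ends and the layout stage cannot
classify them; without the z-drop, extension ploughs through chimeric
junctions and erases the evidence trimming needs. The stitched
alignment is emitted when its identity (matches / columns) is at least
0.65; each unordered pair is attempted from both query sides (chaining
is windowed on the query, so one side can fail where the other
succeeds) and reported once.

## Trimming

Each read is tiled with every overlap touching it. The kept interval is
the longest stretch covered by valid overlaps (pileup depth ≥ 1) — the
extent of the read's valid overlaps; requiring deeper support would
discard every genome region spanned by only one read pair, which at 30×
with 5-kb reads is a few hundred bases at each genome end. A *spur* is an alignment
terminus internal (by > 50 bases) on **both** reads of an overlap — in a
genuine tiling every terminus coincides with one read's physical end, so
a two-sided internal stop marks either a local alignment breakdown or a
chimeric junction. A spur site is classified only when at least 3
partial alignments terminate there (a real junction stops every spanning
alignment; a lone terminus is noise) and it lies more than 50 bases
inside the kept interval. At a site, m counts overlaps strictly
containing the position and n the nearby (±50) spur termini; the read is
chimeric iff m < avg/2, n > avg, or n > m/2, with avg the mean pileup
depth over the read's connected component. A second, topological check
flags reads that are articulation points of the overlap graph whose
removal leaves two components of ≥ 3 reads each *and* whose two neighbor
groups touch disjoint arms of the read. Surviving overlaps are
re-projected onto kept intervals by walking their edit scripts and
dropped below a 300-base clipped span.

## Layout

Overlaps are classified against the kept intervals with 100 bases of
end slack: contained reads are set aside, internal overlaps discarded,
and dovetails become candidate edges between read ends. Edge selection
is iterated mutual-best: each free read end nominates, among edges whose
other end is also free, the longest overlap within ratio 0.95 of the
end's best alignment score (ties: higher score, then smaller partner
id); reciprocal nominations are fixed and the rest re-nominate. The
first round is the classical strict mutual-best rule; later rounds only
pair ends whose first choice was claimed elsewhere, which would
otherwise fragment a 30× dataset into several parallel unitigs. The
score-ratio candidate set (rather than raw longest-overlap) keeps
bubble arms from being merged. Every end then carries at most one edge,
so the graph decomposes into simple paths (cycles are broken at the
smallest read id) that become unitigs; contained reads are re-inserted
at their container's position, with strand and offset derived from the
containment record, as depth for consensus only. A unitig whose tiled
length is > 40% covered by reads linked to a longer unitig is dropped
as redundant.

## Consensus

Each unitig gets an uncorrected backbone stitched from its path reads in
offset order; every junction is refined by aligning the current backbone
tail (500 bases) against the incoming read's prefix and cutting at the
aligned endpoint — offset arithmetic alone misplaces junctions by up to
a few hundred bases, and a duplicated or missing chunk there becomes a
near-repeat that voting cannot cleanly remove.

Member reads are aligned to their hinted backbone region (banded, band
800, window ends free, read overhang past the backbone boundary
allowed). Consensus alignment uses its own scoring — match +2, mismatch
−6, gap open −2, extend −2 — so that with indel-dominant errors a
read's extra or missing base is always represented as the same indel
rather than sometimes as a mismatch with a compensating gap; mixed
representations split majority votes. Indels are then left-aligned
(standard variant normalization) so equivalent placements inside
homopolymers land on the same node. Reads whose alignment identity
falls below 0.6 are excluded: under gap-cheap scoring, unrelated DNA
pairs align at ≈ 0.5 identity (the common-subsequence density of a
4-letter alphabet) while genuinely placed reads stay above ≈ 0.7 even
at 20% error.

The alignments are threaded through a backbone-anchored DAG: nodes are
(column, insertion offset, base) with read-support weights, edges record
observed transitions, and a coverage profile counts the alignments
spanning each column. The consensus is the path from the first to the
last backbone column maximizing the summed *majority margin*: a column
node scores 2·support − coverage, skipped columns contribute their
deletion-vote margin, and each junction charges insertion decisions
level by level against the reads still "alive" at that level. This
makes every base call a plurality vote — a naive positive-weight
heaviest path provably inflates the output, because visiting more nodes
always adds weight. Ties prefer the backbone base. The call is
repeated 3 rounds, realigning reads to the previous round's consensus
(hints are carried through a backbone-to-consensus coordinate map);
against a raw 15–19%-error backbone many correct indel votes sit at the
majority boundary, and one or two rounds against a cleaner backbone
consolidate them. Accuracy saturates after round 3.

## Simulator

The generator emulates: uniform random genomes with an optional planted
repeat family; truncated-normal read lengths (default mean 5 kb,
sd 1.5 kb, min 500); uniform start positions and strands; per-base
substitution/insertion/deletion errors; ±1 homopolymer run-length noise
per run; error rates tripled in a configurable band at the read ends;
and chimeric reads joining two independent fragments at a uniform
junction. Ground truth (source intervals, strands, junctions) is
recorded per read, and `true_overlaps` derives the exact overlap set by
interval intersection.

It does **not** emulate: instrument-specific error profiles or quality
values, sequence-context-dependent error rates, very long repeat
structures, heterozygosity, or coverage biases. Passing tests therefore
demonstrate correctness of the algorithms under a clean i.i.d. error
model at desk scale, not production performance on real flow-cell data.
Note one geometric artifact: with uniform starts inside the genome,
coverage ramps linearly over one read length at each genome end, so
contig ends are called from depth 2–10 and carry most of the residual
consensus error.

## Default problem sizes

The test suite and the acceptance script run on 50-kb genomes at 30×
coverage with 5-kb mean reads (~300 reads): large enough that each read
has dozens of true overlaps and the overlap graph is dense, small enough
to assemble in a few minutes on one core. The three standard datasets
are error-free, 12% error (6% ins / 4% del / 2% sub, homopolymer noise
0.1), and the same noise plus 5% chimeras.

## Known limitations

- All-vs-all overlap is quadratic in read count; the design targets
  ~10³–10⁴ reads, not production runs.
- Repeat resolution is limited to what the best-overlap graph and the
  redundant-unitig filter provide; long exact repeats above read length
  will fragment or collapse.
- One consensus configuration (3 rounds, band 800) is applied to all
  unitigs; very short unitigs (< 2 reads) simply return their backbone.
- Contig ends inherit the simulator's coverage ramp (see above) and are
  a few points less accurate than interiors.
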