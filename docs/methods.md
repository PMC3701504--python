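# Methods

## The mapping contract

Reads are gapless, fixed-length and single-end.  A candidate alignment of
read *r* at position *p* on either strand is scored by Hamming distance;
any comparison involving an N (in read or genome) counts as a mismatch.
A read is **reported** iff the number of locations with distance ≤ *v* is
exactly one (more generally ≤ *m*, default *m* = 1).  This is a
multiplicity filter, not a best-hit filter: a read with a perfect hit and
a second 2-mismatch hit is suppressed entirely.  Consequences worth
stating:

* a kept hit of length *L* with ≤ *k* mismatches has identity
  ≥ (L−k)/L — for L = 80, k = 2 exactly 97.5%;
* ties need no breaking: the filter never chooses among hits;
* raising *v* can only grow the set of reads with ≥ 1 alignment, but may
  *shrink* the uniquely-mapped set (new secondary locations appear).

The production mapper (`map_reads`) uses a pigeonhole seed index: the
read is partitioned into *v* + 1 segments, so under ≤ *v* mismatches at
least one segment matches exactly; the leading ≤ 31-mer of each segment
is looked up in a sorted 2-bit-packed k-mer index of the genome, and
every candidate is verified by full-length Hamming distance.  Candidate
positions whose window would cross a scaffold boundary are discarded
(`pos0 + L ≤ scaffold length` is an invariant of reported hits).  The
exhaustive scanner (`enumerate_alignments`) tests every position on both
strands and exists as the independent oracle; the suite asserts read-by-
read equivalence of the two routes on ~100 kb instances.

Counting convention: downstream statistics count **reads** (one count per
kept read at its leftmost forward-strand coordinate), not distinct
positions, so WGA duplicates that share a start each contribute.  The
counters satisfy `mapped_unique + suppressed_multi = mapped_any` and
`mapped_any + unmapped = total_reads` by construction.

External alignments can replace the built-in mapper through a SAM
ingester.  Its default uniqueness policy is *record-count* (exactly one
non-secondary, non-supplementary aligned record), because multiplicity
tags are aligner-specific; policy *tag* trusts `NH:i:1` instead.

## Density, threshold, classification

`hits/kb` divides a scaffold's unique-hit count by its full length in kb,
N runs included — lengths are taken as assembled, with no mappability
correction.  The on-arm threshold comes either from an **anchor**
scaffold whose physical location is independently known (its own density
becomes the cutoff) or as the **mean density of a trusted region** (total
hits in the region / region kb).  The comparison is inclusive (≥): the
anchor itself is on the arm and must pass.  A zero-density anchor is
rejected as uninformative.

Classification crosses the threshold verdict with a prior placement
(meiotic or physical map; physical outranks meiotic when both exist;
absent priors mean "unmapped"): above+target → confirmed-on-arm,
above+unmapped → newly-assigned, above+elsewhere → reassignment-candidate,
below+target → prior-conflict, below otherwise → under-threshold.
Reassignment candidates clear no second, higher bar — their justification
is the same threshold that admits confirmed scaffolds.

Category accounting reports raw counts plus percentages rounded to two
decimals, with a residual row so counts always conserve exactly.

## Gap detection and segmentation

Unique-hit starts are binned into non-overlapping windows (default
10 kb; the shortest reported structures span hundreds of kb, so ≥ 10
windows cover any real feature; the last window is normalised by its true
length).  A **gap** is a maximal run of windows below the sparse cutoff
(default 1.0 hits/kb — the empirical ceiling for off-arm scaffolds)
spanning at least 100 kb.  Gaps touching a scaffold end are flagged
*terminal* and still reported: a terminal decline can be the laser-cut
taper or a truncated assembly rather than a bad join, so only scaffolds
that are above the on-arm threshold **and** contain a non-terminal gap
are flagged hybrid candidates.

Segmentation labels windows dense/sparse against a cutoff (by default
the calibrated threshold), absorbs contrary runs of ≤ 2 windows (visual
region boundaries in this kind of data are smoothed; a small run-length
tolerance is the simplest declared rule), then merges runs shorter than
500 kb into the longer neighbour (left wins a tie — determinism matters
more than the choice).  Segments tile [0, length) exactly with
alternating states.  No formal changepoint statistic is attempted; the
windows-and-runs rule is transparent and reproduces block structure well
at the densities involved.

## The synthetic experiment

`build_genome` draws i.i.d. uniform ACGT scaffolds and labels a fraction
on-arm; repeat families are fixed units copied verbatim into random
scaffolds of both labels (the only mechanism needed to exercise the
multiplicity filter); hybrid scaffolds concatenate an on-arm and an
off-arm segment (order random, each ≥ 200 kb by default) with the
breakpoint recorded.  `simulate_reads` then draws:

* a contaminant flag per read (Bernoulli, default 0.05) choosing the
  on-arm or off-arm source pool — for hybrids only the on-arm segment is
  eligible as an on-arm source, and the off-arm segment of a hybrid
  receives no reads at all (its sequence exists nowhere else);
* WGA duplication as a pool of fragment start positions with
  lognormal(0, σ = 1.0) amplification weights; reads resample fragments,
  so duplicates share a start coordinate.  σ is a free choice: published
  accounts of single-cell WGA report strong, heavy-tailed amplification
  bias but no usable duplication-rate statistic, and σ = 1.0 yields
  visible duplicate families without degenerate coverage;
* a linear density taper to zero over 100 kb at one boundary, placed at
  the end of the **border scaffold** — the shortest on-arm scaffold, so
  the taper depresses its whole length.  This mirrors the real situation
  in which the scaffold nearest the cut shows severalfold-reduced density
  and is precisely the scaffold used to anchor the threshold;
* substitution errors at 0.005/base (80 bp short-read scale), applied
  before chimera implantation so the implanted primer bases stay exact;
* primer chimeras (default 5% of reads): a read end (prefix or suffix,
  fair coin) is overwritten with ≥ 11 nt of a primer — the public
  transposase motif or a synthetic stand-in WGA adapter (an arbitrary
  fixed sequence, not any vendor's real one);
* a sequencing strand per read (fair coin); truth always records the
  forward-strand start.

Default scale — 60 scaffolds of 50–300 kb (~10 Mb), 200,000 reads — keeps
a full simulate-map-classify cycle near ten seconds while leaving ~40
hits/kb on-arm against < 2 hits/kb off-arm, the same order of contrast
the real experiment shows.  The hybrid-recovery benchmark uses 12
scaffolds of 100–500 kb and 30,000 reads per run so twenty seeded runs
stay cheap; hybrid scaffolds need ≥ 400 kb to host two ≥ 200 kb segments.

What the generator does **not** model: indels, paired ends, quality-score
structure, GC bias, transposase insertion-site bias, true centromeric
repeat architecture, and assembly N-gaps.  Passing tests therefore show
the pipeline's logic is correct under the stated statistical structure,
not that real microdissection data will be as clean; in particular real
off-arm contamination is not uniform and real repeats are not exact
copies, so real thresholds sit closer to the off-arm noise than the
simulated ones do.

## Evaluation conventions

Scaffold-level precision/recall treat categories confirmed-on-arm,
newly-assigned and reassignment-candidate as "called on-arm"; hybrid
scaffolds are excluded from that universe (they are partially on-arm by
construction).  A hybrid join counts as detected iff any reported gap
(terminal ones included — a two-segment hybrid's gap legitimately touches
a scaffold end) overlaps the true off-arm interval; breakpoint error is
the distance from the true breakpoint to the gap edge facing it.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere; SAM output converts to
  1-based on write.
* Seed k-mers are capped at 31 nt so codes fit two bits per base in a
  64-bit integer.
* Windows containing N never enter the k-mer index; this loses no
  alignments because an exact segment cannot contain an N.
* Empty hit sets, zero-hit scaffolds, and empty gap tables flow through
  with typed empty frames rather than errors.
* All randomness derives from `numpy.random.default_rng` seeded from the
  config; identical configs give byte-identical FASTA/FASTQ/TSV outputs.

## Known limitations

The mapper holds the genome index (~8 bytes per base plus the packed
sequence) and all reads in memory — ample headroom at tens of megabases,
not suited to gigabase genomes.  Gapped alignment and paired-end logic
are out of scope.  The region-segmentation defaults (window, smoothing,
minimum region) are declared choices, not fitted ones; profiles of real
data may warrant different settings, which is why they are all exposed in
the pipeline config.
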