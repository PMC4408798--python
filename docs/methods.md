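# Methods

This note documents the models, conventions and numerical choices behind
`srnapipe`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates, weights and units

All coordinates are 0-based half-open, on all interfaces and on disk (BED
matches; RepeatMasker-style input is converted on read).  U is stored as T.
A *nonidentical sequence* is the unit of analysis: reads are collapsed to
distinct sequences with counts (`>sr<id>_x<count>` FASTA dialect).  A
sequence with *h* genomic placements at the configured stringency gets
weight *m/h* per placement, where *m* is 1 (nonidentical mode) or the read
count (reads mode); per-sequence weight is conserved, and consensus-mapping
hits never enter *h*.  Multi-hit reporting is uncapped.

## Ping-pong and duplex signatures

The overlap of an opposite-strand hit pair is defined as the **footprint
intersection** — the number of genomic bases shared by the two 5′-anchored
prefixes.  This definition (rather than the 5′-to-5′ distance) is used
because it is symmetric under swapping all strand labels, and because it
gives the two diagnostic geometries their standard values: a ping-pong pair
shares exactly the 10 bases behind both 5′ ends, and a Dicer duplex of
length-L reads with 2 nt 3′ overhangs shares L − 2 bases (hence the
18–22 bp band for 20–24 nt siRNAs).  Pair weight is the product of the two
hit weights: the product is the only choice that preserves per-sequence
normalization under marginalization (summing a sequence's pairs over its
placements recovers its weight).  Overlaps are capped at 30 bp; each
genomic co-location counts once per hit pair.

Duplex calling operates in transcript-local coordinates against a pairing
map (partner base per position, −1 unpaired), which can come from an ideal
inverted-repeat model or from an MFE fold.  Reads whose footprint touches
an unpaired (loop) base are excluded from calling and reported separately.
For two disjoint reads *a* (upstream) and *b*, *a*'s 3′ overhang is the
distance from the pairing image of its 3′ end to *b*'s 5′ end; a
Dicer-consistent duplex has both overhangs = 2 and overlap in [18, 22].
Calls require ≥ 10 bp mutual overlap so incidental co-located fragments do
not flood the output.

## Cluster prediction

Sliding windows (5 kb, step 1 kb) are *hot* when their summed weight is at
least `density_factor` (10) times the genome-average weight per window and
at least 25 distinct sequences start inside.  Overlapping hot windows
merge; before trimming to the outermost hits, sparse edge blocks are peeled
(hits are grouped into blocks separated by > 500 bp; edge blocks carrying
< 5 % of the candidate's weight are dropped) — without this, a single
background read inside the outermost hot window stretches a boundary by up
to a window length.  Candidates must then be ≥ 1 kb with ≥ 75 % of weight
on sequences carrying the piRNA signature (5′ U or position-10 A) and
≥ 75 % of weight in the 24–34 nt window.  All thresholds are configurable.

Topology: monodirectional if one strand holds ≥ 90 % of weight.  Otherwise
every boundary between adjacent 5′ ends is scored as a divergent split
(minus-left/plus-right or the reverse) by the sum of the two sides' strand
purities, with the constraint that each side keep ≥ 20 % of the weight — a
handful of edge hits must not fake a divergent topology.  The best split
wins (ties to the smallest coordinate); the cluster is bidirectional if
both purities reach 75 %, else mixed.  Note that with a substantial
ping-pong fraction a planted monodirectional cluster carries ~25 % of its
weight on the opposite strand and is reported *mixed* under the default
90 % threshold; this is the thresholds' faithful answer, not an error.

## Motif scanning and enrichment

Scanning is log-odds against background base frequencies estimated from the
scanned sequence, with a pseudocount of 0.01 added per matrix cell; a
window is a hit when its score reaches `threshold` (default 0.8) of the
maximum attainable log-odds, and overlapping same-strand hits of one PWM
within a motif length collapse to the best scorer.  Enrichment uses
scanned-position accounting: the 2×2 table is [[hits_in, bp_in −
hits_in·L], [hits_out, bp_out − hits_out·L]], tested by Pearson chi-square
(df = 1, right tail, no continuity correction).  Type-I calibration of this
construction on uniformly placed sites is part of the test suite.  The two
built-in matrices are synthetic stand-ins that back the simulated world;
real UniPROBE-style matrices are user-supplied inputs (plain 4×L text or
MEME minimal format).

## Conservation

Ortholog search: exact 12-mer seeds between the cluster sequence and the
second genome, merged on shared diagonals into ungapped anchors (seeds
within 120 bp merge; anchors must span ≥ 30 bp at ≥ 60 % identity), then
the heaviest co-linear chain by total anchor bp (ties to the smallest
genome-B start), accepted at ≥ 200 anchored bp.  The reported homologous
interval is the **full-cluster projection** through the chain ends, not the
anchored core: measuring identity over anchored spans only would exclude
hard-to-anchor low-identity edges and bias conservation upward (~+2.5
points at 40 % divergence in our simulations).  Only the forward strand is
searched; the homolog model has substitutions and small indels, not
inversions.

Realignment is local with affine gaps over the paired spans in one dynamic
program (blocks tile the chained region; a single DP avoids double-counted
boundary columns).  Default scoring is match +5 / mismatch −4 / gap open 25
/ extend 5.  The stiff gap penalties are deliberate: with the permissive
12/4 convention of classic DNA aligners, the DP silently re-pairs the
worst-matching stretches through compensating gap pairs — in simulations,
segments with true identity ~23 % realign to read ~75 %, inflating
non-coding identity by 2–3 points above the generating substitution rate.
Orthologous piRNA clusters carry almost no true indels at these
divergences, so stiff gaps cost little and keep per-column identity an
unbiased rate estimate; the scoring is configurable when indel-rich inputs
demand it.

A column is piRNA-coding in a species when ≥ 1 mapped read covers its
residue; column weight is reads_A/T_A + reads_B/T_B with T the species'
total mapped reads, correcting for library size.  Identity per class is
identical / non-gap columns; weighted identity rescales weights to the
class column count before tabulation, so chi-square tests against the
all-columns baseline stay on the count scale.  Under uniform weights,
weighted identity equals plain identity exactly.

## Structure

TE sense transcripts (minus-strand loci reverse complemented) are folded to
their MFE structure with lonely pairs disallowed; loci over 10 kb are
skipped.  The engine contract is `sequence -> dot-bracket`, defaulting to
the ViennaRNA bindings; tests substitute deterministic stubs so results do
not depend on a thermodynamic engine version.  Per-hit paired fraction is
the paired share of the (transcript-clipped) footprint; class means weight
hits by read count, with a pooled-bases mode available.  The transcript-
wide reference is the unweighted paired fraction over all folded bases.
Bootstrap SDs resample sequence records with replacement to the original
count (100 replicates, seeded).

## The synthetic world

The generator's defaults are the study conditions: three 300 kb
chromosomes (clusters must be a small fraction of genome bp — roughly 4 %
here, mirroring ~1 Mb of clusters in a multi-Gb genome — or a genome-
average density cutoff could never separate them); four TE families
(SINE/LINE/DNA at 12–18 % mean divergence, drawn per copy, plus a perfect
inverted-repeat MITE built from a 60 bp stem and 9 nt loop); four 10 kb
clusters at depth 500 with 1U fraction 0.85 (non-U1 reads are
rejection-sampled to a non-U 5′ base so the realized fraction equals the
configured one) and ping-pong fraction 0.3.  Partners overlap the primary's
5′ end by exactly 10 bp; when the primary starts with U the partner's
position 10 is the complementary A — the 10A bias emerges from
complementarity, it is never painted onto the genome.  Read counts follow
P(c) ∝ c⁻² capped at 10⁴ (sRNA libraries are heavy-tailed).  Duplexes are
phased from the stem base in steps of the duplex length, as processive
Dicer measuring from the 2 nt-overhang end produces; MITE copies sit on the
+ strand (an inverted repeat is its own near-reverse-complement, so
orientation carries no information).  The homolog applies per-base
substitution at class rates (motif sites 0.20, read-covered residues 0.30,
the rest 0.40 — "piRNA-coding" is defined by read coverage, matching how
the conservation module classifies columns) plus small indels outside
clusters only, keeping cluster columns well defined; the per-base
correspondence is retained as truth.

Not emulated: sequencing error, adapters, quality scores,
periodate-treatment survival, transcription-unit structure, and real TE
phylogenies.  Passing tests therefore demonstrate correctness of the
computational stages under a faithful geometric/statistical model of the
signals, not performance on real libraries.

## Problem sizes and determinism

The test suite and the acceptance script run on desk-scale worlds (50 kb –
3 Mb genomes, hundreds to thousands of reads, 10–50 replicates for
calibration loops) chosen so the full suite completes in about a minute
while leaving every statistical check well-powered.  All randomness flows
from a single seed per study (`numpy.random.default_rng`; the CLI threads
its `--seed` through every stage), and pipeline outputs are byte-identical
across reruns with the same config and seed.
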