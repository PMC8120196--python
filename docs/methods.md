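# Methods

## Pipeline model and assumptions

clipins detects novel-sequence insertions ≥ 50 bp in a diploid sample from a
coordinate-sorted paired-end short-read alignment.  It assumes an FR library
with an approximately normal insert-size distribution, reads short relative
to the fragment, and breakpoint-bearing reads soft-clipped (not hard-clipped)
by the upstream aligner.  Three stages run in order: breakpoint detection
(clip screen → clip-type evidence → insert-size support filter), genotyping
(DBSCAN over spanning-pair insert sizes), and local assembly of the inserted
sequence.  All internal coordinates are 0-based half-open; only the VCF
writer emits 1-based positions.

## Clip screen

For a clip with sequence S_c at boundary p, the reference continuation S_r is
the |S_c| bases immediately left (head clip) or right (tail clip) of p — the
bases the clipped part would occupy if the read carried no insertion.  The
score is the maximum cell of a Smith–Waterman matrix; with the default
scoring (match +1, mismatch and gap prohibitive) that maximum is exactly the
longest common substring, which keeps the decision scale-free in the clip
length.  The clip is kept when `score < |S_c| · m`.  Choices:

* `m = 0.5` (default).  Random 10–150-mers share runs of ~4–10 bases, well
  under half their length, so insertion-derived clips pass; clips caused by
  slightly shifted alignment share long runs and fail.
* `min_clip_len = 10`: below 10 bp the threshold `|S_c|·m` collides with the
  run lengths expected by chance and the decision degenerates.
* Truncated S_r at contig edges: the effective length in the threshold is
  `min(|S_c|, |S_r|)`.
* Ambiguity bases never match.
* The opposite reading of the screen (keep high-similarity clips) is
  available as `ScreenConfig(invert=True)`; it is not the default because
  the kept set must be the clips that look like novel sequence.
* Standard SW scoring (e.g. −1/−1) is available via `sw_mismatch`/`sw_gap`
  for sensitivity analysis.

## Breakpoint evidence and filtering

Clips are typed by (mate role, clipped end) and grouped by single linkage
within a 10 bp window (the same tolerance used for benchmarking); the
candidate position is the lower median of member boundaries, robust to one
stray clip.  The evidence predicate `J = (LL ∨ RL) ∧ (LR ∨ RR)` demands
support from both sides of the insertion; a candidate supported by, e.g.,
head clips only ({LL, RL}) is rejected but kept in the diagnostics table.
One read contributes one vote per type.

The support filter counts, inside `[p − (μ+3σ), p + (μ+3σ))`, pairs whose
fragment outer span straddles p (`start < p ≤ end`, pair counted once) and
OEA pairs (exactly one mate mapped; orientation is not checked — the
alternative of requiring the anchor to point at p would only tighten the
filter).  The candidate is kept when `spanning + OEA > Cov/2` (strict) and
at least `min_support = 2`, the floor preventing single-read passes in
libraries with Cov < 4.  μ, σ are estimated from proper-pair template
lengths — mean by 5 % symmetric trimming, σ by 1.4826·MAD.  The MAD
estimator is used instead of a trimmed SD because the trimmed SD is not
consistent for σ at the normal (5 % two-sided trimming biases it to ≈ 0.79 σ)
while the scaled MAD is consistent and equally robust to chimeric-pair
outliers.  Coverage is mapped bases over genome length, overridable in
configuration.

## Genotyping

For every both-mapped, unclipped pair whose fragment spans p, the triple
(P_l, P_r, i) is recorded with i = |template length|.  Pairs with a
soft-clipped member are excluded: a clip truncates the apparent outer span at
the clip boundary, so such pairs measure clip placement, not fragment
geometry, and their inclusion smears the insert-size modes (measured effect:
homozygous sites intermittently split into spurious clusters).  DBSCAN runs
on i alone — the triple mixes coordinate and length axes under one eps,
which is dimensionally incoherent; the full triple remains available via
`feature_space="full_triple"`.  Defaults `eps = 50`, `min_samples = 2`.
Two or more clusters ⇒ heterozygous, else homozygous; fewer than
`min_samples` pairs ⇒ homozygous with a low-confidence flag (no library-mode
pairs were seen, consistent with both haplotypes carrying the event).  The
inverse mapping (one cluster ⇒ heterozygous) is kept behind
`rule="literal"`; the default follows the generative logic: a homozygous
site shifts every spanning fragment, a heterozygous site leaves half of them
at the library mode.

### Known limitation: genotype resolution

The genotype signal is intrinsically weak at standard library parameters.
Two effects compound:

1. With insert-size spread σ = 50 and cluster radius eps = 50, the shifted
   and unshifted modes merge whenever the insertion length I leaves no empty
   ≥ 50 bp gap between the two samples — in practice for I ≲ 3–4σ.
   Heterozygous insertions shorter than ~200 bp are therefore typically
   called homozygous.
2. A fragment spans the insertion with both mates fully matching only if its
   length is ≥ 2·read_len + I, so for I near the upper end of 50–300 bp the
   number of clean shifted pairs is ~Poisson(2) at 30X and a second cluster
   (min_samples = 2) rarely forms.

On the standard 30X benchmark (50 insertions of 50–300 bp, half
heterozygous) genotype accuracy on true positives is ≈ 0.52–0.56: homozygous
sites are nearly always correct, heterozygous sites mostly miscalled below
~200 bp.  This is a property of insert-size cluster counting at these
parameters, not of the implementation; breakpoint detection and assembly are
unaffected.

## Assembly and placement

Abnormal reads around a confirmed breakpoint — soft-clipped reads, both
mates of OEA pairs, unmapped reads with an anchored mate — are deduplicated
by (name, mate) and assembled on a de Bruijn graph: k = 31 (odd, below read
length, standard for short-read unitigging), k-mers with count < 2 dropped
(isolated sequencing errors yield singleton k-mers), dead-end tips ≤ 2k
clipped, unitigs ≥ 100 bp emitted.  The graph is built on the stored
(genome-forward) orientation of the reads; a Minia-compatible external
assembler can be substituted through a command template with the same
contract.

Each contig is placed against the reference window `[p − (μ+3σ), p + (μ+3σ))`
by a two-flank dynamic programme: both flanks align gaplessly (mismatches
scored −1, matches +1) ending/starting at a common reference offset, and the
contig bases skipped between the flanks become a single `I` operation.
Gapless flanks are adequate because the k-mer count floor removes nearly all
error k-mers, leaving contigs essentially error-free; the placement
tie-break prefers the most balanced split so a pure-reference contig yields
an all-M alignment rather than a degenerate one-sided one.  Both
orientations are tried (forward wins ties).  A placement is rejected when a
flank is shorter than 20 bp or below 90 % identity; an extraction requires
exactly one `I` ≥ 50 bp.  When several contigs place, the longest single
insertion wins.  Assembled insertions (and the simulator's truth records)
are canonically left-aligned — an insertion bordering matching reference
bases has several equivalent placements, and normalizing both sides makes
exact-sequence comparison well defined.  Sites whose assembly yields no
placeable contig are reported without sequence, not dropped.

## Synthetic data

The simulator emulates a whole SV-implantation + read-simulation + alignment
stack at desk scale.  Defaults are the standard study conditions: uniform
random reference, insertions of 50–300 bp with novel uniform-random content,
half heterozygous, 150 bp reads, insert size Normal(500, 50), 0.1 %
substitution errors, coverage split evenly between haplotypes, insertion
spacing ≥ 2(μ+3σ) so evidence windows never overlap.  Reads are aligned
*analytically* through the exact haplotype→reference coordinate map: full-M
when wholly reference-derived, soft-clipped at the insertion point when the
reference anchor is ≥ 20 bp, unmapped (OEA) otherwise.  Template lengths are
outer spans of the mapped coordinates, so insertion-crossing pairs show the
expected i = L − I shift.

What this does *not* emulate — and therefore what green tests do not
demonstrate about real data: repeat-induced mis-mapping and mapping-quality
structure, indel sequencing errors, quality-dependent error profiles, clip
placement dialects of real aligners at homopolymers, duplications or
mobile-element insertions (insertion content is always novel), and GC bias.
In particular the insertion-free negative control contains no spurious
clips by construction, so the measured precision reflects the evidence and
support gates, not robustness to alignment artifacts.  A FASTQ export is
provided for integration checks with a real aligner.

## Benchmarking

Calls match truth greedily nearest-first, one-to-one, within 10 bp;
precision/recall/F are on the percent scale with F the harmonic mean.
Genotype concordance is reported separately from position metrics.
Benchmark problem sizes (500 kb genome, 50 sites, 30X/5X) were chosen as the
smallest configuration that gives ≥ ~40 supporting fragments per site at
30X and keeps every site's evidence window disjoint; results are stable
across seeds (detection metrics vary by ≤ a few percent).

## Numerical and degenerate-input choices

* Clip grouping and DBSCAN labels are canonicalized so results are invariant
  to input order; re-running the caller on identical input is byte-identical.
* Library estimation requires ≥ 100 proper pairs; fewer is a fatal error.
* Empty inputs: no clips ⇒ no candidates; no spanning pairs ⇒ low-confidence
  homozygous; assembly with < 2k input bases ⇒ sequence-less call.
* Reads with MAPQ 0 are kept by default (`--min-mapq` to change).
* Hard clips are ignored (their sequence is unavailable).
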