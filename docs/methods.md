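# Methods

This note documents the models and procedures implemented in `sncrna`,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical conventions. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Annotation hierarchy

Reads pass through a fixed hierarchy so that no read is ever counted
twice: adapter trimming (optional) → low-complexity filter → miRNA
tiers → ncRNA/cDNA classes with tRF classification → piRNA clusters →
not annotated. The pipeline asserts at the end of every run that the
per-category counts sum to the total input reads (tolerance 1e-6);
fractional counts arise only from the apportioning and multi-gene
splitting rules, both of which conserve totals exactly.

## Adapter inference and trimming

Raw reads of a fixed-length sequencing run end in the 3′ adapter when
the insert is shorter than the read. The motif length is
m = n − 22 clamped to [6, 12], where n is the modal raw read length
(read-count weighted; ties broken toward the longer length) — the
22-nt offset reflects the typical miRNA insert. The motif is the most
frequent m-mer starting after read position `ignore_5p` (default 22),
read-count weighted, ties broken lexicographically so inference is
deterministic. Libraries dominated by longer inserts (e.g. tRNA
halves) can raise `ignore_5p`.

Trimming: the full motif is searched anywhere in the read (leftmost
occurrence) with a mismatch allowance tied to motif length — 2 for
12 nt, 1 for 9–11 nt, 0 for 6–8 nt. If absent, the motif is truncated
one 3′ base at a time (allowance re-derived from the truncated length,
hence monotone non-increasing) and tested against the read's 3′ end
only, down to 6 nt. Zero-length inserts are discarded.

The positional-bias pass aligns the trimmed reads at their 3′ termini
and, while the most frequent terminal base exceeds `bias_threshold`
(default 0.8, strict inequality), strips that position from the reads
ending in it, at most 5 positions. This removes residual adapter
stubs shorter than the minimal 6-nt motif and absorbs a systematic
off-by-a-few in motif detection: when detection settles on a shifted
adapter window, every read retains the same 1–3 leading adapter bases,
which the bias pass then removes uniformly.

## Low-complexity filter

`repeat_fraction` is the largest fraction of the read covered by
non-overlapping occurrences of one 1–5-nt motif, counted anywhere in
the read (tandem repetition is not required — the permissive reading of
a duster-style filter). Self-periodic motifs are canonicalized to their
primitive root before counting. `two_nt_fraction` is the largest
fraction of positions drawn from one of the six unordered base pairs.
A read is rejected iff repeat_fraction > f (default 0.75) or
two_nt_fraction > f + (1−f)·f (0.9375 at the default); both
inequalities strict, so exact-boundary reads are kept.

## Ungapped mapper

Reference collections are small-RNA scale, so the mapper is a
pigeonhole seed-and-verify scan per read/reference pair rather than an
indexed genome aligner: a read with ≤ k substitutions must contain one
of k+1 segments exactly, and exact segment hits enumerate candidate
diagonals which are then verified. Reads containing N never align.
Minus-strand hits are found by mapping the reverse complement and
recording mismatches in read orientation.

Non-template 3′ tails are split by the terminal-run rule: the tail is
the maximal run of consecutive 3′-terminal bases that each disagree
with the template continuation (or lie beyond the reference end). A
terminal base that matches the template stays in the core, so the
templated explanation is always preferred and the reported tail is the
minimal one consistent with the data; a run longer than `max_tail`
(default 2) voids the hit at that locus. One consequence: a
post-transcriptionally added base that coincidentally matches the
genomic continuation is indistinguishable from templated sequence and
is treated as such.

## miRNA tiers

Matures are located on their hairpins by exact coordinates (validated
at load). A read is assigned to the first tier with ≥ 1 hit:
canonical (5′ end at the mature 5′ end, no tail), tailed (same start,
1–2 nt non-template tail), offset (5′ end within ± `offset_window` of
the mature start but not at it), tailed-offset. The window defaults to
± 5 nt, the span reported for offset miRNAs (moRs) in the literature;
reads elsewhere on the hairpin are not miRNAs. Internal modifications
(≤ 1 by default) are substitutions at templated positions, reported in
mature coordinates; offset reads may carry them too. The self-species
pass precedes a cross-species pass over the union of all other species
in the reference, and each hit records its source species. Multi-gene
hits within the winning tier split the read count uniformly per gene.

## ncRNA classes and tRFs

Mapping is plus-strand only (ncRNA fragments are sense degradation
products) with ≤ 1 mismatch by default. For each sequence the best
hits are those with the minimal mismatch count; the distinct classes
among them define hᵢ and the class counts are
c_class = Σ rᵢ/hᵢ. tRNA references carry genomic flanks
(`pad5`/`pad3` header fields); reads ending in CCA that fail to map
directly are retried with the CCA split off as a non-template tail,
reflecting post-transcriptional CCA addition to mature tRNAs.

tRF classes use cloverleaf landmarks projected proportionally from the
canonical 76-nt tRNA — D-loop end 25, anticodon loop 31–39, TψC start
52 — with a ± 2 nt anchoring tolerance (all configurable). Secondary
structure prediction is deliberately out of scope; the proportional
projection is a declared convention, adequate for cytoplasmic tRNAs of
70–90 nt but approximate for bizarre (e.g. some mitochondrial) tRNAs.
tRF-1 requires an oligo-T (≥ 4 T) signal in the trailer; the fragment
must start within tolerance after the mature 3′ end and end at or
before the end of that signal. A read reaching the mature 3′ end with
a CCA (templated or not) is a 3′ CCA-tRF.

## piRNA candidates and the ping-pong signature

Residual reads are mapped to piRNA cluster references exactly
(0 mismatches by default — piRNA candidates are sequence-diverse, and
exact mapping limits false positives) on both strands. The ping-pong
histogram adds the product of read counts for every opposite-strand
pair whose 5′ ends overlap by d ∈ 1..20; the Z-score compares bin 10
with the sample mean and standard deviation of the other 19 bins and
is undefined (reported NA) when the background is constant. The 1..20
background window is the declared convention of the cited Z-score
method.

## phasiRNA detection

Reads of length i are consolidated to plus-strand registers: plus
reads keep their leftmost coordinate, minus reads shift by −2 nt (the
Dicer 2-nt 3′-overhang geometry), so perfect duplex partners share a
register. Windows of `window` nt (default 1000, ≥ 8 phase cycles) slide
by `step` (default window/2); only windows with ≥ 1 length-i read are
analyzed and counted for the Bonferroni divisor. Per window, the
register (position mod i) with the largest read count defines j, and
p = P(X > j) for X ~ Binomial(n, 1/i) — exactly the printed upper-tail
convention; a documented `inclusive_tail` flag switches to P(X ≥ j).
A window is called iff p < alpha / n_windows (alpha 0.05) and passes
the post-filters: phased fraction ≥ 0.5, phased reads at ≥ 5 distinct
consolidated positions, and no more than 90 % of phased reads from one
strand (the source material mentions both 90 % and 95 % caps; 0.9 is
the default here and the parameter is exposed). Overlapping called
windows merge into maximal runs for reporting and phasiRNA lists are
deduplicated. p-values use the regularized incomplete beta through
`scipy.stats.binom.sf`, stable to n = 1e5; tests pin them to exact
rational arithmetic to 1e-12 for n ≤ 60.

## Synthetic data

The generators are deterministic under a seed and attach truth labels
sufficient for confusion matrices, so the entire suite runs without
downloads; real reference files in the same header dialects are
drop-in replacements.

* **Hairpins/miRNA grid**: random ~60-nt precursors with one planted
  21-nt mature (8-nt 5′ flank leaves room for −5 offsets). The grid
  enumerates offsets −5..+5 × all 0–2-nt tails over ACGT × {0, 1}
  internal substitutions (placed away from both termini so the planted
  anchor and tail survive). Truth tiers are re-derived from the
  finished read against the hairpin: a dialed tail base matching the
  template continuation is templated in reality and labeled
  accordingly, and cells whose tail/template coincidences leave more
  than one core mismatch are skipped as degenerate — they are not
  annotatable miRNA reads under the tail convention above. Optional
  per-gene count weights emulate an expression profile.
* **tRNAs/tRF set**: random padded tRNAs (76- and 72-nt matures, 20/30
  nt flanks) with one oligo-T planted in a T-free trailer; one read
  per tRF class per tRNA, exactly half of the emitted sequences
  receiving one internal substitution on a deterministic schedule.
* **Phased loci**: planted runs of consecutive phase registers with
  alternating strands (minus reads placed by duplex geometry) on a
  random genome, plus uniform background that by default stays ≥ 1 kb
  away from the loci — the sensitivity property concerns out-of-window
  background; in-window background legitimately defeats the
  phased-fraction filter and a dedicated test covers that case.
* **Adapter libraries**: error-free reads (insert + adapter) at 36 nt
  with miRNA-scale inserts (24–28 nt), or a fixed 2-nt adapter stub for
  the bias-trim scenario. Inserts are screened so that no adapter
  window near-match (within the trimmer's mismatch ladder) occurs
  upstream of the true boundary: a read violating this has an
  ill-defined insert that no adapter remover could recover.
* **Ping-pong pairs**: opposite-strand pairs with exact 5′-overlap d,
  or independently placed minus reads as the null. Null simulations
  use dense sets (1000 pairs on 20 kb) so background bins are out of
  the sparse-count regime where the Z statistic is lumpy.

What the generators do **not** emulate: sequencing errors beyond single
substitutions, quality scores, 5′ adapters, expression-dependent length
heterogeneity within a class, genomic repeat structure, SNP-vs-editing
ambiguity, and cross-class sequence homology (references are random, so
class cross-talk is far rarer than in real genomes). Passing tests
therefore demonstrate algorithmic correctness under the declared
conventions, not annotation accuracy on real libraries.

## Problem sizes and numerical conventions

Validation runs use desk-scale problems chosen to exercise every code
path: 50 hairpins (~10⁴–10⁵ grid reads with expression weights) for
miRNA recovery, 20 tRNAs × 8 classes for tRFs, 1000 random hit tables
for apportioning, all (j, n ≤ 60) × i ∈ {21, 24} for the binomial tail,
3 planted loci × {1, 10} reads/position × background sweeps plus 100
null replicates for phasing, 300 planted pairs and 100 dense null
replicates for ping-pong, 1100 adapter reads, and complexity-oracle
equivalence exhaustively through length 5 plus 300 random 6–12-mers.

Ties break deterministically everywhere (lexicographic for motifs and
registers, sorted keys in outputs), rounding of tRF boundaries is
half-up, and all randomness flows through `numpy.random.default_rng`
seeds, so identical inputs give byte-identical outputs.

## Known limitations

* No de novo miRNA or ncRNA gene prediction; annotation quality is
  bounded by the supplied references.
* No gapped alignment; isomiRs arising from templated indels are
  missed.
* tRF boundaries are proportional projections, not structure-derived.
* BAM, paired-end reads and base-quality-aware trimming are out of
  scope; map files must be SAM (ungapped records) or the 6-column
  ELAND3 dialect defined in `sncrna.io`.
* The ping-pong Z-score inherits the arbitrariness of its 1..20
  background window; values from different window conventions are not
  comparable.
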