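# Methods

This note documents the models and procedures implemented in `milscan`,
the parameters that matter, the synthetic data the tests rely on, and the
design decisions taken where more than one reading was defensible.

## Preprocessing

Reads are trimmed by exact match against a prefix of the 3' adapter
(default: Illumina TruSeq small-RNA, `TGGAATTCTCGGGTGCCAAGG`), requiring
at least 5 nt of overlap reaching the read's 3' end. Matching is exact —
no mismatches, no error rate — which keeps the stage deterministic; this
is a deliberate simplification relative to error-tolerant trimmers and is
adequate for libraries whose adapters are sequenced faithfully. Reads in
which no adapter is found are discarded entirely (untrimmed reads are not
analysis-safe: their 3' boundary is unknown). Inserts are kept at 15–36 nt,
collapsed to unique sequences with multiplicities, and filtered to a
minimum count of 10. The count filter is the main defence against
degradation noise: a fragment must recur identically ten times before it
is believed. A mean-quality filter exists but defaults to off; quality
strings are otherwise ignored.

## Mapping

Only perfect matches count. A k-mer index (k = 12) proposes candidate
positions for a read's first k-mer; every candidate is verified by
full-length comparison, so seed length affects speed only, never results.
Reads containing N never map. All hits on both strands are reported —
multi-mapper policy is deliberately deferred to downstream consumers,
because the category tables need every placement and the discovery stage
seeds from each placement independently. Minus-strand hits are recorded at
forward-strand coordinates.

## Category tables

An alignment belongs to an exon, intron, tRNA or rRNA only when fully
contained in it; a read straddling an exon–intron junction inside a gene
span is tallied at the gene level only (this prevents a read from being
counted as both exon and intron). A read contained in no annotated span is
intergenic. Per library, a unique read contributes once to every category
it hits anywhere in the genome — weighted by its count in the "total"
tally, by 1 in the "unique" tally. Two consequences are intended: category
sums may exceed the mapped-read totals (multi-category reads), and a
category total may be smaller than its sense + antisense split (a read
hitting the category in both orientations counts once in the total but
once per orientation row). Percentages round half-up at the requested
precision.

## Locus calling and Dicer-dependence

Loci are built per contig by strand-blind single-linkage chaining: sort
alignments by start, chain while consecutive starts are ≤ 300 bp apart,
keep chains holding ≥ 4 distinct read sequences. "Sliding interval of
300 bp" admits several anchorings; start-to-start single linkage is the
simplest and both constants are config fields (`LocusConfig.window`,
`min_unique`). Strand-blind chaining is essential: the most informative
locus class produces sRNAs from both strands. Each locus is classified by
the annotation class with the largest bp overlap of its envelope
(ties broken rRNA > tRNA > exon > intron > intergenic — structural classes
dominate), with orientation from member strands vs feature strand for
exon/intron and both/strand-specific for the rest.

A Dicer-proficient locus with no interval-overlapping locus (≥ 1 bp, any
strand) in the Dicer-deficient library is Dicer-dependent, split into
`dicer_dependent_both` / `dicer_dependent_single` by its own strand
content.

## TPTM and per-read classification

The denominator is the count-weighted sum of mapped unique reads with no
hit overlapping a tRNA or rRNA — each unique sequence counted once, no
matter how many loci it hits (the alternative, per-hit counting, is a
config question deliberately not taken: it would let a single repetitive
read dominate the denominator). Structural reads still receive a TPTM
against the same denominator so they can be inspected, but do not shape
it. By construction the non-structural TPTMs sum to 10⁷ exactly.

Classification uses fixed fold-change thresholds, not a dispersion-based
test — with single libraries per condition there is no replication to
estimate dispersion from. Boundaries are inclusive on the dependent side:
log₂ = −1 is "slight", log₂ = −2 is "strong". Zeros never enter a ratio;
they get the categorical labels `absent_in_mut` / `mut_specific`.

## Folding engine

The discovery stage folds with a maximum-pairing dynamic program: pair
scores WC = 2, G:U = 1, minimum hairpin loop 3 nt, nested structures only.
Among score-optimal structures, ties break toward the structure with the
most stacked (adjacent) pairs — implemented by packing (score, stacks)
into one integer per DP cell, so plain `max` performs the lexicographic
comparison; the inner loops are numba-compiled. The reported
`energy_score` is −(2·stacked-WC-pairs + other pairs): a pairing score in
the artifact's own units, **not** a thermodynamic free energy. A full
nearest-neighbour model would add nothing to the discovery decision, which
only needs arm/loop geometry; the test suite cross-checks the engine
against an independent recursive maximizer and, on a designed perfect
stem, against RNAfold's structure.

## milRNA discovery

Seeds are unique reads with count ≥ 10 whose hits avoid tRNA/rRNA. Around
each placement two windows are excised — 70 nt upstream / 20 downstream
and the mirror (strand-aware, clipped at contig ends) — covering the
43–89 nt precursor range with either arm as mature. A window is accepted
when:

* ≤ 2 base pairs lie entirely inside the mature window (Nussinov pairs
  opportunistically; a real mature does not self-pair beyond that);
* ≥ 75% of the mature's pairing partners lie on one side (the arm), and
  those partners cover ≥ 60% of the mature (`paired_frac`);
* the star arm exists as an ungapped near-reverse-complement of the
  mature on that side: best window scoring WC = 1, G:U = 0.5 must reach
  75% identity. This duplex check, not the global fold, locates the star:
  bulge-tolerant maximum-pairing "helices" in random sequence are dense
  enough that partner-span bounds cannot separate them from true duplexes
  (tried and abandoned), whereas a ≥ 75% contiguous complement is rare in
  background (~10⁻⁴ per window);
* ≥ 90% of the (count-weighted) reads inside the window fall entirely
  within the mature, star or loop windows — mature/star padded 2 nt on
  the 5' side and 5 nt on the 3' side, matching the 3'-heterogeneity of
  Dicer products. The star window carries the canonical 2-nt 3' overhang.

Surviving windows score
`10·signature_frac + 10·paired_frac + 5·[star reads ≥ 1] + log₂(1+mature count)`
and are kept at ≥ 20; overlapping candidates deduplicate keeping the best
score. The cutoff and the structural thresholds above were calibrated on
the simulator so that planted hairpins pass and degradation stacks fail;
all are `MilConfig` fields. The reported precursor is the mature–star
envelope, formatted 1-based inclusive (`Chr: a–b`, `rev(a–b)` for minus).

## Target prediction

Hypothetical 3'-UTRs are the 1-kb genomic windows downstream of each gene
on the coding strand (clipped and flagged at contig ends). The
animal-style scorer is a Smith–Waterman local alignment of the reversed
milRNA against the UTR: WC +5, G:U +2, mismatch −3, gap −8, substitution
scores doubled at milRNA positions 2–8; the gap penalty is flat (the
doubling applies to position scores, i.e. substitutions). A perfect
21-mer site scores 140; the default support threshold is 112 (80%). The
plant-style scorer is the minimum over ungapped windows of
mismatch·1 + G:U·0.5, doubled at positions 2–13, qualifying at ≤ 4. Both
scorers agreeing within 3 nt marks a site as dual-supported.

A site is flagged `star_only` when it belongs to the milRNA's own duplex
rather than being an independent target: either the star arm out-scores
the mature as a binder of the site window, or the window sequence itself
matches the star arm better than it matches the mature's perfect
complement. The second clause is what fires in practice — for a
near-perfect hairpin the star *is* the mature's best complement, so any
precursor falling inside a downstream window produces a perfect-looking
"target" that only the sequence-identity comparison exposes.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not sequencing chemistry. Defaults: 2 contigs × 50 kb of uniform random
sequence; 40 genes of 1–3 exons (exons 120–300 bp, introns 60–120 bp),
8 tRNAs (75 bp), 4 rRNAs (500 bp), 10 hairpin milRNA genes (21-nt mature,
5' U with probability 0.65, 8–20 nt loop, star = reverse complement with
10% of positions mutated, random strand, intergenic), 20 double-stranded
sRNA loci (≈250 bp; half on exons, half intergenic) and 5 planted UTR
target sites (near-complements with two mismatches at milRNA positions 10
and 15 — outside the animal seed, invisible to the perfect-match mapper,
still within both scorers' thresholds). Inter-feature spacing always
exceeds the 300-bp chaining window so features never merge into one
locus.

Reads are emitted from templates: per hairpin, three mature-length
variants (lengths 21 ± truncated-geometric jitter in [17, 25], 5'
anchored) at expected depths 100/25/25 plus a star template at 5% of the
mature depth; per dsRNA locus, six templates per strand at depth 30 with
the 5'-U start bias; background from rRNA (8 templates each), tRNA (4)
and two exon-sense templates per gene, uniform 15–36 nt, no 5' bias —
two per gene keeps coding genes below the 4-unique locus threshold, so
Dicer-null loci arise from structural RNAs, as expected for a Dicer-null
library. Template counts are Poisson; the Dicer-null library divides
Dicer-class rates by the depletion factor (16). Every read carries the
adapter so preprocessing is exercised, and every template carries a
class label (`dicer`/`background`) in the ground truth. All randomness
flows from one seeded generator; runs are bit-reproducible.

What passing the recovery tests shows — and does not show: the pipeline
correctly separates the two read classes *under the generator's
assumptions* (perfectly mappable reads, independent Poisson counts, clean
hairpins, no sequencing error, no adapter dimers, no GC bias, a 60×
smaller genome than a real fungus). Behaviour on real libraries with
repetitive genomes, error-containing reads or partial Dicer redundancy is
not certified by these tests.

## Problem sizes and runtime

The default simulated experiment (≈13k + 5k reads, 100 kb genome) runs
the full pipeline in well under a minute on one CPU; the test suite
(including two full pipeline runs, a 1000-case mapper-oracle suite and a
500-case folding-oracle suite) completes in about half a minute. These
sizes were chosen so that every property is exercised at depths where the
expected signals (count ≥ 10 after a 16× depletion, 4-unique-read loci)
are comfortably above threshold, while iteration stays fast.

## Known limitations

* Adapter trimming is exact-match; heavily error-prone 3' ends would be
  discarded rather than rescued.
* The folding engine maximizes pairing, not free energy; its
  `energy_score` is not comparable to RNAfold MFEs.
* milRNA TPTM attribution gives each candidate the full count of its
  mature read even when the mature multi-maps.
* The target scorers are calibrated schemes, not reimplementations of
  miRanda/TAPIR/psRNATarget; their absolute scores are not comparable to
  those tools, and target-site accessibility (UPE) is not modelled.
* GFF3 input must be a single coherent genome+annotation pair; no
  lift-over, no GTF dialects.
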