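# Methods

This note documents the models and procedures implemented in
`splicestage`, the parameter defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions used throughout.

## Gene model and coordinates

Each gene is represented by one *reference transcript*: its exons in
transcription order, with introns derived as the gaps between
consecutive exons. Which transcript defines the structure is a genuine
degree of freedom; by default the transcript with the most exons is
chosen (ties broken by smallest transcript id), overridable per gene.
Multi-isoform simultaneous models are out of scope — every analysis is
relative to the one reference structure.

Coordinates are 0-based half-open internally and 1-based inclusive at
every interface (GTF, SAM, reported tables). Intron/exon *numbering*
follows transcription order on both strands — on the minus strand exon 1
is the genomically rightmost exon — so "upstream intron *i* / downstream
intron *i+1*" is meaningful regardless of strand. Genomic coordinates
are never flipped, only indices.

## Read-pair classification

Each aligned end is reduced to its contiguous reference segments
(CIGAR `M`/`=`/`X`/`D` extend a segment, `N` splits it) and labeled:

* `ex` — fully inside one exon;
* `int` — fully inside one intron;
* `ex-int` — contiguous across an exon–intron border;
* `ex-ex` — split whose gap(s) exactly match annotated intron(s), with
  all aligned segments exonic;
* `other` — split across any non-annotated gap. Such ends are excluded
  from pair classification but are exactly the input of the
  recursive-splicing detector;
* `outside` — escapes the gene span.

The pair category is a pure function of the unordered label pair and the
mapping-distance bucket (inner distance below/at-or-above the expected
distance). The full table is reproduced in the `classification` module
docstring and asserted exhaustively in the test suite. Two cells deserve
comment:

* `(ex, ex)` in one exon is *unknown* — exons are present at every stage
  of splicing, so the pair carries no stage information.
* `(int, int)` and `(int, ex)` become *intermediate* only in the
  outside-distance branch; within the expected distance they are *pre*.

**Thresholds.** The expected mapping distance and the large-distance
flag both default to 650 bp. The method's narrative value for the
expected distance is "around 500 bp", but its operational definition on
real data draws the line at 650 (<650 normal, ≥650 larger than
anticipated); the operational value is taken as the default and both
thresholds are configurable. The `large` flag is reported independently
of the category.

Counting is per read *pair* (mates resolved by name; secondary and
supplementary alignments ignored), and summaries report raw counts plus
fractions of classified pairs — no further normalization is applied.

## Splice Site Index

SSI = ex–ex / (ex–ex + ex–int), computed separately at each intron's 5′
and 3′ splice site, NA when no informative reads exist. "Spanning"
requires an anchor of ≥3 aligned bases on both sides of the
boundary/junction (configurable); the anchor suppresses 1-bp overhang
noise and is deliberately minimal. Ends of a pair are counted
independently and an end credits every distinct site it genuinely spans.
Coverage is per-base depth of aligned segments only (`N` gaps contribute
nothing); duplicates are kept, since replicate consistency — not
deduplication — is the method's noise control.

**Retention ranking.** A retained intron is unspliced at *both* sites,
so the retention magnitude of intron *i* is the joint lowness
mean(1 − SSI⁵, 1 − SSI³). The p-value is the empirical fraction of the
other introns with magnitude at least as large; the top-ranked intron is
a candidate when p < α (default 0.1). The SSI asymmetry |SSI⁵ − SSI³| is
reported as a separate column because it points at different events
(e.g. exon skipping: low SSI³ of intron *i* with low SSI⁵ of intron
*i+1*), not retention. Ties rank the lower intron index first.

## Splicing order

Two independent evidence types per adjacent intron pair (*i*, *i+1*):

* **Coverage:** delta = median(intron_{i+1}) − median(intron_i), per
  sample. Under the assumption that an intron present longer accumulates
  more coverage, a strongly negative delta suggests the downstream
  intron is removed first. Negative deltas are collected and the first
  quartile Q1 (linear-interpolation quantile, the common default; Q3
  available via config as the laxer variant) defines the cutoff. The
  candidate rule is boundary-inclusive (delta ≤ Q1): with a single
  negative delta Q1 equals that delta, and a strict rule could never
  flag the lone true candidate — the generic situation when exactly one
  pair is swapped in an otherwise sequential gene.
* **Reads:** seq = pairs with one end split across the junction of
  intron *i* and the mate inside intron *i+1* (upstream removed first);
  non-seq = the mirror configuration. splice-ratio = seq/(seq+non-seq),
  near 1 for sequential and near 0 for non-sequential removal.

A pair is **called** non-sequential when it is a coverage candidate in
≥ `min_samples` RNA samples, every flagged sample with read evidence has
ratio < 0.5, and the pair is *not* a coverage candidate in the DNA
control. The read-evidence requirement is waived when seq+non-seq = 0,
so low-coverage data can still be called on coverage alone. The control
comparison is on candidate membership, not raw deltas. The AND-coupling
of the two evidence types when both exist is a design choice; the
correlation between them (Pearson and Spearman, pooled over samples) is
reported so disagreement is visible. Only *local* order is inferred;
reconstructing the global removal order of a transcript from snapshot
data is not possible and not attempted.

## Recursive splicing

Split-read gaps that exactly match an annotated intron are discarded
(complete ordinary splicing); every other gap feeds the detector. The
*inverted coverage* counts gaps covering each position; its derivative
(value at p minus value at p−1) is nonzero only at split boundaries: a
gap [s, e) (0-based half-open) contributes +1 at s and −1 at e.
Positions that are simultaneously a split start and a split end are
excluded. Per-sample peaks are written as signed variableStep wiggle
tracks.

**Consensus:** a position survives when it appears with the same sign,
with per-sample magnitude ≥ 2 reads (singleton splits are the signature
of artifacts — a splicing-free control shows no split position supported
by more than one read), in ≥ `min_samples` samples; the reported value
is the magnitude summed over the supporting samples. Matching is exact
(0 bp tolerance); aligner soft-clip slippage must be handled upstream.

**Junction matrix:** supporting reads are re-extracted from the
alignments (the per-position track loses the connections), and each gap
whose start hits a consensus +peak and whose end hits a consensus −peak
is tallied into a donor × acceptor matrix. Reported coordinates are the
1-based splice-site bases: donor = last aligned base before the gap,
acceptor = first aligned base after it, in transcription sense (on the
minus strand the genomic-right boundary is the donor). Events are typed
5′-recursive (annotated donor), 3′-recursive (annotated acceptor) or
inner (two novel sites); gaps with both boundaries annotated are typed
exon-skipping and kept out of the motif percentages. Junctions sharing
one annotated site are grouped as multi-step chain candidates.

**Motifs:** donor motif = first two gap bases (GT when canonical),
acceptor motif = last two gap bases (AG), reverse-complemented on the
minus strand, with the two flanking retained bases also reported.
Summary percentages are computed only over events with exactly one
non-annotated site, stratified by the number of supporting samples;
double-novel events are omitted as likely novel exons.

**Novel exons:** an intra-intronic interval bounded by a consensus
−peak and the next +peak whose median coverage exceeds k× the containing
intron's median (default k = 2) is flagged as a putative novel exon, and
the flanking split events are removed from the recursive list. This
implements "high between-peak coverage ⇒ exonization" as a testable
ratio rule rather than an absolute peak-height cutoff. Distinguishing a
true novel exon from a recursive intermediate ultimately requires
assaying nuclear vs cytoplasmic RNA and is out of scope, as is
branch-point/lariat detection and splice-site strength scoring.

## Synthetic data

The generator emulates one gene locus sampled at mixed splicing stages.
Defaults: 7 exons of 120–200 bp, introns of 700–1500 bp, random sequence
with GT/AG planted at every annotated and planted splice site; stage
mixture 30% unspliced / 40% partial / 30% mature; fragment sizes
truncated-normal (mean 300, sd 80, min 200 = 2× the 100-bp read length,
so both distance buckets around the 650-bp threshold are exercised);
10,000 pairs per sample. Molecules are drawn from the mixture;
*partial* molecules remove a prefix of the removal-order permutation
(snapshot semantics — the minimal model of a co-transcriptional
snapshot); retention, exon skipping, recursive partial gaps
(annotated donor → planted intra-intronic acceptor) and cryptic exons
are applied per molecule at configured rates. Fragments are sampled
proportionally to molecule length, which naturally over-weights long
unspliced molecules the way real coverage does.

The truth table records, per pair, the source molecule structure, the
stage category the pair must classify into, and each end's exact gap
coordinates. Truth categories are derived by an independent route
(per-base feature maps and a literal copy of the decision table, not the
classifier's interval logic), so pipeline-vs-truth comparisons are a
genuine dual-route check.

Not emulated: sequencing errors and quality models (a uniform mismatch
rate exists for robustness checks only, default 0), capture/probe bias,
multimapping, PCR duplicates, and multiple overlapping genes. Passing
tests therefore demonstrate correctness of the *post-alignment* logic
under clean alignments, not robustness to alignment artifacts.

## Problem sizes and determinism

The test and acceptance experiments use 4,000–50,000 pairs per sample
(50,000 × 3 replicates for order recovery, where junction/intron linkage
reads are rare; 6,000 × 4 samples for recursive recovery), sizes at
which every recovered signal is far from its decision boundary while a
full run completes in well under a minute per experiment. All randomness
flows through explicit integer seeds; identical configurations produce
byte-identical FASTA/GTF/SAM/truth outputs, and the analysis stages
contain no randomness at all (re-running on the same inputs reproduces
byte-identical tables).

For the splicing-free null of the order caller, four control replicates
are evaluated with `min_samples = 4`: with pure noise each sample flags
roughly one arbitrary pair, so requiring the *same* pair in all four
samples drives the expected false-call rate below 1% — the same
consistency logic that makes single-sample candidates unreportable on
real data.

## Known limitations

* One reference transcript per gene; alternative first/last exons or
  isoform-specific introns are not modeled.
* The Q1 cutoff is a relative rule: it always ranks some negative delta
  first, so cross-sample consistency and the DNA control — not the
  cutoff itself — carry the burden of specificity.
* Exact-position consensus matching makes the recursive detector
  sensitive to aligner-dependent split jitter.
* The empirical-rank p-value of the retention module is a ranking
  device, not a calibrated test; with *n* introns its resolution is
  1/(n−1).
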