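# Methods

## Problem and model

`hrdkit` estimates homologous-recombination status from the composition of a
tumor's somatic mutation catalog. The model is a linear-kernel support
vector machine on six engineered features; everything upstream exists to
compute those features reproducibly from standard variant-level inputs.

### Context classification

Every somatic event maps to exactly one channel of its class.

**SBS-96.** A substitution is keyed by its pyrimidine-strand representation:
mutations with purine reference base are reverse-complemented together with
their trinucleotide context, giving 6 substitution types × 16 flanking-base
combinations, written `X[R>A]Y`. Classification requires the reference 3-mer
centered on the mutated base; a center/REF mismatch is a classification
error and the event is excluded into a report rather than silently dropped.

**ID-83.** The shared VCF anchor base is stripped first; classification
operates on the inserted/deleted sequence itself. One-base-pair events are
split by base (A/G collapsed to the pyrimidine label T/C) and by the
homopolymer run length at the site (run including the deleted base for
deletions, adjacent copies for insertions). Longer events are binned by
length {2, 3, 4, 5+} and by the number of additional complete copies of the
event sequence adjacent in the reference (both directions). A deletion of
≥ 2 bp with no adjacent full copy but a shared prefix with the 3′ flank or a
shared suffix with the 5′ flank is microhomology-mediated; the MH length is
the longer of the two partial matches, binned {1, 2, 3, 4, 5+}. A
full-length flank copy is a repeat-mediated deletion, never an MH one — the
two branches are mutually exclusive by construction.

**CN-48.** Allele-specific segments are keyed by zygosity (homozygous
deletion when TCN = 0; LOH when the minor allele is 0; heterozygous
otherwise), by total copy number bin ({1, 2, 3–4, 5–8, 9+} for LOH,
{2, 3–4, 5–8, 9+} for heterozygous), and by size bin ({0–100 kb,
100 kb–1 Mb, 1–10 Mb, 10–40 Mb, > 40 Mb}; homozygous deletions use
{0–100 kb, 100 kb–1 Mb, > 1 Mb}): 3 + 25 + 20 = 48 channels. Segment size
is `end − start + 1` on 1-based inclusive coordinates. Size-bin edges are
half-open on the lower side and inclusive on the upper (e.g. "10–40 Mb"
means size > 10 Mb and ≤ 40 Mb); the convention is arbitrary but used
identically in classification and feature aggregation.

### Enrichment screen

For each channel the screen computes (i) the effect axis: log2 of the ratio
of group means of per-sample channel proportions, with a pseudocount of 1e−6
on both means so the ratio is always finite, and (ii) the significance axis:
a two-sided Fisher exact test on the pooled 2×2 table
[channel count vs all-other-channel count] × [HRD vs HRP], adjusted by
Benjamini–Hochberg within each variant class (96, 83 and 48 channels
separately). A Fisher test needs integer counts, so pooling across samples
is the closest well-defined construction to a test of mean proportions; the
group-mean proportions drive only the fold-change axis. A channel is called
enriched when |log2 FC| exceeds the threshold (0.75 whole-genome, 0.25
exome) **and** −log10 q > 3, with the direction given by the sign.

### Features

Six features per sample: `N[C>G]T` and `N[C>T]G` (each the sum of its four
SBS channels over total substitutions), `DEL.5.MH` (sum of `5:Del:M:1..5`;
a proportion of all indels for WGS, an absolute count for WES — the count
convention is the explicitly stated exome convention, and a flag overrides
the assay default), `LOH:1-40Mb`, `3-9:HET:10-40Mb` and `2-4:HET:>40Mb`
(proportions of all segments). Copy-number feature filters apply to the raw
total copy number, not the binned channel, so a TCN of exactly 9 counts
toward the 3–9 heterozygous feature even though the schema bins it as 9+.
The LOH feature aggregates all TCN ≥ 1 states with minor allele 0 by
default; `loh_max_tcn` caps the range for sensitivity analysis. Segments on
every provided chromosome participate — no sex-chromosome filtering is
applied; callers who want it filter upstream. Any zero denominator yields a
feature value of 0 with a per-sample warning.

### Ground truth, training, prediction

A training sample is HRD iff its genomic-instability scar score (sum of
LOH/TAI/LST counts, consumed as a numeric input) reaches the tissue
threshold — 42 for breast, 63 for ovarian, both inclusive — or BRCA1/2 is
altered. A missing score without a BRCA alteration is an error, never a
default HRP.

Features are standardized with the training-set mean and SD (zero-variance
features fall back to SD 1 with a warning). Model selection runs stratified
10-fold cross-validation over a regularization grid {0.01, 0.1, 1, 10, 100},
choosing the strength with the best mean out-of-fold AUC (ties go to the
stronger regularization). Per-fold weight vectors at the chosen strength are
retained; their mean is the reported feature-weight vector. The final
decision function is refit on all training data. Probabilities come from a
Platt-style logistic fit on the out-of-fold decision values (implemented as
a near-unregularized logistic regression), which keeps probabilities
monotone in the decision value; a probability ≥ 0.50 (inclusive) is an HRD
call. The grid, the AUC selection criterion, the calibration method and the
stratified-fold seed are this package's choices and are all exposed in the
API and CLI; the method itself fixes only the linear kernel, the L2
penalty, 10 folds and the 0.50 threshold. Standardization is fitted once on
the whole training set before cross-validation (the procedure the method
describes); the out-of-fold AUCs are model-selection scores, not unbiased
generalization estimates — held-out cohorts are used for those.

### Whole-exome down-sampling (dWES)

Mutations are kept when any base of the REF span overlaps an exome target
interval. Segments are kept when they overlap at least one interval and
retain their original span and copy numbers: the WES copy-number features
still use the 10–40 Mb and > 40 Mb size bins, which clipped exonic fragments
could never reach, so overlap-retention is the only reading consistent with
the feature definitions. A `--clip` flag provides the alternative
(intersection with the target footprint) for sensitivity analysis.
Down-sampling is idempotent and monotone in the interval set.

## Synthetic data: what it emulates and what it does not

The generator produces seeded toy genomes and HRD/HRP cohorts carrying the
contrasts the classifier relies on — HRD: C>G at NpCpT, ≥ 5 bp deletions at
microhomologies, LOH of 1–40 Mb, heterozygous TCN 3–9 at 10–40 Mb; HRP: CpG
C>T transitions and heterozygous TCN 2–4 above 40 Mb.

**Genome layout.** Copy-number realism needs chromosomes longer than 40 Mb,
but reference sequence is only needed where point mutations land. Each toy
chromosome therefore declares a nominal length (default 4 × 60 Mb) while
uniform-random sequence is synthesized only for a window at its head
(default 500 kb) where all mutations are placed; segments span the full
nominal length, which carries no sequence. Exome targets (150 bp exons at a
jittered ~5 kb pitch, 3% of the genome) are dispersed over the full nominal
span so both mutations and segments down-sample realistically.

**Event placement.** Substitutions are placed only at positions whose
plus- or minus-strand 3-mer matches the sampled channel context, drawn from
a precomputed site index. Microhomology deletions are placed at loci
pre-screened (vectorized over the whole window) so that the 3′-flank prefix
match is exactly the target MH length, the 5′ match does not exceed it, and
no full flank copy exists — every simulated event therefore lands in its
intended channel by construction, and the generator returns its intended
tallies so tests close the loop against the classifier. An empty candidate
list raises with the suggestion to enlarge the toy genome. Background indels
(1 bp deletions and insertions at whatever homopolymer context a random
locus offers) share one composition across classes, so their channel
proportions differ between classes only by the planted-mass complement.

**Study conditions.** Defaults: 50 + 50 samples; Poisson burdens of 3,000
substitutions, 500 indels and 60 segments per sample (the order of magnitude
of whole-genome breast cancers); planted contrasts of 2.5–9× on the channel
groups above. Mixture masses are chosen so the background channels' expected
|log2 FC| stays several standard errors below the 0.75 whole-genome volcano
threshold — the complement of a planted mass necessarily depletes background
proportions, and with carelessly large planted masses that depletion itself
crosses the gate. With 3% exome targets, down-sampled samples carry ~90
substitutions and ~15 indels, the scale of real exomes.

**Limitations.** Per-sample RNG substreams derive from the master seed, so
cohorts are reproducible and order-independent. The generator does not model
clonal structure, sequence composition bias (the toy genome is uniform
ACGT, so CpG contexts are not depleted as in real genomes), coverage or
calling noise, correlated segment structure along chromosomes, or
overlapping events. Passing tests therefore demonstrate that the pipeline
recovers what it assumes — correct classification, feature extraction,
enrichment logic and model behavior — not that the trained toy models
transfer to real cohorts. At the default 50-per-arm scale the indel channels
cannot reach −log10 q > 3 from exome-resolution counts (real exome screens
used an order of magnitude more samples), so the exome-threshold screen is
validated on substitution and copy-number channels and on the absence of
spurious indel flags.

## Numerical choices and degenerate inputs

* Pseudocount 1e−6 in fold changes; q-values floored at 1e−300 before log.
* Zero-variance features scale by 1; zero denominators give 0 with warnings.
* Equal-probability ties in AUC count one half (rank statistic).
* Mutations with non-ACGT alleles, multi-base equal-length substitutions,
  and context mismatches are excluded into parse/exclusion reports — row
  counts always reconcile.
* Segments with major < minor are swapped on read (warning); non-integer or
  negative copy numbers are rejected into the parse report (allele-specific
  callers emitting subclonal fractional copy numbers must be rounded
  upstream — the channel schema is defined on integer states).
* Chromosome names are compared without the `chr` prefix.
* Model files are versioned JSON documents carrying scaler, weights,
  per-fold weights, calibration, the grid searched and the seed.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
classification oracles at 1,000 events per class, the enrichment screen at
50 samples per arm (≈ 3,500 events per sample), model training at 100–120
samples per cohort, concordance on a 40-sample held-out cohort, and a
20-permutation label null. These sizes give stable statistics for every
asserted property while keeping a full run in the low minutes on one CPU.
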