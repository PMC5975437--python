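# Methods notes

## Scope and data model

`riboassoc` consumes transcriptome alignments (SAM/BAM against transcript
references), a GENCODE-dialect GTF + genome FASTA, and optional contaminant
ID lists; read trimming, alignment, and fold-change estimation are upstream
concerns. All coordinates are 0-based half-open transcript coordinates; GTF
input/output is converted at the module boundary. CDS spans merge `CDS` and
`stop_codon` features, so a span always ends with the stop codon and must be
a positive multiple of 3.

## Per-dataset classification

**Expression.** RPKM is computed by a simple weighted scheme: multimapped
reads are split uniformly across their placements, counts summed, RPKM
derived in one pass (an optional second pass re-derives weights from
first-pass RPKM; off by default). This deliberately replaces an EM
quantifier: at the depths and transcript counts involved, rank agreement
with the truth is what matters for the ≥ 1 RPKM expression gate and the
Eq.-style multimap weights, and the simulator tests verify Spearman ≥ 0.95.
Ribo-seq multimap weights use the RNA-seq RPKM of the target transcripts;
all-zero-RPKM placements fall back to uniform weights (the weight formula is
0/0 there). Reads with more than `max_hits` (default 100) placements are
dropped; antisense placements are never counted (strand-specific protocol).
Any read with at least one placement on a contaminant transcript (rRNA,
tRNA, sno/miRNA lists) is removed entirely.

**Region counting.** A read is assigned to a region iff its 5′ end lies in
the region. The 5′ end matches the frame-analysis convention and gives each
read exactly one region per transcript (no double counting at boundaries).

**Density cutoff.** The 90th percentile (linear interpolation, "type 7" —
the convention matters and is fixed package-wide) of ribosome densities of
expressed-mRNA 3′UTRs (minimum length 30 nt, configurable). Classification
is inclusive: density ≥ cutoff → associated. The cutoff sample and the
classified set are both restricted to expressed transcripts; a pseudo-density
for log plots is never used in classification. mRNAs are judged on CDS
density, lncRNAs on the whole transcript.

**Putative ORFs.** ATG→{TGA,TAA,TAG}, length ≥ 30 nt including the stop,
one ORF per (frame, stop): anchored at the most 5′ in-frame ATG with no
intervening stop. Codons containing N never match start/stop (conservative).
All ORFs of a lncRNA are scored; the transcript's level is the maximum
filter count over its ORFs (0 when no ORF exists).

**Coding filters.** FLOSS compares the transcript's footprint-length
histogram (restricted to 25–35 nt and renormalized) to the pooled
expressed-associated-mRNA CDS reference, reported as 1 − total variation so
that 1 is CDS-like. RRS is (ORF density / downstream density) ratio of
Ribo-seq over the same ratio for RNA-seq, with a +1-read pseudocount per
region, scaled to [0,1] by x/(1+x) (monotone; the fixed point 0.5
corresponds to no release signal). The downstream region of a lncRNA ORF is
stop-to-transcript-end; for CDSs it is the annotated 3′UTR. Framescore is
the KL divergence (natural log — the base cannot change percentile-based
pass/fail) between the ORF's add-one-smoothed frame distribution of 5′ ends
and the pooled CDS reference; it is oriented for the shared
"10th-percentile, pass if ≥ cutoff" rule via the strictly decreasing
bijection `frame_sim = exp(−KL)`. Cutoffs are the 10th percentiles of the
scores of translating CDSs (expressed, ribosome-associated mRNAs), so ~90%
of calibration CDSs pass each filter by construction; comparison at the
cutoff is inclusive.

## Cross-dataset integration

Dataset selection requires both mapping rates strictly above 0.30 and the
lncRNA-vs-CDS footprint-length distance `dist = ½·L1` strictly below 0.15;
within a tissue the smallest dist wins, ties broken lexicographically by
dataset id. `M` is the number of *selected* datasets and must be ≥ 2 (the
spec denominator is M − 1). A lncRNA expressed in no selected dataset is
reported with empty scores and excluded from classification; a
`min_datasets` filter (default 1) controls which lncRNAs enter the
percentile computation. The 5th/95th composite thresholds and the top-5% TS
threshold are strict: values exactly at a threshold fall to the non-extreme
class. Consequently, on small or heavily tied score distributions the
extreme classes can be legitimately empty (all-equal scores classify
nothing). TS is summed only over datasets where the lncRNA is associated.

**Enrichment statistics.** `enrichment_test` reports the one-sided Fisher
exact p-value plus an enrichment ratio defined as the relative risk
(a/(a+b)) / (c/(c+d)) — support rate inside the class over the rate outside
— which is the convention the published per-class "odds ratios" follow; the
conditional-MLE odds ratio of the noncentral hypergeometric model is exposed
as a lazily computed attribute for users who want the classical estimator.
Degenerate margins yield p = 1 and an undefined ratio.

## The simulator

The generator emulates what the method assumes about real data, with ground
truth for recovery testing. Defaults (the package's study conditions):

| parameter | default | rationale |
|---|---|---|
| transcripts | 150 mRNA; 100 translated / 100 associated-untranslated / 100 free lncRNA | ≥ 50 per class for stable rate estimates |
| datasets per study | 8 | matches the multi-tissue design the integration needs |
| base RPKM | log-uniform 8–150 | expressed-transcript range; per-dataset lognormal (sd 0.4) tissue variation |
| lncRNA expression breadth | Beta(1,2) per-dataset probability | lncRNAs are mostly tissue-specific; spreads spec and the composite score |
| depths | 10 (Ribo) / 5 (RNA) reads per RPKM·kb; per-dataset multiplier log-uniform 0.5–2 | deep, selected-quality datasets |
| footprint length | N(29, 1.5) clipped to 25–35 nt | ribosome-protected fragment sizes |
| periodicity | per-dataset U(0.80, 0.95) fraction of in-ORF 5′ ends in frame 0 | protocol-dependent phasing quality |
| stop_dropoff | 0.10 | 3′UTR/background coverage relative to a translating ORF; free lncRNAs draw from the same law as mRNA 3′UTRs so the 90th-percentile cutoff sits at its intended operating point |
| contaminants / multimap / antisense | 5% / 5% / 2% | nuisance processes the ingestion stage must remove |

Translated lncRNAs are generated mRNA-like — 30–150 nt leader, 252–801 nt
ORF, 120–400 nt trailer — reflecting documented translated lncRNAs, which
are structurally mRNA-like. Two consequences of the calibration scheme
motivated this: CDS-derived cutoffs implicitly assume ORF coverage
comparable to CDSs (short, shallow ORFs fail all three filters for purely
statistical reasons, at any sequencing depth), and an ORF ending within
~50 nt of the transcript end makes the RRS downstream region degenerate
(pseudocounts and read-length edge effects dominate). Untranslated and free
lncRNAs are 300–700 nt with an embedded 30–90 nt ORF, so every lncRNA has
at least one putative ORF; the three bases before an embedded ATG are forced
to TAA so the enumerated ORF coincides with the truth label.

All ribosome-protected footprints share one length law regardless of what
the ribosome is doing, consistent with the dataset-selection rule (usable
datasets have length-matched lncRNA and CDS footprints). FLOSS is therefore
non-discriminative in end-to-end simulations — associated-untranslated
lncRNAs typically land at A1 by passing FLOSS alone — and FLOSS's
discriminating behaviour is exercised in unit tests with explicitly
different histograms. Reads are emitted as already-aligned SAM records with
no sequencing-error model; positions near the transcript 3′ end are clipped
so reads fit, which slightly distorts frames there.

What passing the recovery tests shows: the pipeline separates the three
populations the generator defines, at the generator's coverage and noise
levels. What it does not show: robustness to P-site offsets, biased
nuclease digestion, incomplete annotations, EM-level quantification
ambiguity, or real contaminant sequence similarity — none of which the
generator models.

## Numerical choices and degenerate inputs

* Percentiles: numpy's default linear interpolation everywhere (type 7).
* Histogram/frame normalization tolerance 1e-6; frequencies validated on
  construction.
* Add-one smoothing: one pseudo-read per frame guarantees strictly positive
  reference frame distributions (KL is undefined otherwise and raises).
* Transcripts with zero in-window footprints are unassessable for coding
  filters and keep level 0 rather than erroring mid-pipeline.
* Empty density vectors, < 10 calibration CDSs, < 20 scored lncRNAs, M < 2
  selected datasets, non-positive mapped-read totals, inverted regions, and
  unknown alignment references are hard errors (`DataError`,
  CLI exit code 3; configuration problems exit 2).

## Known limitations

* The one-pass RPKM under-resolves paralog families compared to EM
  quantifiers; weights can optionally be iterated once.
* FLOSS is computed per transcript (not per ORF) and attached to every ORF
  of the transcript.
* Mapping rates are taken from the dataset profile table (aligner logs),
  not recomputed from raw reads.
* Fold-change tables for NMD/localization comparisons are consumed, not
  produced; `compare_groups` provides the Welch/pooled t machinery.
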