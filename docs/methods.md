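# Methods

## Coordinate conventions and regions

All positions are 0-based, half-open, in transcript space; genomic→transcript
conversion happens once, at annotation load. A transcript is
5'-UTR | CDS (stop included) | 3'-UTR. For analysis the canonical stop codon
is bookkept on the 3'-UTR side: the *adjusted CDS* excludes the stop, and the
*adjusted 3'-UTR* is the stop codon plus the annotated 3'-UTR. The
*extension* runs from the first nucleotide after the canonical stop through
the first downstream in-frame stop codon (inclusive of its 3 nt; a switch
excludes them); the rest of the 3'-UTR is *distal*. Genes whose 3'-UTR
contains no in-frame stop keep the whole post-stop 3'-UTR as extension and
are flagged. For per-position region labels, the canonical stop's three
positions are reported with the extension flank; `stop_in_cds=True` restores
the conventional CDS-includes-stop labelling.

Transcripts failing the model invariants (CDS not a multiple of 3, shorter
than two codons, or not ending in UAA/UAG/UGA) are rejected at load with a
per-record report, never silently dropped. Transcripts without annotated
UTRs receive default lengths of 97 nt (5') and 173 nt (3') — 75th-percentile
values for yeast — taken from flanking genomic sequence, and are flagged
`utr3_annotated=False`. The reference gene set keeps genes with experimental
3'-UTR annotation and without a same-strand overlap of *more than* 18 nt
(exactly 18 is retained; the boundary is read strictly).

## P-sites, frames, counting

P-site positions are 5'-end + a per-read-length offset from a per-sample
table; offsets are consumed, never estimated here. Read lengths are
restricted to 20–23 and 27–32 nt. Frame = (psite − utr5_len) mod 3 with
floored modulo, so frame 0 anywhere on the transcript means in-frame with
the CDS — the frame a readthrough ribosome occupies in the 3'-UTR. Reads
whose P-site falls off the transcript (possible with imputed UTRs) are
dropped and tallied in a QC counter. Metagene profiles pool raw P-site
counts across the gene set and divide by the window total (no per-gene
normalisation before pooling).

Per-gene counts are kept by region × frame. The trimmed CDS count
additionally excludes P-sites in the first 15 and last 33 nt of the
annotated CDS, where start/stop queueing inflates density; the exclusion is
defined on the annotated CDS (stop included), switchable. Genes whose CDS is
shorter than the two zones plus one codon are flagged and yield no trimmed
count.

## Readthrough efficiency

log2 RE = log2[(n_f0_utr3 / L_utr3_adj) / (n_f0_cds_trim / L_cds_trim)].
The numerator uses all frame-0 P-sites in the adjusted 3'-UTR; no exclusion
is applied around the downstream stop because many extensions are shorter
than the exclusion zone — a frame-0 stall there therefore inflates the
estimate slightly, and the generator reproduces this mechanism on purpose so
the bias is measurable (see below). The denominator length includes the
stop codon's 3 nt by default (consistent with the adjusted transcriptome),
switchable. Log base 2 throughout. No pseudocounts: zero trimmed-CDS counts
give NaN (undefined), zero numerator counts give a −∞ sentinel; both drop
from ranked analyses.

Expression filter: a gene is discarded when CDS RPKM < 5 **and** 3'-UTR
RPKM < 0.5 (conjunctive reading; the disjunctive variant is a switch).
High/Low groups are the top/bottom floor(0.15·n) of filtered, finite
estimates, ties broken by gene id for reproducibility; all-tied inputs are
rejected rather than arbitrarily split. Premature-stop (PTC) readthrough is
the ratio of frame-0 counts strictly downstream (through the CDS end) to
strictly upstream of the PTC, which cancels mRNA-level differences.

## Feature set

73 per-gene variables: stop codon; nt −15..−1 and +4..+9 (numbering: stop =
nt +1..+3, +4 = first 3'-UTR nt); first in-frame 3'-UTR stop identity;
P-site and E-site amino acids; for four exit-tunnel regions (aa 3–9, 10–12,
13–19, 20–30 counted back from the stop; aa 1 = P-site residue) the fractions
of charge (+/0/−), polarity, aromaticity and a 4-class Kyte–Doolittle
hydrophobicity binning; 3'-UTR length; externally supplied structure MFE,
structure distance and helix fraction (never computed here); gene-level tAI
as the geometric mean of per-codon values when a codon→tAI table is given;
and two seeded negative controls (uniform integer 1–100, uniform 4-level
factor) used to calibrate importance baselines. Residue class tables are
packaged defaults (charge + = K/R/H, − = D/E) and fully overridable. Genes
too short for a window get NA and a flag; NA core-sequence genes are dropped
from model training, NA external features are median-imputed (or dropped,
per config). The exact historical 81-variable enumeration cannot be
reconstructed from published descriptions; this package's schema file is the
authoritative enumeration for its own models.

## Random-forest models

scikit-learn forests, 100 trees, mtry (max_features) tuned over
{1, 11, …, 81} clipped to the encoded width; categoricals are one-hot
encoded with a group map so importance aggregates back to original features.
5-fold CV — stratified for High/Low classification — selects mtry by best
mean metric: NRMSE (RMSE / per-fold response range) for regression, AUROC
(rank-sum formulation, ties ½) for classification. Importance is explicit
out-of-fit permutation of each feature's column block, 5 repeats by default:
%IncMSE = 100·(MSE_perm − MSE_base)/MSE_base for regression; MDA is the
percentage-point drop in accuracy, 100·(acc_base − acc_perm), which stays
defined when a fold classifies perfectly. Out-of-bag permutation (as in the
classic R implementation) would give different magnitudes; rankings, not
magnitudes, are the supported contract, and the signal-recovery tests assert
rankings across folds. Everything is seeded and bit-reproducible.

## Context statistics

* **Median shifts**: per level of a categorical feature, level median log2 RE
  minus the overall sample median, tested by two-sample Wilcoxon rank-sum of
  the level against all remaining genes (the caption-style one-sample
  signed-rank against the sample median is a variant switch). Note the
  reported delta is attenuated relative to an injected effect because the
  shifted genes move the overall median too.
* **High/Low enrichment**: χ² goodness-of-fit of a group's level counts
  against expectations from reference-set frequencies, Bonferroni-multiplied
  by the number of feature positions in the heatmap (configurable family);
  per-level log2(group fraction / reference fraction); absent levels are
  flagged zero-observation and get no log2 value.
* **Association**: χ² independence test with per-cell Pearson residuals
  (O−E)/√E; attraction positive, repulsion negative; any expected cell < 5
  sets a small-sample flag.
* **Correlations**: tie-corrected Spearman with two-sided p; pairwise-
  complete correlation matrix; translation efficiency = ribosome density /
  expression.

## Synthetic data

The generator emits transcriptomes (FASTA + GFF3, one contig per gene),
footprint libraries (TSV and SAM with soft-clipped 3' overhangs), offset,
truth, and RNA-seq tables, all under one seed. Sequences have an AUG start,
stop-free CDS interior, stop codon drawn from yeast-like usage
(UAA .47 / UAG .23 / UGA .30), nt+4 drawn uniformly unless a stop↔nt+4 odds
coupling is configured, and a guaranteed in-frame downstream stop at a
sampled distance of 1–12 codons. True log2 RE is baseline (−4) + additive
feature effects + Normal(0, σ) gene noise, σ = 1 by default.

Read placement is Poisson per frame-0 codon-grid position: density λ
(default 0.5 reads/nt; deep-coverage analyses below use higher λ) in the
CDS, λ·2^RE in the adjusted 3'-UTR, placed uniformly; off-frame reads are
controlled by `offframe_cds_noise` (CDS) and `frame_fidelity` (3'-UTR,
default 0.9). `stall_multiplier` adds frame-0 pile-ups at the penultimate
codon (inside the CDS exclusion zone, so it must not move RE) and at the
first downstream in-frame stop (inside the numerator, so it must raise RE
by ≈ log2((k+19)/k) for k numerator codons at multiplier 20 — the tests
assert this known overestimation matches theory). The generator does not
model sequencing error, ligation bias, amplification duplicates, positional
(non-uniform) coverage beyond the stall terms, or UTR mis-annotation;
passing recovery tests therefore demonstrate estimator correctness under
Poisson sampling, not robustness to those real-data artefacts.

## Problem sizes and numerical choices

The recovery analyses use: 1,000 genes at λ = 8 with evaluation restricted
to genes with ≥ 50 frame-0 3'-UTR reads (Spearman ρ ≥ 0.9, median |error|
≤ 0.3 log2 units); 800 genes with injected effects UGA +1.5, UAA −1.0,
nt+4=C +0.8 log2 units at gene noise 0.5 for the forest analyses; 2,000 and
4,000 genes for the context statistics; 300,000 uniform P-sites for the
frame calibration. Null calibration of the classifier uses 20
label-permuted seeds at a fixed mid-grid mtry, which keeps the check
O(minutes) without changing the null's meaning. Ties in ranking are broken
by gene id; quantile boundaries use floor(fraction·n); χ² independence is
computed without continuity correction so the residuals match their
closed-form definition.

## Known limitations

3'-UTR structure (MFE), structure distance and helix fractions are inputs
from external predictors, never computed. Offset estimation, deduplication
and alignment are upstream of this package. The numerator's downstream-stop
pile-up bias is documented and simulated but not corrected, matching the
published analysis convention the pipeline follows.
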