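# ribore

Genome-wide quantification of **stop-codon readthrough** from ribosome
profiling, with the statistics needed to ask *which* mRNA and nascent-peptide
features drive it.

When a ribosome reaches a stop codon it normally terminates; occasionally a
near-cognate tRNA decodes the stop instead and elongation continues into the
3'-UTR, producing a C-terminally extended protein. Ribosome profiling makes
this visible as in-frame footprints downstream of the stop codon. `ribore`
turns transcriptome-aligned footprints into per-gene readthrough-efficiency
estimates and runs the downstream feature analyses — random-forest feature
importance and nucleotide-context enrichment — against those estimates. A
fully seeded synthetic-data generator with known per-gene ground truth makes
every stage testable without sequencing data.

Intended users: computational biologists analysing yeast (or other
eukaryotic) ribo-seq libraries, and anyone who needs a readthrough
quantifier with a verifiable error model.

## The statistic

For each gene, footprint P-sites are assigned from the read 5' end via a
per-length offset table, and the reading frame is taken relative to the CDS
start. Readthrough efficiency (RE) is the log2 ratio of frame-0 footprint
density in the adjusted 3'-UTR to frame-0 density in the edge-trimmed CDS:

```
log2 RE = log2 [ (n_f0_utr3 / L_utr3) / (n_f0_cds / L_cds) ]
```

where

* the adjusted 3'-UTR spans the canonical stop codon plus the annotated
  3'-UTR (the stop codon is bookkept on the 3'-UTR side);
* the CDS counts exclude P-sites in the first 15 and last 33 nt of the CDS,
  discounting ribosome queueing at start and stop codons;
* only frame-0 P-sites are counted on either side — readthrough is by
  definition in-frame with the CDS;
* read lengths are restricted to 20–23 and 27–32 nt.

Genes with CDS RPKM < 5 *and* 3'-UTR RPKM < 0.5 are discarded; the top and
bottom 15% of the remaining genes form the High/Low readthrough groups used
by the classification model and the enrichment statistics. The "extension"
(stop codon to the first downstream in-frame stop) and distal 3'-UTR are
tracked separately.

## Worked example

Simulate a 200-gene library with known per-gene readthrough, then quantify:

```
$ ribore simulate --n-genes 200 --seed 42 --density 4 --out demo
$ ribore quantify --reads demo/footprints.tsv --offsets demo/offsets.tsv \
      --gff3 demo/annotation.gff3 --fasta demo/genome.fa --out demo/re.tsv
200 genes quantified; 200 pass expression filters

$ head -4 demo/re.tsv | cut -f1,6,9,10
gene     log2_re   passes_filter  group
g00000   -4.25162  1              Mid
g00001   -4.47622  1              Mid
g00002   -3.84344  1              Mid
```

Each `log2_re` is the estimated per-gene readthrough efficiency: g00000
places about 2^-4.25 ≈ 5% as many in-frame footprints per nucleotide in its
3'-UTR as in its CDS. Comparing against the simulation's programmed truth
(`demo/truth.tsv`) gives Spearman ρ = 0.975 and a median absolute error of
0.14 log2 units at this depth — the estimator tracks the programmed values
closely.

Building the feature matrix for the forest models:

```
$ ribore features --gff3 demo/annotation.gff3 --fasta demo/genome.fa \
      --seed 42 --out demo/feat.tsv --out-schema demo/schema.tsv
200 genes x 73 features
```

The matrix covers the stop codon and its nucleotide neighbourhood (nt −15..−1
and +4..+9), the P-/E-site amino acids, exit-tunnel physicochemical
fractions, 3'-UTR descriptors and two randomized negative controls.
`ribore model` then fits seeded 100-tree random forests (regression on
log2 RE, classification of High vs Low) with 5-fold cross-validation and
reports NRMSE/AUROC plus permutation feature importance; `ribore stats`
runs the Wilcoxon median-shift, χ² enrichment, independence-residual and
Spearman correlation analyses.

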