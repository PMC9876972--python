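# synchrodiff

Multi-omic analysis of a synchronised stem-cell differentiation time course:
differential chromatin accessibility as functional data, bias-corrected
digital genomic footprinting, scalar-on-function regression of accessibility
change on transcription-factor footprints, G-test differential histone
regions, enhancer/super-enhancer grammar, and model-based temporal expression
clustering. A first-class synthetic-data generator with a ground-truth
manifest makes every stage testable end to end without any sequencing data.

The package is aimed at computational biologists analysing time-resolved
ATAC-seq / histone ChIP-seq / RNA-seq designs — cells sampled at fixed
intervals (here 0–72 h in 12-h steps, duplicate ATAC/ChIP libraries,
triplicate RNA) — who want the bespoke statistics of such studies as tested,
reusable functions.

## Core statistics

**Peak score.** A called peak with mean background-normalised signal μ_ns and
BH-corrected enrichment p-value *P* is scored

```
S_p = μ_ns × (−log10 P)
```

**Functional differential accessibility.** Each candidate region's
normalised Tn5-insertion signal is extracted in 31 bins per replicate,
smoothed on 10 equidistant cubic B-splines, and reduced by functional PCA to
the smallest score dimension retaining 95% of the variance. Per region, a
two-sample Hotelling T² compares the two conditions' score vectors using a
covariance pooled across all regions (two replicates per condition make a
per-region covariance singular); T² maps to an F statistic, p-values are
Bonferroni-corrected, and regions with adjusted p ≤ 1e-4 and fold change
FC ≥ 2 (or ≤ 1/2) are called opening (closing). Significant regions are
ranked by

```
S_d = −log(adj.P) × FC × √Baseline ,  Baseline = ½(avg signal t₁ + avg signal t₂)
```

**Digital genomic footprinting.** Reads become Tn5 insertion sites (+4 bp on
the forward strand, −5 bp from the reverse-strand 5′ end). A 6-mer insertion
bias model is fitted from a deproteinised control: weight(k) = control
frequency of the 6-mer spanning [site−3, site+3) divided by the genome
background frequency. Motif-window insertion counts (motif ± 25 bp) follow a
two-component multinomial mixture — unbound ∝ bias, bound ∝ bias × a shared
protection shape estimated by EM — and each match gets a footprint
likelihood ratio FLR = ln P(counts | bound) − ln P(counts | unbound).
Curated footprints have FLR ≥ 10 in every replicate, ≥ 50 footprints for the
PWM, protection score PS ≥ 0 (flank minus motif mean normalised insertion
rate), a single-TF PWM, TF expression ≥ 1 FPKM, highest-FLR deduplication of
overlapping same-TF calls, and optional overlap with an external footprint
set.

**Scalar-on-function regression.** For each TF, the log2 |FC| of selected
differential regions (1.5 < |FC| < 10, windows of 1000 bp around the peak
centre) is regressed on the footprint indicator function represented on five
order-4 B-splines:

```
y_i = α₀ + ∫ x_i(t) β(t) dt + ε_i
```

fitted by OLS through the basis Gram matrix; TFs are ranked by R² with
F-ratio p-values.

**Differential histone regions.** Sliding-window (1 kb / 100 bp) G-tests on
pooled replicate counts, expected counts proportional to library sizes:
G = 2[a ln(a/ê_a) + b ln(b/ê_b)], BH-corrected, |FC| ≥ 2 and adjusted
p ≤ 0.01, windows restricted to called peaks and merged by direction.

**Enhancer grammar.** H3K4me1 intervals anchor enhancer identity: no H3K27ac
overlap → poised; H3K27ac intersection ≤ 3 kb → active; > 3 kb →
super-enhancer; active/super split proximal/distal by H3K4me3 overlap.

**Expression clustering.** log2(FPKM+1), row-scaled profiles are fitted by
Gaussian mixtures over a range of K; the K minimising BIC is selected and
cluster curves are smoothed on 5 cubic B-splines (λ = 0) with ±2 SD bands.

## Worked example

Run the full pipeline on a freshly simulated desk-scale study (2 × 200 kb
genome, 60 open regions, 300 genes, ~1 M insertions per ATAC replicate):

```bash
synchrodiff run --seed 1 --out demo
```

which logs

```
simulated 60 regions, 300 genes
diffacc 0h vs 36h: 11/60 significant
footprints: 150 matches, 72 curated
enhancers: 140 records, 5 classes
expression clustering: K=7 over 258 DE genes
```

and writes per-stage TSVs under `demo/`. The differential-accessibility
table ranks regions by `S_d`; the top planted 4-fold shifts look like

```
chrom   start    end      fc        t2     p_adj  baseline     s_d      status
chr1    93400    94400    3.1771  22685.98  0.0   35.21    5907.66    opening
chr1   157200   158200    0.2061   2848.21  0.0    9.89     123.81    closing
```

— `fc` is the (library-normalised) later/earlier signal ratio, `t2` the
Hotelling statistic, and `status` the call at adjusted p ≤ 1e-4 and
|FC| ≥ 2. Of 150 motif matches, 72 survive the full curation chain. The
single simulated TF's scalar-on-function fit over the 11 differential
regions gives R² = 0.49 (F-ratio 0.96, p = 0.52): with one TF and few
regions the functional model does not significantly out-predict the
intercept, which is the expected behaviour for an isolated factor. The
expression stage selects K = 7: the three scripted smooth cluster shapes
plus the step-like profiles of accessibility-coupled genes.

`demo/run_manifest.json` holds SHA-256 digests of every artifact; repeating
the command with the same seed reproduces them byte for byte.

Each stage is also a library call (`synchrodiff.accessibility.diff_accessibility_test`,
`synchrodiff.footprints.curate_footprints`, ...) and a CLI subcommand
(`diffacc`, `footprint`, `cluster-expr`) over standard formats (BED,
bedGraph, FASTA, TSV tables).

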