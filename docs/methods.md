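# Methods

This note documents the models implemented in `synchrodiff`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Coordinates and core algebra

All coordinates are 0-based half-open (BED convention); bedGraph values
apply to `[start, end)`. "Closer than 40 bp" peak merging joins gaps of at
most 39 bp (strict reading), transitively. Blacklist filtering removes
whole intervals on ≥ 1 bp overlap, never trims. The reverse-strand 5′ end is
the last aligned base (`end − 1`); the Tn5 shift is +4 on the forward
strand and −5 from that base on the reverse strand, so one stranded read
yields exactly one insertion site. Signal binning splits a region into
equal-width bins, assigning remainder bases one per bin from the left, so
results are deterministic and order-independent. MAPQ filters (≥ 10
ChIP/RNA, ≥ 5 ATAC) are ingest-time thresholds. ChIP read extension
(316 bp; 140 bp for ATAC fragments) is applied after any deduplication the
caller performs; the library provides no deduplication of its own.

The interval algebra (merge, subtraction, intersection length, Jaccard
index, overlap queries) is implemented directly as a sorted sweep. It is
the substrate of every stage, and owning it keeps the half-open semantics,
the whole-interval blacklist rule and the strict merge boundary exactly as
specified above.

## Differential accessibility

Per region and replicate, the normalised insertion signal is extracted in
31 bins, smoothed by least squares on 10 equidistant cubic B-splines, and
all smoothed curves of a comparison enter one functional PCA (SVD of the
centred curve matrix). The smallest leading-component count reaching 95%
retained variance defines the score space.

With two replicates per condition a per-region score covariance is
singular, so the within-group scatter is pooled across every region and
condition in the comparison; if the pooled matrix is ill-conditioned
(condition number > 1e8) a small ridge proportional to its mean diagonal is
added. The two-sample Hotelling T² uses this common covariance, and with ν
pooled degrees of freedom and p score dimensions,
F = T² (ν − p + 1)/(ν p) ~ F(p, ν − p + 1). Because ν grows with the region
count this is close to the χ²/p limit; the null calibration (1,000
simulated invariant regions, 2 vs 2) shows no family-wise false positive at
the Bonferroni 0.05 level. The exact covariance treatment of the original
differential tool at two replicates is not published; pooling is this
package's documented choice.

Fold change is the ratio of mean normalised signal over the region
(pseudocount 1e-9); the ranking score uses the natural logarithm by default
(the peak score's log10 is explicit in its definition; the ranking score's
base is not, and any base changes only the scale, not the order) and is
configurable. The tested universe is the union of both conditions' peak
sets after 40-bp merging. Regions significant in no pairwise comparison are
classified invariant.

A caveat surfaced by simulation: per-million library normalisation couples
the apparent fold change to the net direction of change. If essentially
every region shifts the same way the library-size ratio absorbs part of the
effect; with the realistic ~30% differential fraction used by the
generator the distortion is ~1.3× and planted 4-fold shifts are recovered
at 100% with no false flags.

## Footprinting

**Bias model.** The 6-mer covering `[site−3, site+3)` on the insertion
strand (reverse-complemented for − insertions) is counted over a
deproteinised control; the weight is that frequency divided by the genome's
own 6-mer frequency (both strands, pseudocount 1 on all counts). The genome
6-mer table is the stationary distribution of an order-5 Markov fit, which
for k = 6 is the genome frequency itself. Weights for 6-mers absent from
the control stay finite through the pseudocount.

**Mixture and FLR.** Insertion counts over the window (motif ± 25 bp,
strands pooled per position, −-strand matches reversed into motif
orientation) are multinomial. The unbound profile is proportional to the
per-position bias weight; the bound profile additionally multiplies motif
positions by a protection shape π ∈ (0, 1], shared across all matches of a
PWM. π and the mixture weight are estimated by EM (cap 200 iterations,
relative log-likelihood tolerance 1e-6; the M-step for π is an MM fixed
point for the normalised multinomial). FLR is the natural-log likelihood
ratio of the two components at the converged fit; a zero-count window has
FLR 0 by construction. The 10.0 bound threshold is applied per replicate.

An intrinsic property worth stating: the expected FLR of a truly bound
window is n·KL(bound‖unbound) for n insertions in the window. At 80%
central depletion of a 12-bp motif in a ±25 bp window this is ≈ 0.094 nats
per insertion, so windows near 50 insertions have expected FLR ≈ 4.8
(SD ≈ 2.4) and almost never clear 10, even though ranking by FLR separates
bound from unbound nearly perfectly (AUROC ≈ 0.99). FLR ≥ 10 per replicate
becomes reproducible at roughly ≥ 150 insertions per window, the depth
regime deep footprinting libraries reach inside open chromatin; the
pipeline's demonstration simulation uses that regime.

**Protection score.** PS = mean per-base normalised insertion rate over the
two 25-bp flanks minus the mean over the motif, with rates per million
library insertions. The external definition this score stands in for is not
reproduced in full anywhere accessible to this package; the flank-minus-motif
form is fixed and documented here. Positive PS marks central protection.

**Curation** applies, in order: FLR ≥ 10 in every replicate (mean FLR
reported); ≥ 50 surviving footprints per PWM; PS ≥ 0; single-TF PWMs only;
TF expression ≥ 1 FPKM at the same stage (missing expression drops the TF
with a warning); highest-mean-FLR deduplication of overlapping same-TF calls
(ties broken by coordinate); and, when given, ≥ 1 bp overlap with an
external footprint set (e.g. an independent footprinter's relaxed calls,
whose generation is out of scope). The chain is a pure filter — idempotent,
output a subset of input.

**Differential footprinting.** Per-TF overrepresentation among differential
footprints uses 2×2 chi-squared tests (no continuity correction) with BH
adjustment, significance at adjusted p ≤ 0.01. The bivariate metrics per
PWM are FA = log2 mean depth-normalised insertion rate over
[motif edge + 1, edge + 100] on both sides and FPD = (flank − motif)/flank
mean rate; ΔFA and ΔFPD are condition-2 minus condition-1, tested by
chi-squared on the aggregated raw flank/motif counts. Score thresholds for
externally supplied differential footprints (S ≥ 5 or S > 20) are presets,
neither asserted canonical.

**PWM scanning** uses log-odds against a 0-order background with exact
p-values from dynamic programming over the integer-discretised score
distribution (precision 1/1000 bit). The p < 1e-4 threshold is one of the
score distribution's discrete tails, so realised match rates sit at the
largest attainable tail mass below the threshold — conservative, never
anti-conservative. For a sharp consensus PWM that tail includes near-
neighbour words (≤ 2 mismatches for a 12-mer), which is the mathematically
correct behaviour of an exact-p scan.

## Scalar-on-function regression

Regions with effect magnitude max(FC, 1/FC) strictly between 1.5 and 10
enter the model (outliers at ≥ 10 removed), capped at 50,000 by descending
magnitude; the response is log2 of the magnitude (a signed mode exists but
mixing opening and closing regions with signed responses changes the
question being asked, so absolute is the default). The covariate is the
footprint indicator over the 1000-bp window centred on the peak, projected
by least squares on a 1-bp grid onto five order-4 B-splines with
equidistant knots; the window is rescaled to unit length so fits are
translation invariant. The integral ∫x_i(t)β(t)dt reduces to z_i = G c_i
with G the basis Gram matrix, and the model is fitted by OLS. R² and the
F-ratio against the intercept-only model use (5, n−6) degrees of freedom;
under a true β = 0 the p-values are uniform (KS-checked over 500 fits). TFs
with fewer than 15 footprints overlapping the selected regions, or with
footprints in too few distinct regions (production floor 50; desk default
10), are skipped. Footprints from either the earlier or the later time
point of a transition can be used as the reference set.

## Chromatin state

G-tests run on 1 kb windows stepped by 100 bp (the original tool's window
parameters are not printed; these are exposed defaults), counting fragment
midpoints of pooled replicates, with expected counts proportional to
library sizes and p-values from χ²(1). Windows with no reads are untested.
Significant windows (BH p ≤ 0.01, library-normalised fold change ≥ 2 or
≤ 1/2 with pseudocount 0.5) must overlap a called peak of either condition
by ≥ 1 bp; touching same-direction windows merge, summing G and keeping the
smallest adjusted p and the geometric-mean fold change. Genes with a TSS
within 10 kb are annotated.

Enhancer classification anchors on H3K4me1 intervals (the poised definition
requires K4me1+). The K27ac intersection is the total bp of overlap within
the anchor, summed over fragments; exactly 3,000 bp is active (strict > 3 kb
for super). Whether the original analysis computed the intersection per
K4me1 peak or per merged locus is not stated; per-anchor is implemented.
Dynamics report the Jaccard matrix over all (class, time) interval sets with
average-linkage clustering on 1 − JI, poised→active conversion counts
(≥ 1 bp anchor overlap between consecutive time points), and the fraction of
later super-enhancers overlapping earlier ones.

## Expression clustering

FPKM = count × 10⁹ / (library size × gene length). Rows are transformed
log2(FPKM+1) and scaled to mean 0, SD 1 (rows constant to within
floating-point noise become zeros and are kept). Gaussian mixtures with
diagonal per-cluster covariance (a configurable family; diagonal mirrors
standard model-based-clustering defaults without asserting the original
tool's choice) are fitted for each K with 10 seeded initialisations, and
the BIC-minimising K is selected — smaller BIC is better under sklearn's
sign convention. A plain k-means mode exists without BIC selection. The
cluster-count search runs over differentially expressed genes; DE calling
itself is an input (the generator supplies truth-based labels at the
1.5-fold threshold). Cluster profiles are smoothed on 5 cubic B-splines
over the 0–72 h interval with no roughness penalty; the time points are
equally spaced, which the basis evaluation assumes. Bands are pointwise
± 2 SD across member curves.

## Synthetic data generator

The generator emulates the study design: 7 time points (0–72 h), duplicate
ATAC/ChIP, triplicate RNA, on a 2 × 500 kb desk genome with ~200 open
1-kb regions. Insertion counts are Poisson per base and strand — rate =
background (5e-4/bp) + region amplitude, times the strand-specific 6-mer
bias multiplier, times (1 − protection depth) inside occupied motifs; the
deproteinised control (0.3 insertions/bp) sees bias only. Poisson rather
than negative binomial is the simplest model satisfying the mixture's
assumptions; overdispersion can be layered on by scaling rates. The default
region amplitude (1.0 insertions/bp/strand, ~120 insertions per motif
window per replicate) reflects deep footprinting-grade libraries. 30% of
regions step up or down 4-fold at one random transition. ChIP reads are
drawn over scripted mark domains (poised/active/super × proximal/distal
per anchor per time point, with super realised as a 4-kb K27ac∩K4me1
intersection and active as 2 kb) plus uniform background. Expression
profiles are cluster means plus Gaussian log-scale noise; a configurable
fraction of genes is coupled so their expression log2 FC equals their host
region's accessibility log2 FC, with TSSs placed 1 kb downstream of the
region so the 10-kb promoter window covers it.

Every planted signal is recorded in the ground-truth manifest (regions with
per-time amplitudes, motif sites with bound labels, enhancer classes and
intersection lengths, gene clusters, coupling flags, per-transition log2
FCs and DE labels); tests consult only the manifest. Region tables are
emitted sorted by coordinate so manifest rows align positionally with
interval-set iteration order.

What the generator does not emulate — and therefore what passing tests do
not establish about real data: fragment-length mixtures and nucleosome
positioning, duplicate reads, mappability and copy-number artifacts,
overdispersion beyond Poisson, motif-similarity confusion between TFs, and
cross-assay batch effects. Results on real libraries will be noisier in all
stages, most visibly in the bias model (real Tn5 preference spans far more
than one hot 6-mer) and in FLR calibration.

## Determinism and orchestration

A single global seed fans out to per-stage substreams by CRC-32 hashing of
stage names (all derived seeds < 2³¹), so adding a stage does not reshuffle
the others. The pipeline writes per-stage TSVs, a resolved copy of the
configuration, and a SHA-256 manifest; identical seeds reproduce identical
artifacts byte for byte. Configuration is YAML; validation fills defaults,
rejects unknown keys, and reports every error at once. The problem sizes
used by the test suite and the acceptance script (genomes of 0.1–2.4 Mb,
400–1,000 regions, tens of thousands to a few million insertions) are the
package's desk-scale choices; all stages scale linearly in genome length
and insertion count.
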