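# Methods

## Scope and model

`melanotx` implements the transcriptomic comparison workflow used to contrast
targeted degradation of BRAF^V600E (a PROTAC) with its kinase inhibition in
melanoma cells: bulk RNA-seq differential expression, gene-set activity
scoring by combined z-score, differentiation-state positioning along the
melanoma dedifferentiation trajectory, early-resistance readouts (MITF/AXL
ratio, intrinsic-resistance panel, ABC transporters) and comparative-Ct qPCR
concordance. A negative-binomial count simulator with planted gene-set
effects supplies data with the statistical structure the analysis assumes, so
the whole stack runs and is tested without any download.

## Count model and simulator

Counts for gene g in sample j of treatment class c are drawn

    K_gj ~ NB(mean = s_j * mu_g * 2^lfc(g,c),  dispersion = alpha(mu_g))

with baseline means log-normal, log mu ~ N(5.0, 1.5) on the natural-log
scale (median count ~150, a typical bulk RNA-seq depth per gene after
library-size division), dispersion trend alpha(mu) = a0 + a1/mu with defaults
a0 = 0.01, a1 = 1 (the standard bulk trend: high-mean genes approach a
biological CV of 10%, low-mean genes are shot-noise dominated), and
size factors log-normal(0, 0.1) so the normalization stage does real work.
The emulated design is the five-arm experiment — degrader (PROTAC),
degradation-incompetent methylated analogue, vemurafenib, BI-882370, vehicle
control — with 3 biological replicates per arm; the replicate count is a
design default, configurable because the deposited series' per-arm counts are
not printed in the text. Planted effects are per-(gene-set, class) log2 fold
changes, additive on the log2 scale when sets overlap; the truth table
records every gene/class pair (0 for unplanted). With a fixed seed the
generator is bit-identical across runs (single `numpy` Generator, fixed draw
order).

The simulator emulates mean-dispersion structure, library-size variation and
set-coherent fold changes. It does not emulate gene-gene correlation within
samples beyond the planted effects, GC/length biases, outlier counts
(e.g. single-sample spikes) or isoform-level effects — so passing recovery
tests demonstrates correctness of the estimators under the assumed model,
not robustness to every artefact of real libraries.

The qPCR generator inverts the comparative-Ct model: target baseline Ct is
30 − log2(mu+1), the treated arm's Ct is shifted by −log2FC, the reference
gene sits at Ct 20, and independent Gaussian noise of chosen sd is added to
every measurement. Expected 2^-ddCt therefore equals the planted fold change
exactly at zero noise, and the generator refuses a reference gene that
carries a planted effect.

## Preprocessing

Low-count filter: a gene is dropped when its count is below `min_count`
(default 10) in at least `sample_fraction` (default 0.8) of samples; the
boundary is inclusive (below threshold in exactly 80% of samples removes the
gene). Filtering precedes normalization.

Size factors use the median-of-ratios (relative log expression) method:
s_j = median over reference genes of count_gj / geometric-mean_g, the
reference set being genes with strictly positive counts in every sample. An
opt-in pseudo-reference fallback (geometric means over positive entries)
covers matrices with no all-positive gene. Note the estimator is defined
relative to the geometric-mean pseudo-sample, so only ratios of size factors
are identified; tests assert the convention-independent consequences.

Per-gene z-scores are computed across all samples jointly on normalized
counts, sd with the n−1 denominator; zero-variance genes get z = 0 with a
logged warning. Per-class standardization is available behind a flag.

## Differential expression

The DE stage is a self-contained NB Wald workflow ("mini-DESeq2" in spirit):

1. **Dispersion.** Gene-wise method-of-moments on normalized counts with
   within-class pooling and the Poisson sampling correction,
   alpha_raw = (v − xi·mu)/mu², xi = mean(1/s_j). A trend
   alpha(mu) = a0 + a1/mu is fitted across genes by non-negative least
   squares, and gene-wise estimates are shrunk toward it by
   precision-weighted averaging in log space with gene weight (m−2)/2 and a
   fixed trend weight of 2 (at the study's 6 samples per contrast the two
   are balanced). Genes with non-positive raw moments fall back to the
   trend.
2. **Wald test.** Per-gene NB GLM with log link, log size-factor offsets and
   a two-level class indicator (statsmodels IRLS); log2FC is the raw MLE
   coefficient / ln 2 — no shrinkage, because the DEG rule acts on the plain
   fold change. Genes all-zero in both classes get p = NA and are excluded
   from the multiple-testing m; fit failures (e.g. complete separation when
   one class is all-zero) fall back to a continuity-corrected moment
   estimate with no p-value.
3. **BH.** Step-up with cumulative-minimum monotonicity, NaN-aware.
4. **Calling.** up iff FDR < 0.05 and log2FC ≥ 1.5; down iff FDR < 0.05 and
   log2FC ≤ −1.5 (|log2FC| boundary inclusive, FDR strict).

Cook's-style outlier filtering and independent filtering are deliberately
omitted by default. For accession-level reproduction against the reference
tool chain, `engine="pydeseq2"` delegates the whole stage to pyDESeq2; in
the test suite pyDESeq2 serves only as an independent cross-check of the
native engine (log2FC correlation > 0.98, call agreement > 95% on planted
data).

## Combined z-score activity

For a set with n member genes present, a sample's activity is
Z = Σ z_i / √n. The √n denominator keeps the statistic standard normal under
independent null z-scores (empirically sd ≈ 1 over 10⁴ null samples), and
uses the genes actually found, so dropout does not inflate the variance. The
printed form of the equation in the source literature is typographically
ambiguous between Σz/√n and Σz/n; Σz/√n matches the cited combined z-score
method and the magnitude of reported scores, and a `denominator="n"` switch
provides the alternative. Group comparisons are two-sided Welch t on
replicate scores (the comparison test is never named in the source; the
identity is recorded in every result). PCA variance summaries are reported
as the PC1+PC2 fraction of the set-restricted z-score matrix, with per-PC
fractions also emitted. Over-representation analysis is a one-sided
hypergeometric upper tail with BH across sets, standing in for web
enrichment tools.

## Gene panels

Panels whose membership is printed in full in the source study ship in
`panels_printed.gmt`: the 10-gene MAPK transcriptional-output panel (Wagle),
quiescence (CDKN1B, CDKN1A, NR2F1), pro-apoptotic (6), ferroptosis (8),
intrinsic-resistance (8), ABC transporters (4) and the differentiation
marker panel (10). Externally defined sets — PI3K/AKT/mTOR (88 genes in the
original), the 157-marker proliferation list, cyclebase-style phase markers
and the Tsoi differentiation-subtype signatures — are not printed there;
`synthetic_reconstructions.gmt` ships small synthetic stand-ins with
plausible memberships so the machinery is exercised end to end. These are
placeholders: real analyses must override them with the published lists
(any GMT file passed to `load_gene_sets` can do so).

## Differentiation state and resistance

Subtype signatures are scored per sample with the combined z-score; classes
are placed in a two-axis plane (default: neural-crest-like vs
melanocytic-transitory, the latter scored on the union of the melanocytic
and transitory signatures) and labelled by quadrant relative to the
across-class medians of the class means. A class exactly at a cutoff is
flagged on-boundary rather than forced into a quadrant — with an odd number
of classes the median coincides with one class per axis, so on-boundary
labels are expected there. The MITF/AXL ratio is
log2((MITF+c)/(AXL+c)) per replicate on normalized counts with pseudocount
c = 1 (no formula is given in the source; the log scale makes high/low
symmetric and the pseudocount guards zero counts).

## qPCR quantification

dCt = Ct_target − Ct_reference per sample; ddCt = mean treated dCt − mean
control dCt; fold = 2^-ddCt; log2FC = −ddCt exactly. Replicates aggregate at
the dCt level (the standard comparative-Ct derivation) and the SE is
√(var_t/n_t + var_c/n_c) of group dCt values. No amplification-efficiency
correction. Concordance with RNA-seq is Pearson r on matched log2FC vectors
(≥ 3 shared genes).

## Problem sizes and numerical choices

Recovery and calibration checks run at the study scale (2000 genes, 5
classes × 3 replicates); seed-averaged checks use 3–20 seeds chosen per
statistic's variance. Dispersions are floored at 1e−8; GLM IRLS runs at most
100 iterations with tolerance 1e−8; identical replicate vectors in a Welch
comparison return p = 1 by convention (the statistic is 0/0). BH ties
resolve by the cumulative minimum from the largest p. Summary JSON floats
are rounded to 10 decimals so repeated runs are byte-identical.

## Limitations

- The native DE engine is intentionally minimal; exact replication of the
  reference tool's accession-level numbers is delegated to the pydeseq2
  engine and requires fetching the deposited count matrix.
- Reconstructed gene-set stand-ins make subtype/phase outputs on synthetic
  data structurally faithful but biologically non-interpretable until
  replaced with published lists.
- The simulator's independence assumptions understate between-gene
  correlation; observed-FDR checks are therefore easier than on real data.
- Correlation-based marker reports treat the printed correlation thresholds
  of the source literature as coefficients (its "p > .7" reads as r); the
  reports label the quantity r explicitly.
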