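# Methods

This note records the statistical models implemented in `epistage`, the
defaults and why they were chosen, the numerical details, and the limits
of what the synthetic cohorts can demonstrate.

## Coordinates and containers

All genomic coordinates are 0-based half-open (BED convention), including
CpG sites, which are width-1 intervals keyed by the cytosine position;
strand collapsing of CpG pairs is assumed done upstream. Intervals that
share only a boundary coordinate never overlap; every region intersection
in the package uses the ≥ 1 shared base criterion. Strand is carried (for
anchored profiles) but ignored by overlap logic. Methylation tracks,
count matrices and sample sheets are tab-separated text with a header
row; writers sort deterministically so read∘write is the identity.

## Credible-difference DMC calling

Reads are pooled across samples within each group at each CpG; per-sample
hierarchical modelling is deliberately out of scope because the calling
contract is the pooled credible-difference threshold. Each pooled group
level receives a Jeffreys-prior posterior Beta(m + ½, (t − m) + ½). The
credible difference is the bound of the central equal-tailed interval of
p_case − p_ctl nearest zero, zero when the interval spans zero, and its
magnitude is capped at the raw pooled level difference. The cap makes two
useful properties exact rather than asymptotic: |CDIF| ≤ |raw Δ| always,
and CDIF → raw Δ as coverage → ∞ (verified to within 0.01 at pooled depth
10⁵).

Numerics: the CDF of the difference of the two Beta posteriors is
evaluated by 128-node Gauss–Legendre quadrature over the quantile
transform of one posterior, and the two interval bounds are found by
vectorized bisection on [−1, 1] (32 iterations, ≈ 5·10⁻¹⁰ resolution;
documented tolerance 10⁻⁴). A 10⁶-draw Monte-Carlo sampler over the same
posteriors is kept as the independent oracle in the test suite and agrees
to ≈ 10⁻³. Exact antisymmetry under case/control swap is guaranteed by
canonical argument ordering (the statistic is computed once per unordered
pair and negated as needed). The DMC caller skips sites with zero pooled
coverage in either group (never imputes), and exploits the raw-difference
cap to skip sites that cannot reach the threshold — an exact filter, not
an approximation. Credible level defaults to 0.95 and the calling
threshold to 0.20.

DMR merging is direction-stratified: per chromosome and direction,
maximal runs of DMCs whose consecutive start-coordinate gaps are ≤ 200 bp
become DMRs when they contain ≥ 3 members; the span is [first start, last
start + 1). Hyper and hypo runs never merge, which the six-category
heatmap structure of the downstream analysis forces anyway. Input must be
coordinate-sorted; the merger refuses to sort silently.

## NB differential testing

One in-repo negative-binomial Wald engine serves both accessibility and
expression, rather than emulating two external packages; the contract is
the engine defined here. Size factors are median-of-ratios against the
per-feature geometric mean over features nonzero in every sample
(fallback: total-count ratios, with a warning), normalized to geometric
mean 1. Dispersion per feature is the pooled within-group method-of-
moments estimate, shrunk 50/50 toward a log-linear mean–dispersion trend
fitted across features, floored at 10⁻⁸. The Wald statistic is the
difference of log normalized group means (pseudocount 0.5) over its
delta-method standard error with NB variance μ + αμ²; p-values use a
Student-t reference with n₁ + n₂ − 2 degrees of freedom, which calibrates
the small-sample type-I error (measured 0.035 at nominal 0.05 with n = 5
vs 5, 2,000 features, dispersion 0.1). "Adjusted p" means Benjamini–
Hochberg throughout. DAR calls use raw p (the accessibility threshold
sentence specifies a raw p-value); DEG calls use BH q. All thresholds are
strict inequalities, so |log2FC| exactly at a threshold does not qualify.

Normalization invariance (scaling one sample's counts leaves results
unchanged) holds up to the pseudocount and count discreteness; the test
suite asserts it at tolerance 0.05 on log2FC rather than exactly, because
the geometric-mean-1 constraint rescales normalized counts by a common
factor under per-sample scaling.

## Stage-onset categories

The earliest-onset rule is applied literally: a feature takes the
direction and stage of its earliest significant call and later calls are
not considered, even when they flip direction. Features significant at a
later stage with sub-threshold same-direction changes earlier are
governed by the same rule — no look-ahead, no smoothing. One generic
engine serves methylation sites, peaks and genes; srDMRs are produced by
running the DMC-to-DMR merger within each category separately, so
interleaved categories never co-occupy a region.

## Integration and the panel

Peak-level coupling uses Kendall tau-b (tie-corrected; exact p by
enumeration for n ≤ 8 without ties, otherwise the normal approximation)
between normalized accessibility and the read-weighted methylation level
of the peak interval, classified by sign at two-sided p < 0.05 — the
correlated/uncorrelated threshold is a documented default, chosen because
the analysis reports class counts without naming one. All samples enter
one correlation; per-group variants are left to the caller. Within-sample
correlations are estimated by repeated subsampling of peaks without
replacement (defaults 2,000 peaks × 100 repeats, seeded), reported as
mean ± SD.

Region methylation is Σ methylated / Σ total over member CpGs — read-
weighted, never a mean of per-CpG ratios — with missing (zero-coverage)
values flagged absent rather than zero. Accessibility entering the panel
is log2(size-factor-normalized count + 1) for correlation stability.

Panel records are (srDMR, srDAR) pairs, so one srDAR overlapping two
srDMRs yields two records; a per-srDAR deduplicated view is provided.
Per-sample Pearson correlations (t-transform p) relate the three metrics
across panel records. TF–gene co-expression is Pearson r across samples,
co-expressed at p < 0.05, signed by r.

## TF co-localization

Motif-site enrichment is region-containment hypergeometric: the upper
tail of the count of target regions containing ≥ 1 site, drawn from a
background region universe. This deliberately stands in for motif-
discovery enrichment models (GC-matched backgrounds etc.), which are out
of scope; only count-based enrichment over precomputed site calls is
implemented. Epi-TFs are those reaching BH q < α in at least one srDMR
category and at least one srDAR category. Evidence filtering keeps sites
overlapping every supplied evidence track (intersection of evidence), so
adding a track is monotone non-increasing.

Co-localization between two TFs is the Jaccard index of the region sets
they occupy within a stated context — region-level, because the target
display is a symmetric heatmap, which excludes the asymmetric conditional
proportion; the conditional variant (|A∩B|/|A|) is exposed as an option.
Whether proportions should be over regions or over individual sites is
genuinely ambiguous in the source material; region-level is implemented
and site-level noted as a variant. Clustering is average-linkage on
1 − proportion with a maxclust cut (k = 6 mirrors the original figure;
desk-scale cohorts default to 3), deterministic via lexicographic TF
ordering.

## Classification and survival

The classifier is a scikit-learn random forest (500 trees) on the panel's
srDAR methylation — chosen as the panel's key indicator because it
correlates with both other metrics — with a stratified 70/30 train/test
split at a documented seed; hyperparameters, split ratio and repetition
were not specified by the source analysis, so these defaults are exposed
as arguments. Multi-class "average AUC" is the unweighted macro mean of
one-vs-rest AUCs, consistent with per-class AUCs also being reported.
ROC/AUC is computed in-repo (Mann–Whitney with ties half-credited);
missing features are imputed with train-set means.

Sample clustering is Ward linkage on Euclidean distance over region-
methylation vectors, with lexicographic sample ordering for determinism.

Survival stratification splits samples at a quantile (default median) of
mean panel methylation; the low group is ≤ the threshold. The log-rank
chi-square (1 df) is accumulated from observed-vs-expected event sums
over distinct event times with the hypergeometric variance term;
Kaplan–Meier step curves are emitted per group. `lifelines` is the
independent oracle in tests, not the implementation, keeping the dual
route. With no events anywhere, the statistic is flagged undefined
rather than zero.

## The synthetic cohort

The generator emulates the study conditions end to end: four stages
(desk-scale default 10 samples each; the source cohort's 38/33/37/43 can
be configured), CpG coverage Poisson(25.8) floored at 1 so every CpG is
observed, methylated counts beta-binomial with precision 30 (moderate
biological overdispersion — no per-group variance estimates exist to fit
it, so it is documented, not fitted), peak/gene counts negative binomial
(mean 100, dispersion 0.1, log-normal feature baselines and per-sample
size factors), and exponential survival with hazard ∝
exp(−link · panel methylation) under independent uniform censoring, so a
positive link makes low methylation mean high hazard. Survival couples to
the planted *hypo*-methylated regions, mirroring a panel whose
hypomethylation carries the prognostic signal.

Planted effects switch on at their onset stage and persist through IAC —
matching the earliest-onset classification logic; reversals are exercised
only as unit inputs to the assignment rule. Default effect sizes sit at
twice the calling thresholds (methylation Δ 0.4, peak |log2FC| 4, gene
|log2FC| 1.16), the regime in which ≥ 90% category recovery is the
expected behaviour. Each modality draws from its own RNG stream derived
from the master seed, so enlarging one modality never perturbs another,
and identical (config, seed) reproduce bit-identical cohorts.

Genome layout is schematic: one chromosome; each planted methylation
region is 5 CpGs spaced 50 bp; planted peaks (500 bp) are centred on the
planted methylation regions so an srDMR∩srDAR panel exists by
construction; background CpGs and peaks are uniformly tiled. TF site sets
are built from shared region cores sized so that pairwise region Jaccard
equals the configured within-cluster (0.8 in the DAR pool, 0.2 in the
background pool) and between-cluster (0.1) values exactly by
construction.

What this does **not** emulate — and hence what passing tests do not
show about real data: realistic CpG density, CpG islands or TSS
annotation (anchors are synthetic); batch effects and per-sample quality
variation; correlated neighbouring CpGs beyond the planted blocks;
sequence-driven motif occurrence; non-proportional hazards or
covariate-confounded survival. Recovery rates on this generator
demonstrate correctness of the machinery under its stated model, not
field performance.

## Problem sizes

Defaults are desk scale, chosen so the full pipeline (simulate → DMC →
DMR → DAR → DEG → stage → panel → classify → survive) completes in
seconds: 5,000 CpGs, 1,000 peaks, 1,000 genes, 40 samples, 12 TFs. The
calibration simulations use 2,000 NB features, a 5,000-CpG null cohort,
500 survival replicates for null uniformity and 200 for the linked-hazard
direction. All are configurable upward.
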