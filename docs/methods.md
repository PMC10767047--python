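# Methods

`spatglia` reimplements, as a tested pipeline, a spot-level spatial
transcriptomics analysis of glial activation in an amyloid-pathology
("AD") mouse model: clustering spots into anatomical regions, region-wise
differential expression, disease-associated microglia/astrocyte (DAM/DAA)
signature scoring, registration of a fluorescence image to the spot frame
with image-latent gene association, and microglial-signature pseudotime.
Every stage is exercised end to end on data from the package's own
generator, so this note documents both the analysis methods and the
generative model the tests rely on.

## The synthetic study

The generator emulates a 2 genotypes (WT, AD) x 2 ages (3M, 7M) x 2
replicates Visium-style design. Each sample is an offset hex-like lattice
(default 40 x 50 = 2,000 spots, spacing 5 px; row pitch `spacing *
sqrt(3)/2`) partitioned into anatomical regions by parametric geometry:
stacked bands (border, outer cortex, inner cortex, a white-matter band,
striatum, thalamus, border) with an elliptical hippocampal blob. Every
region is non-empty and the WM band is connected by construction.

**Counts.** Gene g in spot s is negative binomial with mean
`baseline_g * fold_p ** a_p(s)` where p is the gene's program and
`a_p(s) in [0, 1]` its activation at that spot, and size (dispersion)
parameter `size` (variance `m + m^2/size`). The default `size = 8` puts
counts in the mildly overdispersed regime of UMI data (variance about
1.5x the mean at typical means); much smaller sizes produce noise levels
at which no spot-level score can separate a two-fold activation, which is
not what UMI-based platforms look like. Optionally each spot's mean
vector is rescaled to a fixed expected library size; by default raw
program means are used so the per-gene mean formula holds exactly.

**Programs.** The default 2,500-gene universe contains

- the eight printed DAM score genes (Lpl, Cst7, Axl, Itgax, Spp1, Cd9,
  Ccl6, Csf1), baseline 2, fold 2 (configurable);
- seven auxiliary activation genes from the 28-gene microglial panel
  (Apoe, B2m, Fth1, Lyz2, Trem2, Ctsl, Timp2), same field;
- thirteen homeostatic microglial genes (Hexb, Cst3, Cx3cr1, ...),
  baseline 2, fold 0.7 — they *fall* with activation;
- the seven DAA genes (Ggta1, Gsn, Osmr, Vim, Serpina3n, Ctsb, Gfap);
- 60 marker genes per region at fold 3 (region-identity programs,
  always on in their own region) — region expression contrasts of this
  size are ordinary for brain anatomy (e.g. myelin genes in WM);
- lognormal-baseline background genes (fold 1) filling the universe.

**Activation field (the WM-early / GM-late pattern).** For the DAM, DAA
and panel programs: AD-3M has WM = 0.8 and GM = 0.1; AD-7M has WM = 1.0
and GM = 0.8; WT is 0 everywhere; border regions carry a BAM-like 0.4 in
every animal. Activation is monotone in age for AD spots, which is the
ground truth the pipeline must recover.

**Plaque image.** The image is a Gaussian-blurred splat field: each spot
deposits `log1p(driver counts)` at its pixel, blurred with a point-spread
sigma (default 3 px), normalized to [0, 1], plus clipped Gaussian read
noise (sd 0.02), then optionally resampled through a known derangement
transform. For image-association studies a dedicated single-sample
simulation gives the driver gene (Cst7) a focal activation field of
Gaussian blobs (six blobs, sigma 14 px, fold 6) — amyloid plaques are
focal deposits and Cst7 is among the most strongly induced DAM genes, so
a strong, spatially structured driver is the realistic condition. The
"true intensity field" used when evaluating latents is the noiseless
image averaged over each spot's 32 x 32 patch footprint, i.e. measured on
the same spatial support as the features; point-sampling at spot centres
would compare quantities smoothed at two different scales and is
confounded at tissue edges.

**Gradient simulation (for pseudotime).** Each spot draws a latent
activation `u ~ Uniform(0, 1)`; activated panel genes follow
`fold ** u` and homeostatic genes `fold ** -u` with fold 8 (DAM markers
swing an order of magnitude on activation). Group labels emulate the
study design: a spot is (AD, 7M) with probability `0.85 u`, otherwise a
random other genotype/age, so the low-activation pole is WT-dominated.

**What the generator does not emulate.** No batch or per-replicate
effects beyond sampling noise, no spatial autocorrelation within a region
beyond the program structure, no cell-type mixtures within spots, no H&E
texture, no UMI/read-level artefacts, no mitochondrial genes (the
mito-fraction covariate is constant and is dropped with a warning).
Passing tests therefore demonstrate correctness of the algorithms under
the stated generative model, not robustness to every artefact of real
Visium data.

## Clustering

Counts are log-normalized per spot (`ln(1 + count/total * 10^4)`,
natural log, scale factor 10,000 — the standard constants of the named
method). Highly variable genes (default n = 2,000) are ranked by
vst-style standardized variance: a lowess trend (frac 0.3, locally
linear) of log10 variance on log10 mean predicts each gene's technical
sd; counts standardized by that sd are clipped at `sqrt(n_spots)` and the
variance of the clipped values is the ranking statistic. Expression is
then residualized on covariates (total counts and mitochondrial fraction
by default), z-scored with the population sd and clipped at +-10. PCA
keeps the top 30 components, signs fixed so the largest-|loading| gene of
each component is positive. A shared-nearest-neighbor graph (k = 20,
Jaccard weights, pruned below 1/15) feeds Louvain community detection at
resolution 0.2; the vertex order is shuffled by the seed and final labels
are size-ranked, making the labeling deterministic under a fixed seed.
Cluster markers come from one-vs-rest two-sided Wilcoxon rank-sum tests
with BH correction, retained at adjusted p < 0.05 and logFC > 0.3.
Cluster-to-region annotation on synthetic data takes the majority
ground-truth region per cluster (the study's visual atlas comparison has
no synthetic analog). Replicate QC is the Pearson correlation of
per-gene average log-normalized expression between samples of a group.

The k for the kNN graph and the edge-weight scheme are package choices
(the source method names only the algorithm and resolution).

## Differential expression

The two-part hurdle test models each gene's log-normalized expression as
a logistic component on detection (expression > 0) and a Gaussian
component on the positive values. Both components include an intercept,
the group indicator, and (by default, toggleable) the spot's fraction of
detected genes as a covariate. The combined statistic is the sum of the
two likelihood-ratio statistics referred to chi-square with 2 df (one
group coefficient per component). Numerical choices: the logistic model
is fitted by IRLS with fitted probabilities clamped to
`[1e-6, 1 - 1e-6]`, which keeps the statistic finite under complete
separation (0% or 100% detection in a group); the Gaussian LR uses the
profile-MLE form `n ln(RSS0/RSS1)` with residual sums floored at 1e-12;
genes all-zero in both groups get p = 1 and logFC = 0; the continuous
component contributes 0 when fewer than three positive spots exist or all
positives fall in one group. logFC is the natural log of de-logged group
means with a +1 pseudocount:
`ln((mean(expm1 x_A) + 1) / (mean(expm1 x_B) + 1))` — the ecosystem
convention matching the thresholds' scale (adjusted p < 0.05 with
logFC > 0.25 for genotype contrasts within a cluster, 0.3 for
cluster-vs-cluster markers). BH adjustment is the step-up rule
implemented directly and cross-checked against an independent reference
implementation in the tests.

The pseudobulk robustness check sums counts per sample within a cluster,
contrasts groups by a two-sided t-test on log2 CPM, and repeats under
label shuffles. With two samples per group only three balanced splits
exist, so shuffles are drawn from the label permutations that do not
reproduce the true grouping in either orientation; DEG counts use raw
p < 0.05 and are reported descriptively (an n = 2/group t-test supports
counting, not inference). Under a true null the true labeling still wins
about one time in three by exchangeability — the diagnostic signal is
the near-certain win on spiked data.

## Signature scores

The module score is the binned-control score: genes are binned into 24
equal-frequency bins of average log-normalized expression (stable rank
cuts); each signature gene draws 100 control genes from its own bin
(without replacement when the bin is large enough, with replacement
otherwise; the signature genes themselves are excluded from the pool);
the per-spot score is the mean expression of the signature genes minus
the mean of the drawn controls. A constant matrix scores exactly zero,
and a recorded seed reproduces scores bit-for-bit. Group comparisons
report per-(cluster, age) genotype means/medians and a two-sided Wilcoxon
p, with fully tied inputs defined as p = 1.

## Image registration and gene association

Images are preprocessed by grayscale conversion, an Otsu threshold brain
mask, and Gaussian smoothing with sigma 5. Registration estimates the
resampling map (fixed frame to moving frame) by Powell optimization of a
mean-squared-error metric over a 3-level multi-resolution pyramid, rigid
(rotation about the image centre plus translation) then full affine;
the returned chain is the inverse, mapping moving coordinates into the
spot frame. The metric is evaluated only over pixels whose sampling
point lands inside the moving image, with a minimum-overlap guard of
50% — otherwise the zero-padded wedges created by rotation dominate the
metric and the optimizer trades alignment for edge coverage. An optional
nonlinear stage runs Gaussian-regularized demons (additive updates,
field smoothing sigma 2, step cap 2 px) — a deliberately simple stand-in
for symmetric diffeomorphic methods — and is kept only if it improves
the masked metric, otherwise the linear transform is returned with a
warning.

Patches are 32 x 32, centred at spot positions with the half-open
convention `[c - 16, c + 16)` and zero padding outside the image. The
feature extractor is a pluggable contract whose shipped implementation is
a training-free bank (mean, sd, 10/50/90% quantiles, gradient-magnitude
mean/sd via central differences, mean Gaussian responses at sigma 1/2/4);
a CNN extractor can be plugged in but nothing in the package requires
trained weights. Features are z-scored and reduced by PCA;
"ImageLatent_1" is sign-fixed to correlate positively with patch mean
intensity. Gene association regresses each gene's log-normalized
expression on the standardized latent; the coefficient is the OLS slope
(equal to the closed form, asserted to 1e-10 in tests), genes are ranked
by descending coefficient, and the top 100 form the image-associated
set. Which variable the source method's "regression coefficient" puts on
which axis is not documented; slope-on-latent is this package's reading.

## Pseudotime

The 28-gene microglial panel (homeostatic plus disease-associated
markers) restricts the matrix; at least half the panel must resolve.
Panel expression is log-normalized, z-scored and embedded by PCA (10
components). The principal graph is learned in a 2-D graph space (the
leading embedding dimensions): k-means with
`k = clamp(ceil(n_spots/50), 5, 100)` centroids, refined for 10
iterations by a SimplePPT-style elastic update (each centroid moves to a
weighted average of its assigned spots and its tree neighbours, strength
1.0) alternating with the minimum spanning tree, then a final MST and
projection of every spot to its nearest point on any edge. The
low-dimensional graph space and the elastic refinement both address the
same failure mode — in higher dimensions, or without regularization,
off-manifold noise between centroids rivals their on-manifold spacing
and the tree grows lateral spur leaves; reference trajectory tools learn
their graphs in a 2-D embedding with an elastic (SimplePPT) objective
for the same reason. A side effect of the elastic pull is mild
contraction of the tree ends, so extreme spots tie at the boundary
pseudotime, as in the reference tools.

The root operationalizes the source's manual "late-phase" orientation:
per node, the fraction of projected spots in the late disease group
(AD, 7M) is computed, and the root is the leaf with the minimal late
fraction (ties to the smallest node id, with a warning; leaves without
projected spots are excluded). Pseudotime is geodesic distance along the
tree from the root to each spot's projection; branches are root-to-leaf
paths, with shared-trunk spots flagged and assigned to every branch
containing their edge; branch labeling by marker profile (e.g. the
high-Axl or high-Lpl trajectory) is a reporting helper that ranks
branches by mean expression of a query gene. Expression-versus-pseudotime
curves use equal-count windows (default 20) with per-window mean and sd.

## Over-representation

Generic over-representation of a query list against GMT gene sets: the
upper-tail hypergeometric probability `P(X >= k)` with BH adjustment
across sets, the universe defaulting to all genes in the dataset. This
replaces database-backed GO/KEGG calls; identifier mapping and ontology
structure are out of scope.

## Problem sizes used by the test suite and acceptance script

Full-design checks (region recovery) use the default 8 x 2,000-spot,
2,500-gene study. Repeated-run checks use scaled designs chosen to keep
each stage's statistical conditions intact: DE calibration uses 2,000
null genes at 200 spots/group and 100 fold-2 spikes; the WM-early check
uses 20 runs of a 2-sample 18 x 20 study with GM activation at parity;
registration and image association use a 256 x 256 image over a 2,000-
spot sample with a 500-gene universe; pseudotime uses 20 runs of the
500-spot gradient simulation; the pseudobulk check uses 20 runs of a
4-sample 14 x 14 study. The unit suite uses smaller variants of the same
configurations.

## Known limitations

- The region geometry is a stylized coronal section; clustering accuracy
  on it does not bound accuracy on real anatomy.
- The hurdle test's chi-square reference is asymptotic; at very small
  groups (fewer than ~50 spots) the type-I error drifts from nominal.
- The demons stage regularizes by Gaussian smoothing only and is not
  diffeomorphic; large or folding warps are out of scope.
- Branch decomposition yields one branch per leaf; the number of
  trajectories on real data depends on the learned tree and need not be
  three.
- Registration assumes the moving and fixed images share intensity
  structure (MSE metric); multimodal pairs would need the optional
  mutual-information metric, which is not implemented.
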