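# Methods

`rootpheno` implements a desk-scale pipeline for seedling root-system-
architecture (RSA) phenomics of a diversity panel: simulated inputs with
recorded ground truth, image-based trait extraction, mixed-model genetics of
the extracted traits, ideotype scoring, population structure, and a
mixed-model association scan. This note records the models, the parameter
choices, the numerical decisions, and what the synthetic tests do and do not
demonstrate about real data.

## Root-growth simulator

A root system is a set of 2-D polylines in cm, seed point at the origin,
*y increasing downward*. The primary axis grows in fixed steps of 0.05 cm —
small enough that arclength error from within-step curvature is negligible
(<0.1%) at realistic tortuosity. The heading `theta` (degrees from vertical,
signed) follows an AR(1) process per step,

    theta_t = (1 - gravitropism) * theta_{t-1} + Normal(0, tortuosity_sd),

so `gravitropism` in [0, 1] is the per-step relaxation toward the gravity
axis and `tortuosity_sd_deg` the per-step heading noise. First-order
laterals emerge along the primary as a Poisson process in arclength: within
the day window in which a stretch of primary grew, the number of new
laterals is Poisson(`lateral_rate_per_cm` x new arclength), positioned
uniformly on it; consequently the total count at day *d* is Poisson(rate x
primary length at *d*), the property the goodness-of-fit test checks. Each
lateral starts at `+-Normal(lateral_angle_mean_deg, lateral_angle_sd_deg)`
from vertical (random side) and grows by the same step process at
`lateral_rate` cm/day. The primary tapers linearly from `diameter_base_cm`
to `diameter_tip_cm` over its current length; laterals are drawn at the tip
diameter.

An optional `min_lateral_spacing_cm` thins emergences to a hard-core
(Matérn-I) process. This is the generator's notion of *well-separated
laterals*: at 20 px/cm, emergences closer than a few pixels are physically
unresolvable in any image, so recovery guarantees are stated for the
hard-core regime while the default remains pure Poisson.

Default parameters bracket a mung-bean-like seedling at day 15: primary
rate 2.85 cm/day (~43 cm primary), lateral density 3.2 per cm of new
primary with 0.19 cm/day elongation (~130 visible laterals, total length
~230 cm, growth rate ~25 cm/day between days 12 and 15), mean emergence
angle 50 degrees, and a 0.32→0.16 cm taper (median diameter ~0.24 cm).
These magnitudes are plausibility brackets, not estimates fitted to any
particular panel.

Snapshots default to days 12, 15 and 18, and every generator is
deterministic given its integer seed.

### Ground truth

`true_traits` evaluates the trait set directly on the polylines: TRL as the
sum of arclengths, PRL the primary arclength, DEP/WID the extents of the
thickness-inflated silhouette (so a rendered mask's bounding box is the
estimator of the same quantity), LRB the count of laterals with nonzero
length, TRL_Upper/LED from the centerline depth extent split into three
equal bands, and LRA as the *median over points sampled every 0.05 cm along
all laterals of the tangent angle from vertical* (tangents by central
difference over ±0.1 cm). The image pipeline uses the identical sampling
convention, which is what makes the ±5-degree recovery statement
well-posed; an emergence-angle-only definition would disagree with any
whole-lateral estimate whenever laterals curve gravitropically.

## Renderer

Polylines are rasterized with per-segment width from the diameter taper and
round joints; the clean render is binary (255 on 0). The nuisance model
adds, in order: distinct fore/background gray levels, a linear illumination
ramp along the rows, bright circular speckles ("water spots"), and Gaussian
pixel noise — enough structure to exercise threshold selection without
modeling a specific camera. Renders are byte-deterministic.

## Image pipeline

**Segmentation.** Rotation to portrait if needed, optional top-band crop
(label removal), channel selection (gray/LAB-L/HSV-V/single RGB channel),
Otsu threshold by default, 8-connected components with debris below 25 px
discarded and the largest component retained. An empty result raises a
blank-image signal; blank images are excluded from analysis.

**Skeleton graph.** `skimage.morphology.skeletonize` thins the mask; pixels
of degree ≠ 2 become nodes and pixel chains become edges. Three cleanups
make the graph match the physical topology: (1) leaf chains shorter than
`max(prune_cm, local root radius at the junction)` are removed — thinning
spurs scale with local thickness, so the radius guard adapts the prune
length instead of hard-coding it; (2) junction cliques (several adjacent
degree-3 pixels at one physical branch point) are contracted to single
nodes; (3) degree-2 nodes left over are spliced out.

**Edge lengths.** Summing 1/sqrt(2) pixel steps overestimates digitized
straight lines by up to ~8% near 22.5-degree orientations, which would
consume the entire TRL error budget. The default estimator therefore
resamples each chain at 5-px anchors and sums Euclidean anchor distances
(`length_method="resampled"`); the raw step-sum stays available as
`length_method="chain"`. A vertical 100-px bar measures 100 px under both.

**Primary path and laterals.** The seed node is the topmost endpoint (ties:
leftmost). The primary is the Dijkstra path from the seed to the deepest
endpoint; among equal-depth endpoints the longer path wins. A lateral that
outgrows the primary in depth will capture the path — there is no reliable
pixel-level signal to distinguish that case from a tortuous primary, so the
behaviour is documented rather than guessed at. Lateral emergences are
counted as attachment points of off-path skeleton components to the path,
clustered along the path at a 3-px tolerance so that a stem frayed into
several skeleton pieces, or attached through adjacent pixels, counts once;
crossing laterals still count once per distinct emergence.

**Traits.** DEP/WID from the mask bounding box; DIA as the median of
`(2*EDT - 1)` px along the path (the -1 corrects the distance transform's
half-pixel bias); CVA from the convex hull; SOL = area/hull in (0, 1];
RHZO as the area added by a 2 mm dilation; PRA/VOL from the cylinder model
along the path; depth thirds on the skeleton's own extent with per-edge
band fractions so TRL = TRL_Upper + TRL_Lower exactly; LRA as above, with
chains under 5 px (junction rungs/frays) excluded and chains smoothed by a
3-px moving average before resampling — the window that minimizes angle
error against the simulator oracle while avoiding the step-angle
quantization of coarser subsampling. NWA is the raw skeleton pixel count;
published trait tables sometimes carry NWA and SOL on undocumented scales,
so `nwa_divisor` and `sol_scale` rescalings are exposed and recorded in the
output metadata rather than silently applied.

Recovery, verified against the simulator oracle at 20 px/cm with 0.5 cm
hard-core lateral spacing (see `tests/test_acceptance.py` and
`scripts/acceptance.py`): TRL within 5%, exact lateral counts, LRA within
5 degrees, DEP/WID within 2 px. Outside the hard-core regime a small tail
(~3% of systems) loses up to ~8% of TRL when two laterals run nearly
parallel and their renders merge — a genuine resolution limit, not a
skeleton defect.

## Phenotypic statistics

**Tukey filter.** Quartiles by linear interpolation between order
statistics (the numpy default); fences at Q1/Q3 ∓ 1.5 IQR; filtering is
applied before model fitting, optionally within groups (e.g. per day).
The convention is recorded because fence membership depends on it.

**Mixed model.** Per trait, `y = mu + chamber + (chamber:block) +
(chamber:block:sub-block) + genotype + e`, chamber fixed, the rest iid
normal random effects. REML is evaluated on the profiled scale: with
variance ratios `gamma_i = sigma_i^2 / sigma_e^2`, the criterion needs only
the Cholesky factor of the q x q matrix `I + D Z'Z D` (q = total random
levels, a few hundred at desk scale), and the residual variance is profiled
out analytically. L-BFGS-B optimizes the ratios with non-negativity bounds
from three starts; boundary estimates are flagged. A dense-grid
profile-likelihood oracle in the tests pins the deviance to 1e-4 on a
printed fixture. Unbalanced tables are handled as-is; nothing is imputed.

**BLUPs, PEV and heritability.** Henderson's mixed-model equations at the
REML estimates give the genotype BLUPs and the full genotype block of the
prediction-error covariance. The Cullis broad-sense heritability is
`H = 1 - Vdelta / (2 sigma_g^2)` with `Vdelta` the mean over genotype pairs
of `Var(BLUP_i - BLUP_j)`, computed exactly from that block (g up to ~1000;
a diagonal-only approximation is available behind `pev_mode="average"` and
reports its own error). `sigma_g^2 = 0` yields H = 0 with a degenerate-fit
flag; numerically out-of-range values are clipped and flagged. BLUPs are
reported as genotype effect plus the mean fixed-effect intercept so
downstream ranking operates in trait units. In the balanced limit with
block variances 0 this reduces to `H = r sigma_g^2 / (r sigma_g^2 +
sigma_e^2)`, the check used at r = 8.

Descriptive statistics (mean, median, min, max, SD with n-1, CV%) can be
computed on raw observations (default) or genotype means; correlations are
Pearson, pairwise-complete, with zero-variance traits dropped loudly.

## Ideotype scoring

Rank per component trait (1 = best in the trait's preferred direction,
average ranks on ties), sum, rank the sums; final ties break by genotype id
and are flagged. Topsoil foraging uses TRL_GR, WID, TRL_Upper (all up);
steep-cheap-deep uses TRL_GR (up), LRA bound to *steepness* (down under the
from-vertical convention; a flag flips it for from-horizontal data), and
solidity (down). Scoring operates on BLUPs by default — they are what the
mixed model extracts per genotype — and the scheme is deliberately
unweighted. Monotonicity (improving one component never worsens the final
rank) and permutation invariance are property-tested.

## Population structure

PCA mean-imputes per site, centers (optionally scales), and uses SVD;
constant features are dropped with a warning. Clustering is complete-linkage
agglomeration on Euclidean distances of the mean-imputed, centered dosage
matrix (or a trait matrix), cut at k; SciPy's deterministic earliest-pair
tie rule applies, so duplicated points merge first at height 0. The cluster
count is a majority vote of three internal indices — silhouette,
Calinski-Harabasz, and the Tibshirani gap statistic with B = 50 uniform
reference sets — a reduced panel standing in for the 30-index comparisons
of common R tooling; the full per-index table is returned for audit and
vote ties resolve to the smaller k, flagged.

Pairwise Fst is the Weir-Cockerham (1984) estimator: per biallelic locus
the a (among-population), b (among-individual) and c (within-individual)
components from allele frequencies, per-cluster genotyped counts and
observed heterozygosity (dosage-1 fraction among genotyped individuals),
combined as the ratio of averages `theta = sum(a) / sum(a+b+c)` over
polymorphic loci with at least two genotyped individuals per cluster. The
genotype simulator's Balding-Nichols model (subpopulation frequencies
Beta-distributed around an ancestral frequency with dispersion F) provides
the known target; F = 0 bypasses the degenerate Beta. Estimator code is
pinned to an independently written scalar implementation at 1e-10.

## GWAS

Sites are filtered on missingness (> 15% removed) and minor allele
frequency (< 0.01 removed — the standard reading; the literal "MAF > 0.01
removed" wording some protocols print is available behind a flag for
comparison). Kinship is the centered VanRaden matrix `Z Z' / (2 sum p(1-p))`
on mean-imputed dosages. The scan is P3D: the null model `y = X b + u + e`,
`u ~ N(0, sigma_g^2 K)`, X = intercept plus the first 3 dosage PCs
(configurable), is fitted once by REML in the eigenbasis of K (1-D
optimization of the variance ratio, grid-bracketed), and the resulting
covariance whitens the data for all marker tests — per-marker GLS slopes
with two-sided t tests, fully vectorized. Marker R^2 is the share of
covariate-adjusted, whitened phenotypic variance explained by the marker;
the definition is recorded in the scan metadata since published tables
rarely state theirs. Markers collinear with the covariates get missing
p-values and are excluded from the Bonferroni denominator `alpha / m`.
At K = identity the scan reduces exactly to OLS (tested to 1e-6), null
p-values are uniform, and including K + PCs holds genomic inflation within
[0.9, 1.1] on structured panels where the uncorrected scan inflates past
1.2.

A deliberately red check: with a planted QTL at 10% of phenotypic variance,
n = 200 and m = 1000, detection at Bonferroni has analytic power ~0.74
(noncentrality sqrt(200 * 0.1/0.9) = 4.71 against a 4.06 threshold),
slightly reduced further by the QTL's own contribution to the kinship; the
measured rate is ~64-68%, so a >= 80%-detection requirement is not
attainable at these sizes and the corresponding assertion fails honestly
rather than being loosened.

## What the synthetic data does and does not show

The generators reproduce the statistical skeleton of a chamber experiment —
design structure, variance components, Poisson branching, Balding-Nichols
differentiation, missingness — but not root hairs, second-order laterals,
overlapping seedlings, paper texture, color variation, linkage
disequilibrium, or genotype-dependent growth. Passing tests therefore
demonstrate that the estimators recover what they claim from data obeying
their assumptions; they do not certify segmentation quality on real
photographs, where thresholding and crossing-root topology are the dominant
error sources.

## Problem sizes

Tests and the acceptance script run at deliberately modest sizes — 50
rendered systems at 20 px/cm, 96 genotypes x 8 replicates for mixed-model
simulations, 2 x 100 individuals x 5000 loci for Fst, 200-individual panels
with 400-1000 markers and 200 replicate scans for GWAS calibration — sizes
at which every check completes in seconds to a couple of minutes while the
sampling error of each checked quantity stays well inside its stated
tolerance.
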