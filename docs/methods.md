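# Methods

`radclust` implements a CT radiomics analysis chain: extraction of a
440-feature vector per tumor, consensus clustering of the features to find
redundant groups, validation of the clustering on external cohorts,
quantification of clinical associations, and medoid-based multivariable
prognostic signatures. A synthetic phantom module generates cohorts with a
known latent structure so that every stage can be tested against ground
truth.

## Radiomic features

Exactly 440 features per image/mask pair, in four groups:

- **Intensity (15).** First-order statistics of the in-mask HU
  distribution: energy, entropy, kurtosis, maximum, mean, mean absolute
  deviation, median, minimum, range, RMS, skewness, standard deviation,
  uniformity, variance, total energy (energy × voxel volume). Entropy and
  uniformity are histogram statistics (base-2 logs). Variance is the
  sample variance; skewness/kurtosis are population moment ratios.
- **Shape (8).** Volume (voxel count × voxel volume), surface area,
  surface-to-volume ratio, sphericity π^{1/3}(6V)^{2/3}/A, compactness
  V/(√π A^{3/2}) and 36πV²/A³, spherical disproportion A/(4πR²) with
  R=(3V/4π)^{1/3}, and the maximum 3D diameter (largest pairwise distance
  between surface-voxel centers), all in physical units.
- **Texture (33).** 22 GLCM statistics (autocorrelation, cluster
  prominence/shade/tendency, contrast, correlation, difference entropy,
  dissimilarity, energy, entropy, two homogeneities, IMC1/IMC2, IDMN, IDN,
  inverse variance, maximum probability, sum average/entropy/variance,
  variance) and 11 GLRLM statistics (SRE, LRE, GLN, RLN, RP and the
  low/high gray-level variants). Matrices are built per direction over the
  13 unique offsets of the 26-neighborhood (modulo sign) and statistics
  averaged over directions. GLCMs use distance 1 voxel and are symmetrized
  by adding the transpose before normalization. GLRLM runs are maximal
  same-level voxel sequences inside the mask; runs break at mask
  boundaries. Sum variance is centred on the sum average (conventions in
  the literature vary between sum average and sum entropy here).
- **Wavelet (384).** A one-level undecimated (stationary) coiflet-1
  transform of the full image yields 8 sub-bands on the original grid; the
  15 intensity and 33 texture statistics are recomputed inside the original
  mask on each sub-band. The transform uses the energy-preserving
  normalization, so the LLL band is a unit-DC-gain low pass. Shape features
  are not recomputed per sub-band — they depend only on the mask, so the
  copies would be byte-identical; the 440 total only balances without them.

**Discretization.** Texture and histogram statistics use a fixed bin count
(default 32) over the in-mask intensity range, per sub-band for wavelet
features. A fixed-count scheme is scale-robust, which matters because
wavelet sub-band amplitudes differ from HU by orders of magnitude. A
fixed-bin-width mode is available.

**Degenerate inputs.** Constant regions are mapped to a single gray level;
skewness and kurtosis of a zero-variance region are defined as 0, GLCM
correlation as 1, and IMC1 as 0. These conventions keep constant phantoms
NaN-free and are deliberate, documented choices rather than numerical
accidents.

**Geometry conventions.** Texture offsets are voxel steps on the native
grid (no resampling); shape features use the physical spacing. Surface area
comes from a marching-cubes triangulation of the mask after a light 0.5
voxel Gaussian pre-smoothing: raw binary marching cubes overestimates a
digital ball's area by ~7%, which would cap sphericity near 0.92; with
smoothing a radius-20 ball scores 0.96, and masks too small for the
smoothed field to cross the iso-level fall back to the binary surface.

## Consensus clustering of features

Features (not patients) are the clustered items. The dissimilarity is
1 − r with r the Pearson correlation of two feature columns across
patients; correlation is affine-invariant, so no prior normalization of the
features is needed. Linkage is Ward in the "apply the Lance–Williams ward
update to the dissimilarity itself" convention (ward.D); internally this is
computed as scipy's ward on √d, which is algebraically identical. Each
consensus iteration draws an 80% feature subsample (all patients kept),
clusters it, and cuts the tree at every candidate K; consensus(i,j) is the
fraction of co-clusterings among co-inclusions. Pairs never co-sampled
(vanishingly rare) are reported as consensus 0 with a warning. The default
is 10,000 iterations; analyses in this repository use 1,000, where
consensus entries differ from the 10,000-iteration values by well under
0.05 on structured phantoms.

**Choosing K.** A(K) is the area under the empirical CDF of off-diagonal
consensus entries and Δ(K) its relative gain over K−1. Splitting beyond the
true cluster count still gains 0.03–0.08 relative area (resampling
ambiguity; larger for fewer/bigger clusters), while gains at or below the
true K measured 0.18–0.45 on redundancy phantoms, so the elbow threshold
defaults to 0.1. The candidate range is the elbow neighborhood [K*, K*+1],
where K* is the largest K with Δ(K) above threshold; within it the K with
the highest **median per-cluster consensus** wins, ties to the smaller K.
The range deliberately excludes K below the elbow: merging well-separated
clusters is perfectly stable under feature resampling, so small K would
win every median-consensus comparison and the rule would degenerate to
K=2 on exactly the data where the answer is clearest.

A caveat this package makes explicit: structureless (pure noise) data also
produces large relative delta-areas at small K — the known null artifact of
consensus clustering — so no fixed threshold can make the elbow rule
"collapse" on noise. Noise is instead recognizable by its median cluster
consensus (~0.5, category "poor") against ~1.0 for real structure.

Per-cluster statistics: cluster consensus (mean consensus over within-
cluster pairs; singletons defined as 1) with qualitative categories poor
(<0.5) / moderate (<0.75) / high (≥0.75), and cluster compactness (mean
|r| over within-cluster pairs — absolute value, keeping the stated [0,1]
range even for anti-correlated members).

## Cluster validation and overlap

An external cohort is clustered by plain hierarchical clustering (no
resampling) at the reference K. Agreement is the unadjusted Rand statistic
RS = (SS+DD)/C(n,2) over feature pairs, computed via the contingency-table
identity (the tests check it against a naive pair loop). Significance is a
one-sided permutation test shuffling the external labels over features
(preserving cluster sizes), with the add-one estimator
p = (1+#{RS_null ≥ RS_obs})/(1+B). Cluster-by-cluster overlap of two
clusterings is the Jaccard index of member sets with categories poor/
moderate/high at 0.5 and 0.75.

## Clinical associations

Survival associations use Harrell's concordance index. A pair is
comparable when the patient with the strictly smaller observed time had
the event; tied observed times are incomparable (the strict convention —
one unambiguous rule rather than special-casing censored ties); tied risk
scores count 1/2. Features are never sign-flipped: CI < 0.5 is reported
as-is, and cluster means use raw CIs. Categorical covariates use the
rank-based AUC; covariates with >2 levels use the mean of pairwise
two-class AUCs over class pairs (the later-sorting class of each pair is
"positive", which makes the 2-class case reduce exactly to the plain AUC).

The per-feature prognostic screen permutes outcomes (B=1000 by default),
corrects across the 440 features by Benjamini–Hochberg, and flags features
with q < 0.05 and CI > 0.5. Cluster-level significance recomputes every
feature's statistic under each outcome permutation and re-averages within
the cluster. Qualitative performance categories: poor (<0.6), moderate
(<0.75), high (≥0.75).

## Signatures

The medoid of a cluster is the feature with the highest mean |r| to its
cluster mates (ties broken lexicographically; constant features excluded).
One medoid per cluster enters a multivariable model: Cox proportional
hazards for survival, logistic regression for categorical parameters (one
binary model per class pair beyond two levels, aggregated by pairwise
AUC). Medoid columns are standardized with training mean/sd and the
parameters travel with the model; evaluation on a new cohort applies the
stored standardization and coefficients and never refits. Model fitting
delegates to lifelines (Cox partial likelihood) and scikit-learn
(logistic); non-convergence or separation falls back to a small ridge
penalty with a warning.

## The phantom cohorts

Two generators provide ground truth at different levels.

**Image phantom** (`generate_cohort`). Each of N patients carries four
latent standard-normal factors: size (log radius multiplier, 0.18/sd,
clipped at ±2 sd so the tumor provably fits the grid), mean attenuation
(25 HU/sd), texture correlation length (log multiplier 0.35/sd around a
1.2-voxel Gaussian kernel) and heterogeneity amplitude (log multiplier
0.4/sd around 30 HU). The tumor is an ellipsoid (radii uniform in 5–8.5 mm
per axis) modulated by degree-2 spherical harmonics (sd 0.06); the interior
is mean + a spatially correlated Gaussian field (exactly centred over the
interior, so the zero-noise interior mean is exact) + 3 HU white noise on
a −100 HU background. Survival is exponential proportional hazards on the
factors (default β = 0.8 on the mean factor, baseline hazard 0.05) with
independent uniform censoring whose horizon is solved by bisection to hit
the target censoring fraction (default 0.3). Histology/stage/HPV follow
logistic and ordinal-logit models on the factors. One RNG stream per
cohort, seeded from the PhantomSpec. `draw_outcomes` redraws outcome vectors from
the latent truth alone — the instrument for null calibrations where
outcomes must be independent of the images.

`planted_feature_groups` labels each extracted feature with the factor of
its largest |Pearson r| (below a floor, default 0.3: "unassigned"). A
structural property worth knowing: dispersion-type statistics respond to
any latent change with both signs (uniformity falls where entropy rises),
so under the signed 1 − r dissimilarity each image-level factor induces
*two* anti-correlated feature poles. The unsigned argmax-|r| partition is
therefore not recoverable as K clusters of a K-factor image phantom — which
is why cluster-recovery experiments use the second generator.

**Feature-level redundancy phantom** (`latent_feature_table`). Groups of
features equal to their group's latent factor plus independent noise
(positive unit loadings; noise sd 0.7, giving within-group r ≈ 0.67 —
comparable to a compact radiomic cluster). Defaults: 4 factors × 15
features, the planted partition known by construction. On this instrument
the consensus pipeline selects K = 4 and recovers the partition exactly
across seeds, and an independently generated cohort validates at RS ≈ 1.

**What the phantoms do not emulate:** CT reconstruction physics, organ
context and tissue boundaries other than the tumor rim, inter-scanner
variation, delineation variability, and correlated (structured) noise.
Passing tests demonstrate the pipeline's statistical machinery on data
with known truth, not clinical performance on real cohorts.

## Problem sizes and numerical choices

Study-scale analyses in the tests and the acceptance script use
200-patient cohorts on 44³ grids (tumor radii 5–8.5 voxels), 1,000
consensus iterations over K = 2..8, 1,000-permutation validation tests,
100-permutation nulls for the 200-draw calibration study (the add-one
permutation p is exactly discrete-uniform under the null, so a 100-point
grid is sufficient for a Kolmogorov–Smirnov uniformity check at n = 200;
calibration uses an 80-patient subset), and a single ~64-voxel-diameter
tumor for the per-patient extraction timing. Tolerances: brute-force
oracle agreement is asserted at 1e-10; CSV round-trips at 1e-12.

## Known limitations

- Single-level wavelet decomposition only; no LoG or other filter banks.
- No isotropic resampling by default (offsets are voxel steps); anisotropic
  spacings therefore mix physical distances across directions.
- The delta-area elbow needs a threshold; 0.1 is calibrated for crisp-to-
  moderate redundancy structure and is configurable, but no threshold
  detects pure-noise inputs (use the stability categories for that).
- Harrell's CI with the strict tie rule discards tied-time pairs entirely;
  heavy time ties would waste information (not an issue for continuous
  simulated times).
- The pairwise-logistic multiclass signature aggregates per-pair AUCs; it
  does not produce a single calibrated multiclass probability.
- Medoid purity depends on the granularity of the clustering: because each
  image-level factor splits into anti-correlated feature poles under 1 - r,
  a coarse K merges poles of different factors and the resulting medoids
  (chosen for within-cluster centrality) can track any single factor only
  weakly, diluting downstream signatures. Finer K (closer to the number of
  poles) yields purer medoids and stronger transfer.
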