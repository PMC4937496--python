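# radclust

Radiomic feature clustering and prognostic signatures for 3D CT tumor
volumes.

Radiomics converts a segmented tumor on a CT scan into hundreds of
quantitative descriptors — intensity histogram statistics, 3D shape,
gray-level co-occurrence and run-length texture, wavelet sub-band
variants. Many of those descriptors measure nearly the same thing, which
inflates models and hides what is actually prognostic. `radclust`
addresses the redundancy directly: it clusters the *features* (not the
patients), checks that the clusters are stable under resampling and
reproducible in external cohorts, quantifies each cluster's association
with survival and clinical covariates, and compresses each cluster into a
single representative feature (its medoid) for multivariable prognostic
models.

The package is aimed at quantitative-imaging researchers who want a
tested, reproducible reference implementation of this analysis chain, plus
a synthetic phantom generator with planted ground truth for validating
each stage.

## What it computes

- **Features** — exactly 440 per image/mask pair: 15 first-order intensity,
  8 shape, 33 texture (22 GLCM + 11 GLRLM statistics averaged over the 13
  unique 3D directions), and 8 × 48 = 384 wavelet features from a one-level
  undecimated coiflet-1 transform.
- **Consensus clustering** — Ward linkage on the dissimilarity 1 − r
  (Pearson correlation of feature columns across patients), with 80%
  feature resampling. The consensus matrix M(i,j) is the fraction of
  resampling iterations in which features i and j co-cluster; the number
  of clusters K comes from the delta-area elbow of the consensus CDF
  followed by the highest-median-cluster-consensus rule.
- **Validation** — Rand statistic RS = (|SS|+|DD|)/C(n,2) between a
  reference clustering and a freshly clustered external cohort, with a
  label-permutation significance test; Jaccard overlap |L∩H|/|L∪H| between
  individual clusters of two cohorts.
- **Clinical relevance** — per-feature and per-cluster Harrell concordance
  index (survival) and rank-based AUC (categorical covariates; pairwise
  multiclass AUC beyond two levels), permutation significance,
  Benjamini–Hochberg FDR across features.
- **Signatures** — one medoid per cluster into a multivariable Cox
  proportional-hazards or logistic model; training-cohort standardization
  travels with the model and evaluation never refits.

## Worked example

Consensus clustering on a cohort with four planted redundant feature
groups (`examples/03_consensus_clusters.py`):

```text
delta-area per K: {2: 0.508, 3: 0.275, 4: 0.177, 5: 0.031, 6: 0.03, 7: 0.028, 8: 0.027}
candidate K range from the elbow: (4, 5)
chosen K: 4
per-cluster consensus (stability): {1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0}
per-cluster mean |r| (compactness): {1: 0.645, 2: 0.665, 3: 0.649, 4: 0.669}
```

The relative gain in consensus-CDF area collapses after K=4 (0.177 →
0.031), so the elbow bounds the candidates to {4, 5}; K=4 wins with every
cluster re-forming in essentially all resampling iterations (consensus
1.0). Compactness ≈ 0.67 is the mean within-cluster correlation implied by
the generator's noise level.

Building and transferring a prognostic signature
(`examples/06_prognostic_signature.py`, 80 patients per cohort):

```text
standardized Cox coefficients (log hazard per sd):
  wavelet_HLL_firstorder_energy                 +0.907
  wavelet_LHH_glcm_imc2                         +0.612
  wavelet_HLH_glcm_sum_entropy                  +0.335
  wavelet_HLH_glcm_homogeneity2                 +0.230

training CI:   0.676
validation CI: 0.587
```

The phantom plants a log-hazard of 0.8 per sd on the mean-attenuation
factor; the medoid tracking intensity location gets the dominant
coefficient and the signature keeps most of its discrimination on an
independent cohort (CI ≈ 0.59 at n = 80, ~0.65–0.70 at n = 200; 0.5 is
chance).

The other examples cover cohort simulation, feature extraction, external
validation with cluster overlap, and per-feature/per-cluster clinical
screens. A thin CLI mirrors the library (`radclust simulate | extract |
cluster | validate | overlap | associate | screen | signature | run`).

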