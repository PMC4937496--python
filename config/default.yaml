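# Full default configuration for `radclust run` (CLI flags override).
# Every stochastic stage requires `seed`; it is left unset here on purpose
# so unseeded runs fail loudly rather than silently irreproducibly.

out_dir: radclust_run
n_patients: 40
grid_shape: [44, 44, 44]
radii_range: [5.0, 8.5]

# gray-level discretization for histogram/texture features
n_bins: 32

# consensus clustering
n_iterations: 1000
subsample_fraction: 0.8
k_candidates: [2, 3, 4, 5, 6, 7, 8]
delta_area_threshold: 0.1

# permutation tests (validation, screens, cluster associations)
n_perm: 1000

# seed: 42
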