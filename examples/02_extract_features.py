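"""Extract the 440-feature radiomic vector from one tumor.

The vector concatenates 15 first-order intensity statistics, 8 shape
descriptors, 33 texture statistics (22 GLCM + 11 GLRLM, averaged over the
13 unique 3D directions) and 384 wavelet features (the same intensity and
texture statistics on the 8 sub-bands of an undecimated coiflet-1
transform).
"""

from collections import Counter

from radclust import PhantomSpec, extract_all, generate_cohort

cohort = generate_cohort(PhantomSpec(n_patients=2, seed=3))
vec = extract_all(cohort.images[0], cohort.masks[0])

print(f"features extracted: {len(vec.values)}")
print(f"group sizes: {dict(Counter(vec.groups.values()))}")
print("\na few values:")
for name in [
    "firstorder_mean",
    "firstorder_entropy",
    "shape_volume",
    "shape_sphericity",
    "glcm_contrast",
    "glrlm_long_run_emphasis",
    "wavelet_HHH_firstorder_variance",
]:
    print(f"  {name:40s} {vec.values[name]:12.4f}")
# shape_volume is in mm^3; firstorder_mean in HU; texture statistics are
# dimensionless functionals of the discretized gray-level distribution.
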