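"""Simulate a small phantom cohort and look at what it contains.

Each patient is a 3D CT-like volume with an ellipsoidal tumor whose size,
mean attenuation, texture correlation length and heterogeneity amplitude
are driven by four latent factors; survival and categorical outcomes are
linked to those factors.
"""

from radclust import PhantomSpec, generate_cohort

spec = PhantomSpec(n_patients=6, seed=1)
cohort = generate_cohort(spec)

print(f"patients: {len(cohort.images)}")
print(f"grid: {cohort.images[0].shape}, spacing {cohort.images[0].spacing} mm")
print(f"tumor sizes (voxels): {[m.n_voxels for m in cohort.masks]}")
print("\nlatent factors (ground truth driving the images):")
print(cohort.latent.round(2))
print("\nclinical outcomes linked to the factors:")
print(cohort.clinical[["time", "event", "histology", "stage", "hpv"]].round(2))
# The 'mean' factor carries a log-hazard of 0.8 per sd by default, so
# patients with higher mean attenuation tend to fail earlier.
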