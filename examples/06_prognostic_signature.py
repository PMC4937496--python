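"""Build a medoid-based Cox signature and test it on a validation cohort.

One representative feature (the medoid: highest mean |r| to its cluster
mates) is taken per cluster; a multivariable Cox model is fitted on the
training cohort and evaluated — without refitting — on an independent
validation cohort.
"""

from radclust import (
    ConsensusConfig,
    PhantomSpec,
    consensus_cluster,
    evaluate_signature,
    extract_cohort,
    fit_cox_signature,
    generate_cohort,
    select_medoids,
)

train = generate_cohort(PhantomSpec(n_patients=80, seed=21))
val = generate_cohort(PhantomSpec(n_patients=80, seed=22))
t_train = extract_cohort(train.images, train.masks, train.patient_ids)
t_val = extract_cohort(val.images, val.masks, val.patient_ids)

result = consensus_cluster(
    t_train, ConsensusConfig(n_iterations=200, k_candidates=tuple(range(2, 8)), seed=21)
)
medoids = select_medoids(t_train, result.assignment)
print(f"cluster medoids ({len(medoids)}):")
for m in medoids:
    print(f"  {m}")

model = fit_cox_signature(t_train, train.clinical, medoids)
print("\nstandardized Cox coefficients (log hazard per sd):")
for m, c in model.coefficients.items():
    print(f"  {m:45s} {c:+.3f}")

ci_train = evaluate_signature(model, t_train, train.clinical)
ci_val = evaluate_signature(model, t_val, val.clinical)
print(f"\ntraining CI:   {ci_train:.3f}")
print(f"validation CI: {ci_val:.3f}")
# The planted prognostic effect sits on the mean-attenuation factor, so the
# medoid of the cluster tracking intensity location (here the low-pass-band
# energy) carries the dominant coefficient, and the validation CI stays
# above 0.5 (around 0.6 at this modest cohort size; ~0.65-0.70 at n=200).
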