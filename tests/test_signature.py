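import numpy as np
import pandas as pd
import pytest

from radclust import (
    ClusterAssignment,
    SignatureModel,
    auc,
    evaluate_signature,
    fit_cox_signature,
    fit_logistic_signature,
    select_medoids,
)
from radclust.features.extract import FeatureTable
from radclust.phantom import draw_outcomes, latent_feature_table


def table_from(data: pd.DataFrame) -> FeatureTable:
    return FeatureTable(data=data, groups=pd.Series({c: "latent" for c in data.columns}))


def survival_from_factor(z: pd.Series, beta: float, seed: int, censoring=0.3):
    latent = pd.DataFrame({"f": (z - z.mean()) / z.std()})
    return draw_outcomes(
        latent, (beta,), 0.05, censoring,
        {"histology": (0.0,), "stage": (0.0,), "hpv": (0.0,)}, seed=seed,
    )


# --- medoids --------------------------------------------------------------

def test_medoid_is_hub_of_correlation_triangle():
    rng = np.random.default_rng(0)
    n = 400
    hub = rng.standard_normal(n)
    # two satellites correlate ~0.9 with the hub, ~0.8 with each other
    data = pd.DataFrame(
        {
            "sat1": hub + 0.5 * rng.standard_normal(n),
            "hub": hub,
            "sat2": hub + 0.5 * rng.standard_normal(n),
        },
        index=[f"P{i}" for i in range(n)],
    )
    asg = ClusterAssignment(labels=pd.Series([1, 1, 1], index=data.columns), k=1)
    assert select_medoids(table_from(data), asg) == ["hub"]


def test_singleton_cluster_medoid_is_itself():
    rng = np.random.default_rng(1)
    data = pd.DataFrame(
        rng.standard_normal((50, 3)), columns=["a", "b", "lone"],
        index=[f"P{i}" for i in range(50)],
    )
    asg = ClusterAssignment(labels=pd.Series([1, 1, 2], index=data.columns), k=2)
    assert select_medoids(table_from(data), asg)[1] == "lone"


def test_medoid_tie_breaks_lexicographically():
    rng = np.random.default_rng(2)
    base = rng.standard_normal(60)
    # two identical columns: equal mean |r|, lexicographically first wins
    data = pd.DataFrame(
        {"zzz": base, "aaa": base.copy()}, index=[f"P{i}" for i in range(60)]
    )
    asg = ClusterAssignment(labels=pd.Series([1, 1], index=data.columns), k=1)
    assert select_medoids(table_from(data), asg) == ["aaa"]


def test_medoid_invariant_to_affine_rescaling():
    table, truth = latent_feature_table(n_patients=100, n_factors=2, features_per_factor=6, seed=3)
    labels = pd.Series(pd.factorize(truth)[0] + 1, index=truth.index)
    asg = ClusterAssignment(labels=labels, k=2)
    med1 = select_medoids(table, asg)
    scaled = table.data.copy()
    scaled[med1[0]] = scaled[med1[0]] * -42.0 + 7.0
    med2 = select_medoids(table_from(scaled), asg)
    assert med1 == med2


# --- Cox signature --------------------------------------------------------

def test_planted_prognostic_factor_dominates_coefficients():
    table, truth = latent_feature_table(n_patients=250, n_factors=3, seed=4)
    labels = pd.Series(pd.factorize(truth)[0] + 1, index=truth.index)
    asg = ClusterAssignment(labels=labels, k=3)
    medoids = select_medoids(table, asg)
    z = table.data[truth.index[truth == "factor1"]].mean(axis=1)
    clin = survival_from_factor(z, beta=0.9, seed=5)
    clin.index = table.data.index
    model = fit_cox_signature(table, clin, medoids)
    coefs = {m: abs(c) for m, c in model.coefficients.items()}
    factor1_medoid = [m for m in medoids if truth[m] == "factor1"][0]
    assert coefs[factor1_medoid] == max(coefs.values())


def test_evaluation_is_deterministic_and_never_refits():
    table, truth = latent_feature_table(n_patients=150, n_factors=2, features_per_factor=8, seed=6)
    labels = pd.Series(pd.factorize(truth)[0] + 1, index=truth.index)
    asg = ClusterAssignment(labels=labels, k=2)
    medoids = select_medoids(table, asg)
    z = table.data[truth.index[truth == "factor0"]].mean(axis=1)
    clin = survival_from_factor(z, beta=0.8, seed=7)
    clin.index = table.data.index
    model = fit_cox_signature(table, clin, medoids)
    before = dict(model.coefficients)
    ci1 = evaluate_signature(model, table, clin)
    ci2 = evaluate_signature(model, table, clin)
    assert ci1 == ci2
    assert model.coefficients == before


def test_sign_flipped_coefficients_give_complement_ci():
    table, truth = latent_feature_table(n_patients=120, n_factors=2, features_per_factor=6, seed=8)
    labels = pd.Series(pd.factorize(truth)[0] + 1, index=truth.index)
    asg = ClusterAssignment(labels=labels, k=2)
    medoids = select_medoids(table, asg)
    z = table.data[truth.index[truth == "factor0"]].mean(axis=1)
    clin = survival_from_factor(z, beta=0.8, seed=9, censoring=0.0)
    clin.index = table.data.index
    model = fit_cox_signature(table, clin, medoids)
    ci = evaluate_signature(model, table, clin)
    flipped = SignatureModel(
        medoids=model.medoids,
        model_kind="cox",
        coefficients={m: -c for m, c in model.coefficients.items()},
        standardization=model.standardization,
    )
    assert evaluate_signature(flipped, table, clin) == pytest.approx(1 - ci)


def test_train_validation_transfer_and_null():
    train, truth = latent_feature_table(n_patients=200, n_factors=2, features_per_factor=8, seed=10)
    val, _ = latent_feature_table(n_patients=200, n_factors=2, features_per_factor=8, seed=11)
    labels = pd.Series(pd.factorize(truth)[0] + 1, index=truth.index)
    asg = ClusterAssignment(labels=labels, k=2)
    medoids = select_medoids(train, asg)

    def clin_for(table, beta, seed):
        z = table.data[truth.index[truth == "factor0"]].mean(axis=1)
        c = survival_from_factor(z, beta=beta, seed=seed)
        c.index = table.data.index
        return c

    model = fit_cox_signature(train, clin_for(train, 0.8, 12), medoids)
    ci_val = evaluate_signature(model, val, clin_for(val, 0.8, 13))
    assert 0.55 <= ci_val <= 0.8
    null_model = fit_cox_signature(train, clin_for(train, 0.0, 14), medoids)
    ci_null = evaluate_signature(null_model, val, clin_for(val, 0.0, 15))
    assert 0.4 <= ci_null <= 0.6


def test_missing_medoid_column_rejected():
    table, truth = latent_feature_table(n_patients=60, n_factors=2, features_per_factor=4, seed=16)
    labels = pd.Series(pd.factorize(truth)[0] + 1, index=truth.index)
    asg = ClusterAssignment(labels=labels, k=2)
    medoids = select_medoids(table, asg)
    clin = survival_from_factor(table.data.iloc[:, 0], beta=0.5, seed=17)
    clin.index = table.data.index
    model = fit_cox_signature(table, clin, medoids)
    reduced = table_from(table.data.drop(columns=medoids[:1]))
    with pytest.raises(ValueError, match="missing"):
        evaluate_signature(model, reduced, clin)


# --- logistic signatures --------------------------------------------------

def class_outcome_from_factor(z: pd.Series, effect: float, classes, seed: int):
    rng = np.random.default_rng(seed)
    zs = (z - z.mean()) / z.std()
    if len(classes) == 2:
        p = 1 / (1 + np.exp(-effect * zs))
        return np.where(rng.uniform(size=len(z)) < p, classes[1], classes[0])
    score = effect * zs + rng.logistic(size=len(z))
    cuts = np.quantile(score, np.linspace(0, 1, len(classes) + 1)[1:-1])
    return np.array(classes)[np.searchsorted(cuts, score)]


def test_binary_logistic_reduction_and_transfer():
    train, truth = latent_feature_table(n_patients=250, n_factors=2, features_per_factor=8, seed=18)
    val, _ = latent_feature_table(n_patients=250, n_factors=2, features_per_factor=8, seed=19)
    labels = pd.Series(pd.factorize(truth)[0] + 1, index=truth.index)
    asg = ClusterAssignment(labels=labels, k=2)
    medoids = select_medoids(train, asg)

    def clin_for(table, seed):
        z = table.data[truth.index[truth == "factor1"]].mean(axis=1)
        hist = class_outcome_from_factor(z, 1.5, ["adeno", "squamous"], seed)
        return pd.DataFrame(
            {"patient_id": table.data.index, "time": 1.0, "event": 1, "histology": hist}
        ).set_index("patient_id", drop=False)

    model = fit_logistic_signature(train, clin_for(train, 20), medoids, "histology")
    assert model.model_kind == "logistic"
    score_auc = evaluate_signature(model, val, clin_for(val, 21))
    assert score_auc >= 0.6  # planted effect detectable out of sample
    # the factor-1 medoid should dominate the fitted coefficients
    coefs = dict(zip(medoids, map(abs, model.coefficients["model"]["coef"])))
    factor1_medoid = [m for m in medoids if truth[m] == "factor1"][0]
    assert coefs[factor1_medoid] == max(coefs.values())


def test_label_permuted_multiclass_auc_near_half():
    train, truth = latent_feature_table(n_patients=200, n_factors=2, features_per_factor=6, seed=22)
    val, _ = latent_feature_table(n_patients=200, n_factors=2, features_per_factor=6, seed=23)
    labels = pd.Series(pd.factorize(truth)[0] + 1, index=truth.index)
    asg = ClusterAssignment(labels=labels, k=2)
    medoids = select_medoids(train, asg)
    rng = np.random.default_rng(24)

    def null_clin(table, seed):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "patient_id": table.data.index,
                "time": 1.0,
                "event": 1,
                "stage": rng.choice(["I", "II", "III"], len(table.data)),
            }
        ).set_index("patient_id", drop=False)

    model = fit_logistic_signature(train, null_clin(train, 25), medoids, "stage")
    assert model.model_kind == "pairwise_logistic"
    assert len(model.coefficients) == 3  # one model per class pair
    a = evaluate_signature(model, val, null_clin(val, 26))
    assert a == pytest.approx(0.5, abs=0.08)


def test_model_json_round_trip():
    table, truth = latent_feature_table(n_patients=80, n_factors=2, features_per_factor=4, seed=27)
    labels = pd.Series(pd.factorize(truth)[0] + 1, index=truth.index)
    asg = ClusterAssignment(labels=labels, k=2)
    medoids = select_medoids(table, asg)
    clin = survival_from_factor(table.data.iloc[:, 0], beta=0.5, seed=28)
    clin.index = table.data.index
    model = fit_cox_signature(table, clin, medoids)
    restored = SignatureModel.from_json(model.to_json())
    assert restored.medoids == model.medoids
    assert restored.coefficients == model.coefficients
    assert evaluate_signature(restored, table, clin) == evaluate_signature(model, table, clin)
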