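import numpy as np
import pandas as pd
import pytest

from radclust import (
    ClusterAssignment,
    auc,
    benjamini_hochberg,
    cluster_association,
    concordance_index,
    feature_prognosis_screen,
    multiclass_auc,
    performance_category,
)
from radclust.features.extract import FeatureTable
from radclust.phantom import latent_feature_table


def brute_ci(risk, time, event):
    """Oracle: explicit loop with the stated pair convention."""
    n = len(risk)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


def brute_auc(score, label):
    pos = [s for s, l in zip(score, label) if l == 1]
    neg = [s for s, l in zip(score, label) if l == 0]
    total = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return total / (len(pos) * len(neg))


# --- concordance index ----------------------------------------------------

def test_perfect_concordance():
    time = np.array([1.0, 2.0, 3.0, 4.0])
    assert concordance_index(-time, time, np.ones(4, int)) == 1.0


def test_constant_risk_is_half():
    time = np.array([1.0, 2.0, 3.0, 4.0])
    assert concordance_index(np.zeros(4), time, np.ones(4, int)) == 0.5


def test_five_patient_hand_case_matches_oracle():
    time = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
    event = np.array([1, 1, 0, 1, 1])
    risk = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
    assert concordance_index(risk, time, event) == pytest.approx(
        brute_ci(risk, time, event), abs=1e-12
    )


def test_ci_matches_oracle_on_random_censored_data():
    rng = np.random.default_rng(0)
    for trial in range(10):
        n = 20
        time = rng.exponential(5, n).round(1)  # rounding makes occasional ties
        event = rng.integers(0, 2, n)
        event[0] = 1
        risk = rng.normal(size=n).round(2)
        if not ((time[:, None] < time[None, :]) & (event[:, None] == 1)).any():
            continue
        assert concordance_index(risk, time, event) == pytest.approx(
            brute_ci(risk, time, event), abs=1e-10
        )


def test_tied_times_are_incomparable():
    # both event: excluded; the only comparable pair is (t=1 -> t=2)
    time = np.array([1.0, 2.0, 2.0])
    event = np.array([1, 1, 1])
    risk = np.array([3.0, 5.0, 1.0])
    assert concordance_index(risk, time, event) == pytest.approx(0.5)  # one of two pairs


def test_all_censored_raises():
    with pytest.raises(ValueError, match="comparable"):
        concordance_index([1.0, 2.0], [1.0, 2.0], [0, 0])


def test_anticoncordant_complement_without_censoring():
    rng = np.random.default_rng(1)
    time = rng.exponential(3, 15)
    risk = rng.normal(size=15)
    event = np.ones(15, int)
    ci = concordance_index(risk, time, event)
    assert concordance_index(-risk, time, event) == pytest.approx(1 - ci)


def test_ci_agrees_with_lifelines_on_tie_free_data():
    from lifelines.utils import concordance_index as ll_ci

    rng = np.random.default_rng(2)
    time = rng.exponential(5, 50)
    event = rng.integers(0, 2, 50)
    event[:5] = 1
    risk = rng.normal(size=50)
    # lifelines scores "predicted survival" (higher = longer): pass -risk
    assert concordance_index(risk, time, event) == pytest.approx(
        ll_ci(time, -risk, event), abs=1e-12
    )


# --- AUC ------------------------------------------------------------------

def test_auc_examples():
    assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
    assert auc([1, 2, 3, 4], [1, 1, 0, 0]) == 0.0
    assert auc([1, 1, 2, 2], [0, 1, 0, 1]) == 0.5


def test_auc_complement_identity():
    rng = np.random.default_rng(3)
    score = rng.normal(size=30)
    label = rng.integers(0, 2, 30)
    label[:2] = [0, 1]
    assert auc(score, label) == pytest.approx(1 - auc(-score, label))


def test_auc_matches_brute_force_with_ties():
    rng = np.random.default_rng(4)
    for trial in range(10):
        score = rng.integers(0, 5, 20).astype(float)  # heavy ties
        label = rng.integers(0, 2, 20)
        label[:2] = [0, 1]
        assert auc(score, label) == pytest.approx(brute_auc(score, label), abs=1e-10)


def test_auc_null_mean_half():
    rng = np.random.default_rng(5)
    vals = []
    for seed in range(50):
        score = rng.normal(size=100)
        label = rng.permutation([0] * 50 + [1] * 50)
        vals.append(auc(score, label))
    assert np.mean(vals) == pytest.approx(0.5, abs=0.03)


def test_auc_single_class_raises():
    with pytest.raises(ValueError):
        auc([1, 2], [1, 1])


# --- multiclass AUC -------------------------------------------------------

def test_multiclass_reduces_to_auc_for_two_classes():
    rng = np.random.default_rng(6)
    score = rng.normal(size=40)
    label = np.array(["a"] * 20 + ["b"] * 20)
    assert multiclass_auc(score, label) == pytest.approx(
        auc(score, (label == "b").astype(int))
    )


def test_three_ordered_classes_give_one():
    score = np.array([1, 2, 3, 4, 5, 6], dtype=float)
    label = np.array(["A", "A", "B", "B", "C", "C"])
    assert multiclass_auc(score, label) == 1.0


def test_three_class_toy_matches_pairwise_enumeration():
    score = np.array([1, 5, 3, 4, 2, 6], dtype=float)  # two swaps vs perfect
    label = np.array(["A", "A", "B", "B", "C", "C"])
    expected = np.mean(
        [
            brute_auc(score[:4], [0, 0, 1, 1]),  # A vs B
            brute_auc(score[[0, 1, 4, 5]], [0, 0, 1, 1]),  # A vs C
            brute_auc(score[2:], [0, 0, 1, 1]),  # B vs C
        ]
    )
    assert multiclass_auc(score, label) == pytest.approx(expected, abs=1e-10)


# --- BH -------------------------------------------------------------------

def test_bh_hand_ladder():
    q = benjamini_hochberg([0.01, 0.02, 0.04, 0.5])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.5])


def test_bh_monotone_in_p_order():
    rng = np.random.default_rng(7)
    p = rng.uniform(size=60)
    q = benjamini_hochberg(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-15)
    assert np.all(q >= p - 1e-15)
    assert np.all(q <= 1.0)


def test_bh_agrees_with_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(8)
    p = rng.uniform(size=100) ** 2
    q = benjamini_hochberg(p)
    _, q_ref, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(q, q_ref, atol=1e-12)


# --- screens and cluster associations ------------------------------------

def null_clinical(index, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "patient_id": index,
            "time": rng.exponential(10, len(index)),
            "event": rng.integers(0, 2, len(index)) | (np.arange(len(index)) == 0),
            "histology": rng.choice(["adeno", "squamous"], len(index)),
            "stage": rng.choice(["I", "II", "III"], len(index)),
        }
    ).set_index("patient_id", drop=False)


def test_screen_flags_planted_factor_not_noise():
    table, truth = latent_feature_table(n_patients=150, n_factors=2, features_per_factor=10, seed=9)
    rng = np.random.default_rng(10)
    z = table.data[truth.index[truth == "factor0"]].mean(axis=1)
    hazard = 0.05 * np.exp(0.9 * (z - z.mean()) / z.std())
    clin = pd.DataFrame(
        {
            "patient_id": table.data.index,
            "time": rng.exponential(1 / hazard),
            "event": 1,
        }
    ).set_index("patient_id", drop=False)
    res = feature_prognosis_screen(table, clin, n_perm=200, seed=11)
    f0 = truth.index[truth == "factor0"]
    f1 = truth.index[truth == "factor1"]
    assert res.loc[f0, "significant"].mean() >= 0.8
    assert res.loc[f1, "significant"].mean() <= 0.2
    assert np.all(res["q"] >= res["p"] - 1e-15)


def test_screen_null_false_flag_rate_controlled():
    table, _ = latent_feature_table(n_patients=80, n_factors=2, features_per_factor=15, seed=12)
    rates = []
    for seed in range(10):
        clin = null_clinical(table.data.index, seed)
        res = feature_prognosis_screen(table, clin, n_perm=100, seed=seed)
        rates.append(res["significant"].mean())
    assert np.mean(rates) <= 0.05 + 2 * np.std(rates) / np.sqrt(len(rates)) + 0.01


def test_cluster_association_survival_and_categories():
    table, truth = latent_feature_table(n_patients=120, n_factors=2, features_per_factor=8, seed=13)
    labels = pd.Series(pd.factorize(truth)[0] + 1, index=truth.index)
    asg = ClusterAssignment(labels=labels, k=2)
    clin = null_clinical(table.data.index, 14)
    rep = cluster_association(table, clin, asg, outcome="survival", n_perm=50, seed=15)
    assert set(rep.index) == {1, 2}
    assert ((rep["statistic"] >= 0) & (rep["statistic"] <= 1)).all()
    assert (rep["category"] == rep["statistic"].map(performance_category)).all()


def test_cluster_association_singleton_cluster_mean_is_feature_stat():
    table, _ = latent_feature_table(n_patients=60, n_factors=2, features_per_factor=2, seed=16)
    names = list(table.data.columns)
    labels = pd.Series([1] + [2] * (len(names) - 1), index=names)
    asg = ClusterAssignment(labels=labels, k=2)
    clin = null_clinical(table.data.index, 17)
    rep = cluster_association(table, clin, asg, outcome="survival", n_perm=10, seed=18)
    expected = concordance_index(
        table.data[names[0]].to_numpy(), clin["time"].to_numpy(), clin["event"].to_numpy()
    )
    assert rep.loc[1, "statistic"] == pytest.approx(expected)


def test_cluster_association_multiclass_outcome():
    table, truth = latent_feature_table(n_patients=90, n_factors=2, features_per_factor=5, seed=19)
    labels = pd.Series(pd.factorize(truth)[0] + 1, index=truth.index)
    asg = ClusterAssignment(labels=labels, k=2)
    clin = null_clinical(table.data.index, 20)
    rep = cluster_association(table, clin, asg, outcome="stage", n_perm=30, seed=21)
    assert ((rep["p"] > 0) & (rep["p"] <= 1)).all()


def test_mean_ci_category_example():
    assert np.mean([0.55, 0.60, 0.65]) == pytest.approx(0.60)
    assert performance_category(0.60) == "moderate"
    assert performance_category(0.59) == "poor"
    assert performance_category(0.75) == "high"


def test_null_cluster_pvalues_roughly_uniform():
    table, truth = latent_feature_table(n_patients=60, n_factors=2, features_per_factor=6, seed=22)
    labels = pd.Series(pd.factorize(truth)[0] + 1, index=truth.index)
    asg = ClusterAssignment(labels=labels, k=2)
    ps = []
    for seed in range(30):
        clin = null_clinical(table.data.index, 100 + seed)
        rep = cluster_association(table, clin, asg, outcome="survival", n_perm=50, seed=seed)
        ps.append(rep.loc[1 + seed % 2, "p"])
    from scipy.stats import kstest

    assert kstest(ps, "uniform").pvalue > 0.01
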