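"""Univariable and cluster-level clinical associations of radiomic features.

Survival associations use Harrell's concordance index (CI): over patient
pairs in which the patient with the strictly smaller observed time had the
event, the fraction where the higher risk score belongs to the earlier
failure (tied scores count 1/2; tied times are incomparable). Categorical
associations use the rank-based AUC; parameters with more than two levels
use the mean of pairwise two-class AUCs.

Features are never sign-flipped: a CI or AUC below 0.5 is reported as-is.
Permutation significance is one-sided (association above chance) with the
add-one estimator; the per-feature survival screen is corrected across
features by Benjamini-Hochberg.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .consensus import ClusterAssignment
from .features.extract import FeatureTable

__all__ = [
    "concordance_index",
    "auc",
    "multiclass_auc",
    "benjamini_hochberg",
    "feature_prognosis_screen",
    "cluster_association",
    "performance_category",
]


# --- elementary statistics ------------------------------------------------

def _comparable_pairs(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices (i, j) with time_i < time_j and event_i = 1."""
    t = time[:, None] < time[None, :]
    ok = t & (event[:, None] == 1)
    return np.nonzero(ok)


def concordance_index(risk, time, event) -> float:
    """Harrell's CI of a risk score against right-censored survival."""
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    i, j = _comparable_pairs(time, event)
    if len(i) == 0:
        raise ValueError("no comparable pair (e.g. all patients censored)")
    higher = risk[i] > risk[j]
    tied = risk[i] == risk[j]
    return float((higher.sum() + 0.5 * tied.sum()) / len(i))


def auc(score, label) -> float:
    """Rank-based two-class AUC: P(score_positive > score_negative), ties 1/2."""
    score = np.asarray(score, dtype=float)
    label = np.asarray(label)
    classes = np.unique(label)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    pos = label == classes[1]
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(score)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def multiclass_auc(score, label) -> float:
    """Mean pairwise two-class AUC over all unordered class pairs.

    For each pair the class that sorts later is the positive class, which
    makes the two-class case reduce exactly to :func:`auc`.
    """
    score = np.asarray(score, dtype=float)
    label = np.asarray(label)
    classes = sorted(np.unique(label).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    aucs = []
    for a, b in itertools.combinations(classes, 2):
        sel = (label == a) | (label == b)
        aucs.append(auc(score[sel], label[sel]))
    return float(np.mean(aucs))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def performance_category(value: float) -> str:
    """Qualitative prognostic/predictive label."""
    if value >= 0.75:
        return "high"
    if value >= 0.6:
        return "moderate"
    return "poor"


# --- vectorized helpers ---------------------------------------------------

def _ci_columns(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Harrell CI of every column of x at once (same pair convention)."""
    i, j = _comparable_pairs(time, event)
    if len(i) == 0:
        raise ValueError("no comparable pair")
    higher = x[i] > x[j]
    tied = x[i] == x[j]
    return (higher.sum(axis=0) + 0.5 * tied.sum(axis=0)) / len(i)


def _auc_columns(x: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """Rank-based AUC of every column against a binary indicator."""
    n1 = int(positive.sum())
    n0 = len(positive) - n1
    ranks = np.apply_along_axis(rankdata, 0, x)
    u = ranks[positive].sum(axis=0) - n1 * (n1 + 1) / 2
    return u / (n1 * n0)


def _multiclass_auc_columns(x: np.ndarray, label: np.ndarray) -> np.ndarray:
    classes = sorted(np.unique(label).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    parts = []
    for a, b in itertools.combinations(classes, 2):
        sel = (label == a) | (label == b)
        parts.append(_auc_columns(x[sel], (label[sel] == b)))
    return np.mean(parts, axis=0)


def _check_alignment(table: FeatureTable, clinical: pd.DataFrame) -> pd.DataFrame:
    missing = [pid for pid in table.data.index if pid not in clinical.index]
    if missing:
        raise ValueError(f"clinical rows missing for patients: {missing[:5]}")
    return clinical.loc[table.data.index]


# --- screens and cluster-level reports ------------------------------------

def feature_prognosis_screen(
    table: FeatureTable,
    clinical: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature CI with permutation p and BH q across all features.

    The permutation null permutes the patients' outcomes (equivalently the
    feature rows) jointly for all features; the flag marks q < 0.05 together
    with CI > 0.5 (no orientation flipping).
    """
    clin = _check_alignment(table, clinical)
    x = table.data.to_numpy(dtype=float)
    time = clin["time"].to_numpy(dtype=float)
    event = clin["event"].to_numpy(dtype=int)
    ci = _ci_columns(x, time, event)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(x.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(len(time))
        ci_null = _ci_columns(x[perm], time, event)
        exceed += ci_null >= ci - 1e-12
    p = (1 + exceed) / (1 + n_perm)
    q = benjamini_hochberg(p)
    return pd.DataFrame(
        {
            "ci": ci,
            "p": p,
            "q": q,
            "significant": (q < 0.05) & (ci > 0.5),
        },
        index=table.data.columns,
    )


def cluster_association(
    table: FeatureTable,
    clinical: pd.DataFrame,
    assignment: ClusterAssignment,
    outcome: str = "survival",
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cluster mean CI (survival) or mean AUC (categorical outcome).

    The permutation null permutes the outcome over patients, recomputes every
    feature's statistic and re-averages within each cluster; p is one-sided
    with the add-one estimator. Output rows are clusters with columns
    ``statistic`` (mean CI or mean AUC), ``p`` and ``category``.
    """
    clin = _check_alignment(table, clinical)
    x = table.data.to_numpy(dtype=float)
    labels = assignment.labels.reindex(table.data.columns).to_numpy()
    if np.any(pd.isna(labels)):
        raise ValueError("assignment does not cover all features")
    clusters = list(range(1, assignment.k + 1))
    members = {c: np.flatnonzero(labels == c) for c in clusters}
    if any(len(v) == 0 for v in members.values()):
        raise ValueError("empty cluster in assignment")

    if outcome == "survival":
        time = clin["time"].to_numpy(dtype=float)
        event = clin["event"].to_numpy(dtype=int)

        def stat(xp: np.ndarray) -> np.ndarray:
            return _ci_columns(xp, time, event)

    else:
        lab = clin[outcome].to_numpy()
        if len(np.unique(lab)) < 2:
            raise ValueError(f"outcome {outcome!r} has a single level")

        def stat(xp: np.ndarray) -> np.ndarray:
            return _multiclass_auc_columns(xp, lab)

    per_feature = stat(x)
    obs = {c: float(per_feature[members[c]].mean()) for c in clusters}
    rng = np.random.default_rng(seed)
    exceed = {c: 0 for c in clusters}
    for _ in range(n_perm):
        perm = rng.permutation(x.shape[0])
        null_stat = stat(x[perm])
        for c in clusters:
            if null_stat[members[c]].mean() >= obs[c] - 1e-12:
                exceed[c] += 1
    return pd.DataFrame(
        {
            "statistic": [obs[c] for c in clusters],
            "p": [(1 + exceed[c]) / (1 + n_perm) for c in clusters],
            "category": [performance_category(obs[c]) for c in clusters],
            "n_features": [len(members[c]) for c in clusters],
        },
        index=pd.Index(clusters, name="cluster"),
    )
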