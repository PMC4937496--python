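"""Medoid selection and multivariable radiomic signatures.

A cluster's medoid is its single most representative feature — the one with
the highest mean absolute Pearson correlation to the other cluster members.
The medoids of a clustering form the signature's variables: a multivariable
Cox proportional-hazards model for survival, or logistic regression for
categorical parameters (one model per class pair when there are more than
two levels, aggregated by the pairwise multiclass AUC).

Medoid columns are standardized with training-cohort mean/sd before fitting;
the standardization transfers with the model so evaluation on a validation
cohort never refits anything.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .clinical import auc, concordance_index
from .consensus import ClusterAssignment
from .features.extract import FeatureTable

__all__ = [
    "SignatureModel",
    "select_medoids",
    "fit_cox_signature",
    "fit_logistic_signature",
    "evaluate_signature",
]


@dataclass
class SignatureModel:
    """A fitted multivariable signature over cluster medoids."""

    medoids: list[str]
    model_kind: str  # "cox" | "logistic" | "pairwise_logistic"
    coefficients: dict  # cox: name -> beta; logistic: per (pair) model
    standardization: dict[str, tuple[float, float]]  # name -> (mean, sd)
    outcome: str = "survival"
    training_meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "medoids": self.medoids,
            "model_kind": self.model_kind,
            "coefficients": self.coefficients,
            "standardization": {k: list(v) for k, v in self.standardization.items()},
            "outcome": self.outcome,
            "training_meta": self.training_meta,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        d = json.loads(text)
        return cls(
            medoids=d["medoids"],
            model_kind=d["model_kind"],
            coefficients=d["coefficients"],
            standardization={k: tuple(v) for k, v in d["standardization"].items()},
            outcome=d.get("outcome", "survival"),
            training_meta=d.get("training_meta", {}),
        )

    def design_matrix(self, table: FeatureTable) -> np.ndarray:
        missing = [m for m in self.medoids if m not in table.data.columns]
        if missing:
            raise ValueError(f"medoid columns missing from table: {missing}")
        cols = []
        for m in self.medoids:
            mu, sd = self.standardization[m]
            cols.append((table.data[m].to_numpy(dtype=float) - mu) / sd)
        return np.column_stack(cols)


def select_medoids(table: FeatureTable, assignment: ClusterAssignment) -> list[str]:
    """Per cluster, the feature with the highest mean |r| to its cluster mates.

    Singleton clusters contribute their only feature; ties break to the
    lexicographically first name. Constant features cannot be medoids.
    """
    medoids = []
    for c in range(1, assignment.k + 1):
        names = assignment.members(c)
        if len(names) == 1:
            medoids.append(names[0])
            continue
        sub = table.data[names].to_numpy(dtype=float)
        sd = sub.std(axis=0)
        keep = sd > 0
        if not keep.all():
            dropped = [n for n, k in zip(names, keep) if not k]
            warnings.warn(f"constant features excluded from medoid candidacy: {dropped}")
            names = [n for n, k in zip(names, keep) if k]
            sub = sub[:, keep]
        r = np.abs(np.corrcoef(sub, rowvar=False))
        np.fill_diagonal(r, np.nan)
        mean_r = np.nanmean(r, axis=0)
        best = np.nanmax(mean_r)
        candidates = sorted(n for n, v in zip(names, mean_r) if v >= best - 1e-12)
        medoids.append(candidates[0])
    return medoids


def _standardization(table: FeatureTable, medoids: list[str]) -> dict[str, tuple[float, float]]:
    out = {}
    for m in medoids:
        col = table.data[m].to_numpy(dtype=float)
        sd = float(col.std(ddof=0))
        if sd == 0:
            raise ValueError(f"medoid {m!r} is constant in the training cohort")
        out[m] = (float(col.mean()), sd)
    return out


def fit_cox_signature(
    table: FeatureTable,
    clinical: pd.DataFrame,
    medoids: list[str],
    penalizer: float = 0.0,
    ridge_fallback: float = 0.1,
) -> SignatureModel:
    """Multivariable Cox PH fit on the standardized medoid columns."""
    clin = clinical.loc[table.data.index]
    n_events = int(clin["event"].sum())
    if n_events < 10:
        warnings.warn(f"only {n_events} events; Cox coefficients may be unstable")
    std = _standardization(table, medoids)
    df = pd.DataFrame(
        {m: (table.data[m] - std[m][0]) / std[m][1] for m in medoids},
        index=table.data.index,
    )
    df["time"] = clin["time"].to_numpy(dtype=float)
    df["event"] = clin["event"].to_numpy(dtype=int)
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        warnings.warn("Cox fit did not converge; refitting with a ridge penalty")
        cph = CoxPHFitter(penalizer=ridge_fallback)
        cph.fit(df, duration_col="time", event_col="event")
    coefs = {m: float(cph.params_[m]) for m in medoids}
    if not all(np.isfinite(list(coefs.values()))):
        raise RuntimeError(f"non-finite Cox coefficients: {coefs}")
    return SignatureModel(
        medoids=list(medoids),
        model_kind="cox",
        coefficients=coefs,
        standardization=std,
        outcome="survival",
        training_meta={"n_patients": len(df), "n_events": n_events, "penalizer": penalizer},
    )


def _fit_binary_logistic(x: np.ndarray, y: np.ndarray, fallback_c: float = 1.0):
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
            model.fit(x, y)
        except (ConvergenceWarning, Exception):
            warnings.simplefilter("default", ConvergenceWarning)
            warnings.warn("logistic fit unstable (separation?); using an L2-regularized fit")
            model = LogisticRegression(C=fallback_c, solver="lbfgs", max_iter=2000)
            model.fit(x, y)
    return model


def fit_logistic_signature(
    table: FeatureTable,
    clinical: pd.DataFrame,
    medoids: list[str],
    outcome: str,
) -> SignatureModel:
    """Logistic signature for a categorical parameter.

    Two classes: a single logistic model. More classes: one binary logistic
    model per unordered class pair (evaluated later by pairwise AUC).
    """
    clin = clinical.loc[table.data.index]
    labels = clin[outcome].astype(str).to_numpy()
    classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError(f"outcome {outcome!r} has a single level")
    std = _standardization(table, medoids)
    x = np.column_stack(
        [(table.data[m].to_numpy(dtype=float) - std[m][0]) / std[m][1] for m in medoids]
    )
    coefficients: dict = {}
    if len(classes) == 2:
        y = (labels == classes[1]).astype(int)
        model = _fit_binary_logistic(x, y)
        coefficients["model"] = {
            "classes": classes,
            "coef": model.coef_[0].tolist(),
            "intercept": float(model.intercept_[0]),
        }
        kind = "logistic"
    else:
        for a, b in itertools.combinations(classes, 2):
            sel = (labels == a) | (labels == b)
            y = (labels[sel] == b).astype(int)
            model = _fit_binary_logistic(x[sel], y)
            coefficients[f"{a}|{b}"] = {
                "classes": [a, b],
                "coef": model.coef_[0].tolist(),
                "intercept": float(model.intercept_[0]),
            }
        kind = "pairwise_logistic"
    return SignatureModel(
        medoids=list(medoids),
        model_kind=kind,
        coefficients=coefficients,
        standardization=std,
        outcome=outcome,
        training_meta={"n_patients": len(labels), "classes": classes},
    )


def evaluate_signature(model: SignatureModel, table: FeatureTable, clinical: pd.DataFrame) -> float:
    """Score a fitted signature on a cohort without refitting.

    Cox models return the Harrell CI of the linear predictor; logistic models
    return the (pairwise multiclass) AUC of the fitted scores.
    """
    clin = clinical.loc[table.data.index]
    x = model.design_matrix(table)
    if model.model_kind == "cox":
        lp = x @ np.array([model.coefficients[m] for m in model.medoids])
        return concordance_index(
            lp, clin["time"].to_numpy(dtype=float), clin["event"].to_numpy(dtype=int)
        )
    labels = clin[model.outcome].astype(str).to_numpy()
    if model.model_kind == "logistic":
        spec = model.coefficients["model"]
        score = x @ np.array(spec["coef"]) + spec["intercept"]
        sel = np.isin(labels, spec["classes"])
        return auc(score[sel], labels[sel])
    # pairwise logistic: each pair scored by its own model, mean pairwise AUC
    aucs = []
    for spec in model.coefficients.values():
        a, b = spec["classes"]
        sel = (labels == a) | (labels == b)
        if len(np.unique(labels[sel])) < 2:
            continue
        score = x[sel] @ np.array(spec["coef"]) + spec["intercept"]
        aucs.append(auc(score, labels[sel]))
    if not aucs:
        raise ValueError("no class pair present in the evaluation cohort")
    return float(np.mean(aucs))
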