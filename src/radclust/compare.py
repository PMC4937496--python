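"""Agreement between feature clusterings: Rand statistic and Jaccard overlap.

The Rand statistic scores two clusterings of the same feature set by the
fraction of feature pairs on which they agree (clustered together in both,
or apart in both). Its significance comes from a one-sided permutation test
that shuffles one clustering's labels over the features (preserving cluster
sizes). The Jaccard index scores the overlap of two individual clusters as
member sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import ClusterAssignment, ConsensusResult, hierarchical_clusters
from .features.extract import FeatureTable

__all__ = [
    "PairConcordanceCounts",
    "rand_statistic",
    "rand_permutation_test",
    "validate_external",
    "jaccard_overlap",
    "overlap_matrix",
    "overlap_category",
]


@dataclass(frozen=True)
class PairConcordanceCounts:
    """Counts over all unordered feature pairs: together/apart in (P, C)."""

    ss: int  # together in both
    sd: int  # together in C only
    ds: int  # together in P only
    dd: int  # apart in both

    def __post_init__(self) -> None:
        n_pairs = self.ss + self.sd + self.ds + self.dd
        # SS+SD+DS+DD must be C(n,2) for some integer n
        n = (1 + np.sqrt(1 + 8 * n_pairs)) / 2
        if n_pairs < 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(f"pair counts {self} do not sum to a C(n,2)")

    @property
    def total(self) -> int:
        return self.ss + self.sd + self.ds + self.dd


def _aligned_labels(p: ClusterAssignment, c: ClusterAssignment) -> tuple[np.ndarray, np.ndarray]:
    if set(p.labels.index) != set(c.labels.index):
        diff = set(p.labels.index) ^ set(c.labels.index)
        raise ValueError(f"clusterings cover different feature sets; difference: {sorted(diff)}")
    order = list(p.labels.index)
    return p.labels.to_numpy(), c.labels.reindex(order).to_numpy()


def _pairs(x: np.ndarray) -> int:
    return int((x * (x - 1) // 2).sum())


def _rand_from_labels(lp: np.ndarray, lc: np.ndarray) -> tuple[float, PairConcordanceCounts]:
    # contingency-table identity: SS = sum C(n_ij,2); together-in-P = sum C(a_i,2)
    n = len(lp)
    kp, kc = int(lp.max()) + 1, int(lc.max()) + 1
    contingency = np.bincount(lp * kc + lc, minlength=kp * kc)
    ss = _pairs(contingency)
    together_p = _pairs(np.bincount(lp))
    together_c = _pairs(np.bincount(lc))
    ds = together_p - ss
    sd = together_c - ss
    total = n * (n - 1) // 2
    counts = PairConcordanceCounts(ss=ss, sd=sd, ds=ds, dd=total - ss - sd - ds)
    return (counts.ss + counts.dd) / counts.total, counts


def rand_statistic(
    p: ClusterAssignment, c: ClusterAssignment
) -> tuple[float, PairConcordanceCounts]:
    """RS = (SS + DD) / C(n,2) over all unordered feature pairs."""
    lp, lc = _aligned_labels(p, c)
    return _rand_from_labels(lp, lc)


def rand_permutation_test(
    p: ClusterAssignment, c: ClusterAssignment, n_perm: int = 1000, seed: int = 0
) -> float:
    """One-sided permutation p-value for RS (agreement above chance).

    Null: C's label vector shuffled over features, preserving cluster sizes.
    Add-one estimator: p = (1 + #{RS_null >= RS_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    lp, lc = _aligned_labels(p, c)
    rs_obs, _ = _rand_from_labels(lp, lc)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        rs_null, _ = _rand_from_labels(lp, rng.permutation(lc))
        if rs_null >= rs_obs - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def validate_external(
    reference: ConsensusResult | ClusterAssignment,
    external_table: FeatureTable,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Cluster an external cohort at the reference K and score the agreement.

    The external cohort gets plain hierarchical clustering (no resampling) at
    the reference number of clusters; RS and its permutation p are returned.
    """
    ref = reference.assignment if isinstance(reference, ConsensusResult) else reference
    missing = set(ref.labels.index) ^ set(external_table.data.columns)
    if missing:
        raise ValueError(f"feature sets differ: {sorted(missing)}")
    external = hierarchical_clusters(external_table, ref.k)
    rs, counts = rand_statistic(ref, external)
    pval = rand_permutation_test(ref, external, n_perm=n_perm, seed=seed)
    return {
        "rand_statistic": rs,
        "counts": counts,
        "p_value": pval,
        "n_perm": n_perm,
        "seed": seed,
        "external_assignment": external,
    }


def jaccard_overlap(a, b) -> float:
    """|A n B| / |A u B| of two feature sets."""
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("both sets are empty")
    return len(a & b) / len(a | b)


def overlap_category(j: float) -> str:
    if j >= 0.75:
        return "high"
    if j >= 0.5:
        return "moderate"
    return "poor"


def overlap_matrix(a: ClusterAssignment, b: ClusterAssignment) -> pd.DataFrame:
    """Pairwise Jaccard of every cluster of `a` against every cluster of `b`."""
    rows = {}
    for ca in range(1, a.k + 1):
        rows[ca] = {
            cb: jaccard_overlap(a.members(ca), b.members(cb)) for cb in range(1, b.k + 1)
        }
    return pd.DataFrame(rows).T
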