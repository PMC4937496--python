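"""End-to-end orchestration: simulate -> extract -> cluster -> validate ->
associate -> signature, writing every artifact to an output directory.

The configuration is a plain dataclass loadable from YAML; every stochastic
stage draws from a seed recorded in the run log, so re-running a config
reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as rio
from .clinical import cluster_association, feature_prognosis_screen
from .compare import validate_external
from .consensus import ConsensusConfig, consensus_cluster
from .features.extract import extract_cohort
from .image import DiscretizationSpec
from .phantom import PhantomSpec, generate_cohort
from .signature import evaluate_signature, fit_cox_signature, select_medoids

logger = logging.getLogger("radclust")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Full pipeline configuration; seeds are mandatory for stochastic stages."""

    out_dir: str = "radclust_run"
    n_patients: int = 40
    grid_shape: tuple[int, int, int] = (44, 44, 44)
    radii_range: tuple[float, float] = (5.0, 8.5)
    n_bins: int = 32
    n_iterations: int = 1000
    subsample_fraction: float = 0.8
    k_candidates: tuple[int, ...] = tuple(range(2, 9))
    delta_area_threshold: float = 0.1
    n_perm: int = 1000
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if isinstance(cfg.grid_shape, list):
            cfg.grid_shape = tuple(cfg.grid_shape)
        if isinstance(cfg.radii_range, list):
            cfg.radii_range = tuple(cfg.radii_range)
        if isinstance(cfg.k_candidates, list):
            cfg.k_candidates = tuple(cfg.k_candidates)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole analysis on a simulated training/validation cohort pair.

    Returns a report dict; all artifacts (feature CSVs, assignment CSV,
    consensus matrix, association CSVs, signature JSON, run log) land in
    ``config.out_dir``.
    """
    if config.seed is None:
        raise ValueError("config.seed is required: stochastic stages refuse to run unseeded")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    disc = DiscretizationSpec(n_bins=config.n_bins)
    report: dict = {"config": asdict(config)}

    def stage(name):
        logger.info("stage=%s config_seed=%s", name, config.seed)

    try:
        stage("simulate")
        train = generate_cohort(
            PhantomSpec(
                n_patients=config.n_patients,
                grid_shape=tuple(config.grid_shape),
                radii_range=tuple(config.radii_range),
                seed=config.seed,
            )
        )
        val = generate_cohort(
            PhantomSpec(
                n_patients=config.n_patients,
                grid_shape=tuple(config.grid_shape),
                radii_range=tuple(config.radii_range),
                seed=config.seed + 1,
            )
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    try:
        stage("extract")
        table_train = extract_cohort(train.images, train.masks, train.patient_ids, disc)
        table_val = extract_cohort(val.images, val.masks, val.patient_ids, disc)
        rio.write_feature_table(table_train, out / "features_train.csv")
        rio.write_feature_table(table_val, out / "features_validation.csv")
        rio.write_clinical(train.clinical, out / "clinical_train.csv")
        rio.write_clinical(val.clinical, out / "clinical_validation.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'extract' failed: {exc}") from exc

    try:
        stage("cluster")
        ccfg = ConsensusConfig(
            n_iterations=config.n_iterations,
            subsample_fraction=config.subsample_fraction,
            k_candidates=tuple(config.k_candidates),
            delta_area_threshold=config.delta_area_threshold,
            seed=config.seed,
        )
        result = consensus_cluster(table_train, ccfg)
        rio.write_assignment_csv(result.assignment, out / "clusters_train.csv")
        np.savetxt(
            out / "consensus_matrix.csv", result.consensus[result.chosen_k], delimiter=","
        )
        report["chosen_k"] = result.chosen_k
        report["cluster_consensus"] = result.cluster_consensus
        report["cluster_correlation"] = result.cluster_correlation
    except Exception as exc:
        raise RuntimeError(f"stage 'cluster' failed: {exc}") from exc

    try:
        stage("validate")
        validation = validate_external(
            result, table_val, n_perm=config.n_perm, seed=config.seed
        )
        report["validation_rand_statistic"] = validation["rand_statistic"]
        report["validation_p"] = validation["p_value"]
        rio.write_assignment_csv(
            validation["external_assignment"], out / "clusters_validation.csv"
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'validate' failed: {exc}") from exc

    try:
        stage("associate")
        screen = feature_prognosis_screen(
            table_val, val.clinical, n_perm=config.n_perm, seed=config.seed
        )
        screen.to_csv(out / "feature_prognosis.csv", index_label="feature")
        assoc = cluster_association(
            table_train,
            train.clinical,
            result.assignment,
            outcome="survival",
            n_perm=config.n_perm,
            seed=config.seed,
        )
        assoc.to_csv(out / "cluster_survival_association.csv")
        report["n_significant_features"] = int(screen["significant"].sum())
    except Exception as exc:
        raise RuntimeError(f"stage 'associate' failed: {exc}") from exc

    try:
        stage("signature")
        medoids = select_medoids(table_train, result.assignment)
        model = fit_cox_signature(table_train, train.clinical, medoids)
        (out / "signature_cox.json").write_text(model.to_json())
        report["medoids"] = medoids
        report["signature_train_ci"] = evaluate_signature(model, table_train, train.clinical)
        report["signature_validation_ci"] = evaluate_signature(model, table_val, val.clinical)
    except Exception as exc:
        raise RuntimeError(f"stage 'signature' failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
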