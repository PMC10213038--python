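"""End-to-end orchestration: simulate -> features -> cluster -> label ->
validate, from a single configuration with derived per-stage seeds and a
provenance manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import average_subject_membership, fit_model, profiles_frame, validity_scan
from .cohort import CohortConfig, covariates_frame, generate_baseline_behavior, \
    generate_cohort, generate_feature_cohort
from .features import PreprocessParams, features_frame
from .labeling import compute_deltas, label_responders
from .montage import feature_names
from .validation import baseline_structure_check, clustering_holdout

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "runs/latest"
    seed: int = 0
    simulate: bool = True
    simulate_waveforms: bool = False   # full EEG synthesis vs feature fast path
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    algorithm: str = "spectral"
    k: int = 4
    m: float = 1.7
    n_components: int | None = None
    alpha: float = 0.05
    outlier_sd: float = 2.5
    scan_validity: bool = False
    holdout_frac: float = 0.8
    holdout_folds: int = 20
    features_csv: str | None = None    # to run on user-supplied features
    behavior_csv: str | None = None
    covariates_csv: str | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2 (a single cluster has no structure)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        pre = PreprocessParams(**raw.pop("preprocess", {}))
        return cls(cohort=cohort, preprocess=pre, **raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed, so every
    stage is independently reproducible."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, writing per-stage CSV/JSON outputs plus a
    provenance manifest to ``config.out_dir``. Returns a result dictionary
    with the in-memory stage outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "package_version": __version__,
        "global_seed": config.seed,
        "stage_seeds": {},
        "rows": {},
    }

    # --- simulate / load -------------------------------------------------
    truths = None
    if config.simulate:
        sim_seed = stage_seed(config.seed, "simulate")
        manifest["stage_seeds"]["simulate"] = sim_seed
        if config.simulate_waveforms:
            truths, recordings, behavior = generate_cohort(config.cohort, sim_seed)
            features = features_frame(recordings, config.preprocess)
        else:
            truths, features, behavior = generate_feature_cohort(config.cohort, sim_seed)
        covariates = covariates_frame(truths)
        baseline = generate_baseline_behavior(truths, sim_seed, config.cohort)
    else:
        if not (config.features_csv and config.behavior_csv and config.covariates_csv):
            raise ValueError("stage 'load': features/behavior/covariates CSVs required "
                             "when simulate is false")
        features = pd.read_csv(config.features_csv)
        behavior = pd.read_csv(config.behavior_csv)
        covariates = pd.read_csv(config.covariates_csv)
        baseline = None
    features.to_csv(out / "features.csv", index=False)
    behavior.to_csv(out / "behavior.csv", index=False)
    covariates.to_csv(out / "covariates.csv", index=False)
    manifest["rows"]["features"] = len(features)
    manifest["rows"]["behavior"] = len(behavior)

    # --- cluster ----------------------------------------------------------
    cl_seed = stage_seed(config.seed, "cluster")
    manifest["stage_seeds"]["cluster"] = cl_seed
    X = features[feature_names()].to_numpy()
    if config.scan_validity:
        scan = validity_scan(X, seed=cl_seed, m=config.m)
        scan.to_csv(out / "validity.csv", index=False)
    model = fit_model(X, config.algorithm, config.k, seed=cl_seed,
                      m=config.m, n_components=config.n_components)
    memberships = pd.DataFrame(model.memberships,
                               columns=[f"u_{c+1}" for c in range(config.k)])
    memberships.insert(0, "session_index", features["session_index"].to_numpy())
    memberships.insert(0, "subject_id", features["subject_id"].to_numpy())
    memberships.to_csv(out / "memberships.csv", index=False)
    subject_m = average_subject_membership(model.memberships,
                                           list(features["subject_id"]))
    profiles = profiles_frame(subject_m)
    profiles.to_csv(out / "profiles.csv", index=False)
    pd.DataFrame(model.prototypes, columns=feature_names()).to_csv(
        out / "prototypes.csv", index=False)
    manifest["rows"]["profiles"] = len(profiles)

    # --- label ------------------------------------------------------------
    correlations, labels = label_responders(
        profiles, behavior, covariates,
        alpha=config.alpha, outlier_sd=config.outlier_sd)
    correlations.to_csv(out / "correlations.csv", index=False)
    labels_payload = [dataclasses.asdict(l) for l in labels]
    (out / "labels.json").write_text(json.dumps(labels_payload, indent=2))
    manifest["rows"]["correlations"] = len(correlations)
    manifest["rows"]["labels"] = len(labels_payload)

    # --- validate ---------------------------------------------------------
    va_seed = stage_seed(config.seed, "validate")
    manifest["stage_seeds"]["validate"] = va_seed
    holdout = clustering_holdout(X, list(features["subject_id"]),
                                 config.algorithm, config.k,
                                 frac=config.holdout_frac,
                                 folds=config.holdout_folds,
                                 seed=va_seed, m=config.m)
    validation_report = {
        "clustering_holdout": {
            "fraction": holdout.fraction,
            "folds": holdout.folds,
            "mean_agreement": holdout.mean_agreement,
            "agreement": holdout.agreement,
        }
    }
    if baseline is not None:
        base = baseline_structure_check(baseline, profiles)
        base.to_csv(out / "baseline_check.csv", index=False)
        validation_report["baseline_check_rejections"] = int(
            (base["p"] <= config.alpha).sum())
    (out / "validation.json").write_text(json.dumps(validation_report, indent=2))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return dict(truths=truths, features=features, behavior=behavior,
                covariates=covariates, model=model, profiles=profiles,
                correlations=correlations, labels=labels,
                validation=validation_report, manifest=manifest)
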