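"""Robustness procedures for the clustering and correlation stages.

Two hold-out schemes mirror the pipeline's stability checks:

* **Clustering hold-out**: repeatedly fit the clustering on a subject-level
  train split (default 80% of subjects), assign each held-out session to the
  nearest train prototype, and measure agreement with a full-data fit after
  optimal label matching, together with internal validity metrics on train
  and combined assignments.
* **Correlation hold-out**: repeatedly (default M=1000) re-run the partial
  Spearman correlation and rank-sum test on subject-level subsamples at 80,
  60 and 40% of the cohort, summarizing the distribution of coefficients and
  p-values and the mean distance of the subsample points to the full-data
  least-squares fit line.

All subsampling moves whole subjects (every session of a subject travels
together), stratified by stimulation group, and is deterministic for a
fixed seed.

A baseline structure check (Kruskal-Wallis across clusters on pre-treatment
behavioral values) verifies that the phenotype clusters carry no baseline
performance differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_score
from sklearn.metrics.pairwise import euclidean_distances

from .cluster import fit_model, match_labels
from .labeling import partial_spearman, remove_outliers, wilcoxon_members_vs_rest


@dataclass
class HoldoutReport:
    fraction: float
    folds: int
    train_silhouette: list[float]
    combined_silhouette: list[float]
    agreement: list[float]      # per fold, vs full-data fit

    @property
    def mean_agreement(self) -> float:
        return float(np.mean(self.agreement))


@dataclass
class RobustnessSummary:
    fraction: float
    M: int
    rho_mean: float
    rho_sd: float
    corr_p_mean: float
    corr_p_sd: float
    wilcoxon_p_mean: float
    wilcoxon_p_sd: float
    fit_distance_mean: float
    fit_distance_sd: float


def nearest_prototype(X: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    """1-based label of the closest prototype (Euclidean) per sample."""
    d = euclidean_distances(np.asarray(X, float), np.asarray(prototypes, float))
    return d.argmin(axis=1) + 1


def clustering_holdout(X: np.ndarray, subject_ids: list[str], algorithm: str,
                       k: int, frac: float = 0.8, folds: int = 20,
                       seed: int = 0, m: float = 1.7) -> HoldoutReport:
    """Subject-level train/test hold-out of the clustering stage."""
    X = np.asarray(X, float)
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    sids = np.asarray(subject_ids)
    unique = pd.unique(sids)
    n_train = int(round(frac * len(unique)))
    if n_train >= len(unique):
        raise ValueError("empty test split")
    full = fit_model(X, algorithm, k, seed=seed, m=m)
    full_labels = full.hard_labels

    rng = np.random.default_rng(seed)
    report = HoldoutReport(frac, folds, [], [], [])
    for _ in range(folds):
        train_subjects = set(rng.choice(unique, size=n_train, replace=False))
        train_mask = np.array([s in train_subjects for s in sids])
        if train_mask.sum() < k:
            raise ValueError("train split smaller than k")
        model = fit_model(X[train_mask], algorithm, k, seed=seed, m=m)
        test_labels = nearest_prototype(X[~train_mask], model.prototypes)
        combined = np.empty(len(X), dtype=int)
        combined[train_mask] = model.hard_labels
        combined[~train_mask] = test_labels
        aligned = match_labels(full_labels, combined)
        report.agreement.append(float((aligned[~train_mask]
                                       == full_labels[~train_mask]).mean()))
        if len(np.unique(model.hard_labels)) >= 2:
            report.train_silhouette.append(
                float(silhouette_score(X[train_mask], model.hard_labels)))
        if len(np.unique(combined)) >= 2:
            report.combined_silhouette.append(float(silhouette_score(X, combined)))
    return report


def correlation_holdout(
    membership: np.ndarray,
    deltas: np.ndarray,
    covariates: np.ndarray | None,
    groups: np.ndarray | None = None,
    fractions: tuple[float, ...] = (0.8, 0.6, 0.4),
    M: int = 1000,
    seed: int = 0,
    hard_members: np.ndarray | None = None,
    outlier_sd: float = float("inf"),
) -> list[RobustnessSummary]:
    """Repeated subject-level hold-out of the correlation/Wilcoxon analysis
    for one cluster x endpoint.

    ``membership``: the cluster's averaged membership per subject;
    ``deltas``: the endpoint's active-sham difference per subject;
    ``hard_members``: boolean membership of the cluster's hard assignment
    (required for the rank-sum part). Distance to the full fit is the mean
    absolute vertical residual of the subsample's points to the full-data
    degree-1 least-squares line of delta vs membership."""
    membership = np.asarray(membership, float)
    deltas = np.asarray(deltas, float)
    n = len(membership)
    q = 0 if covariates is None else np.asarray(covariates).reshape(n, -1).shape[1]
    keep = remove_outliers(deltas, outlier_sd)
    membership, deltas = membership[keep], deltas[keep]
    covariates = None if covariates is None else np.asarray(covariates).reshape(n, -1)[keep]
    groups = np.zeros(len(membership)) if groups is None else np.asarray(groups)[keep]
    hard = None if hard_members is None else np.asarray(hard_members, bool)[keep]
    n = len(membership)

    slope, intercept = np.polyfit(membership, deltas, 1)
    rng = np.random.default_rng(seed)
    summaries = []
    for frac in fractions:
        if frac > 1 or int(np.floor(frac * n)) < q + 3:
            raise ValueError(f"fraction {frac} leaves too few subjects")
        rhos, cps, wps, dists = [], [], [], []
        for _ in range(M):
            if frac == 1.0:
                idx = np.arange(n)
            else:
                idx = _stratified_subsample(groups, frac, rng)
            Z = None if covariates is None else covariates[idx]
            rho, p = partial_spearman(membership[idx], deltas[idx], Z)
            rhos.append(rho)
            cps.append(p)
            if hard is not None and hard[idx].any() and (~hard[idx]).any():
                _, wp = wilcoxon_members_vs_rest(deltas[idx][hard[idx]],
                                                 deltas[idx][~hard[idx]])
                wps.append(wp)
            dists.append(float(np.mean(np.abs(
                deltas[idx] - (slope * membership[idx] + intercept)))))
        summaries.append(RobustnessSummary(
            fraction=frac, M=M,
            rho_mean=float(np.nanmean(rhos)), rho_sd=float(np.nanstd(rhos)),
            corr_p_mean=float(np.nanmean(cps)), corr_p_sd=float(np.nanstd(cps)),
            wilcoxon_p_mean=float(np.mean(wps)) if wps else float("nan"),
            wilcoxon_p_sd=float(np.std(wps)) if wps else float("nan"),
            fit_distance_mean=float(np.mean(dists)),
            fit_distance_sd=float(np.std(dists)),
        ))
    return summaries


def _stratified_subsample(groups: np.ndarray, frac: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Without-replacement subject subsample preserving group proportions."""
    idx_parts = []
    for g in pd.unique(groups):
        pool = np.where(groups == g)[0]
        take = max(1, int(round(frac * len(pool))))
        idx_parts.append(rng.choice(pool, size=min(take, len(pool)), replace=False))
    return np.sort(np.concatenate(idx_parts))


def baseline_structure_check(baseline: pd.DataFrame,
                             hard_clusters: pd.DataFrame,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis test across clusters on pre-treatment behavioral
    values, per endpoint. Clusters with fewer than 2 subjects are excluded
    (noted in the report); with fewer than 2 usable clusters the endpoint is
    skipped with a message."""
    merged = baseline.merge(hard_clusters[["subject_id", "hard_cluster"]],
                            on="subject_id")
    rows = []
    for (task, metric), ep in merged.groupby(["task", "metric"]):
        samples, excluded = [], []
        for c, grp in ep.groupby("hard_cluster"):
            if len(grp) >= 2:
                samples.append(grp["value"].to_numpy())
            else:
                excluded.append(int(c))
        if len(samples) < 2:
            rows.append(dict(task=task, metric=metric, statistic=np.nan,
                             p=np.nan, n_clusters=len(samples),
                             excluded_clusters=excluded,
                             message="skipped: fewer than 2 usable clusters"))
            continue
        stat, p = stats.kruskal(*samples)
        rows.append(dict(task=task, metric=metric, statistic=float(stat),
                         p=float(p), n_clusters=len(samples),
                         excluded_clusters=excluded,
                         message="" if p > alpha else "baseline structure detected"))
    return pd.DataFrame(rows)
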