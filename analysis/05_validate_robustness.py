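"""Robustness of the clustering and correlation stages.

1. Subject-level 80/20 clustering hold-out: nearest-prototype assignment of
   held-out sessions, agreement with the full-data fit.
2. Repeated correlation hold-out (M = 200) at 80/60/40% of subjects for the
   planted positive-responder endpoint: distribution of rho and p-values.
3. Baseline structure check: Kruskal-Wallis across clusters on simulated
   pre-treatment task performance (no structure planted).

Reads results/cohort/ and results/clustering/, writes results/validation/.
"""

import json
from pathlib import Path

import pandas as pd

from eegpheno.cohort import CohortConfig, generate_baseline_behavior, \
    generate_feature_cohort
from eegpheno.labeling import compute_deltas
from eegpheno.montage import feature_names
from eegpheno.validation import (
    baseline_structure_check,
    clustering_holdout,
    correlation_holdout,
)

IN_COHORT = Path("results/cohort")
IN_CLUST = Path("results/clustering")
OUT = Path("results/validation")
SEED = 20260927


def main() -> None:
    features = pd.read_csv(IN_COHORT / "features.csv")
    behavior = pd.read_csv(IN_COHORT / "behavior.csv")
    covariates = pd.read_csv(IN_COHORT / "covariates.csv")
    profiles = pd.read_csv(IN_CLUST / "profiles_spectral.csv")
    X = features[feature_names()].to_numpy()
    OUT.mkdir(parents=True, exist_ok=True)
    report = {}

    holdout = clustering_holdout(X, list(features.subject_id), "spectral", 4,
                                 frac=0.8, folds=20, seed=SEED)
    report["clustering_holdout"] = dict(
        fraction=holdout.fraction, folds=holdout.folds,
        mean_agreement=holdout.mean_agreement)
    print(f"clustering hold-out (80% train, 20 folds): mean test agreement "
          f"{holdout.mean_agreement:.3f}")

    # correlation hold-out on the planted positive endpoint, pooled subjects
    deltas = compute_deltas(behavior)
    ep = deltas[(deltas.task == "N-Back") & (deltas.metric == "accuracy")
                & (deltas.concurrency == "non-concurrent")]
    merged = ep.merge(profiles, on="subject_id").merge(covariates, on="subject_id")
    merged["sex_code"] = (merged.sex == "male").astype(float)
    # cluster with the strongest positive accuracy association
    best_c = max(range(1, 5), key=lambda c: merged[f"u_{c}"].corr(merged.delta))
    Z = merged[["age", "sex_code", "iq", "handedness"]].to_numpy()
    out = correlation_holdout(
        merged[f"u_{best_c}"].to_numpy(), merged.delta.to_numpy(), Z,
        merged.group.to_numpy(), fractions=(0.8, 0.6, 0.4), M=200, seed=SEED,
        hard_members=(merged.hard_cluster == best_c).to_numpy())
    report["correlation_holdout"] = [s.__dict__ for s in out]
    print(f"correlation hold-out for cluster {best_c} (N-Back accuracy, "
          f"non-concurrent), M=200:")
    for s in out:
        print(f"  {int(s.fraction * 100):3d}%: rho {s.rho_mean:+.3f} "
              f"(SD {s.rho_sd:.3f}), corr p {s.corr_p_mean:.4f} "
              f"(SD {s.corr_p_sd:.4f}), fit-line distance "
              f"{s.fit_distance_mean:.4f} (SD {s.fit_distance_sd:.4f})")

    cfg = CohortConfig()
    truths, _, _ = generate_feature_cohort(cfg, seed=SEED)
    baseline = generate_baseline_behavior(truths, SEED, cfg)
    base = baseline_structure_check(baseline, profiles)
    base.to_csv(OUT / "baseline_check.csv", index=False)
    n_reject = int((base.p <= 0.05).sum())
    print(f"baseline structure check: {n_reject} of {len(base)} endpoints "
          f"reject at alpha=0.05 (no baseline structure planted)")
    report["baseline_rejections"] = n_reject

    (OUT / "robustness.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
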