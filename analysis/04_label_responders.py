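"""Label each phenotype cluster as positive / negative / non-responder.

Per condition family (stimulation group x task concurrency): active-sham
deltas per endpoint, +/-2.5 SD outlier removal, partial Spearman correlation
of subject-averaged memberships with deltas (adjusted for age, sex, IQ,
handedness), BH-FDR within the family, sign-rule draft verdicts, and
rank-sum Wilcoxon confirmation of members vs the rest.

Reads results/cohort/ and results/clustering/, writes results/labeling/.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from eegpheno.labeling import label_responders

IN_COHORT = Path("results/cohort")
IN_CLUST = Path("results/clustering")
OUT = Path("results/labeling")


def main() -> None:
    profiles = pd.read_csv(IN_CLUST / "profiles_spectral.csv")
    behavior = pd.read_csv(IN_COHORT / "behavior.csv")
    covariates = pd.read_csv(IN_COHORT / "covariates.csv")
    correlations, labels = label_responders(profiles, behavior, covariates,
                                            alpha=0.05, outlier_sd=2.5)
    OUT.mkdir(parents=True, exist_ok=True)
    correlations.to_csv(OUT / "correlations.csv", index=False)
    (OUT / "labels.json").write_text(
        json.dumps([dataclasses.asdict(l) for l in labels], indent=2))

    n_sig = int((correlations.draft_verdict != "non").sum())
    print(f"{len(correlations)} correlations tested; {n_sig} significant drafts")
    if labels:
        print("confirmed responder labels (cluster, condition, endpoint, "
              "verdict, rho, wilcoxon p_adj):")
        for l in labels:
            print(f"  cluster {l.cluster} | {l.condition} | {l.endpoint} | "
                  f"{l.verdict} | rho={l.rho:+.3f} | p={l.wilcoxon_p_adj:.4f}")
    else:
        print("no confirmed responder labels")


if __name__ == "__main__":
    main()
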