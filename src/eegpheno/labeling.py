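"""Cluster response labeling: covariate-adjusted correlation of cluster
memberships with active-sham behavioral differences, FDR correction, and
rank-sum confirmation.

For every experimental condition (stimulation group x task concurrency) and
every behavioral endpoint (task x metric), the per-subject active-minus-sham
performance difference is correlated with the subject's averaged cluster
membership using a partial Spearman correlation adjusted for age, sex, IQ
and handedness. P-values are corrected per condition family with the
Benjamini-Hochberg step-up procedure. A significant correlation labels the
cluster a *positive* responder when it implies better performance under
active stimulation (higher accuracy or faster RT) and *negative* for the
reverse; the draft label is confirmed only if a rank-sum Wilcoxon test of
the cluster's members against all remaining subjects (BH-corrected within
the condition) is also significant, otherwise the cluster is a
*non-responder* for that endpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("age", "sex", "iq", "handedness")


@dataclass
class ResponderLabel:
    cluster: int
    condition: str          # "<group>/<concurrency>"
    endpoint: str           # "<task> <metric>"
    verdict: str            # 'positive' | 'negative' | 'non'
    rho: float
    corr_p_adj: float
    wilcoxon_p_adj: float | None = None


# ---------------------------------------------------------------------------
# Deltas and outlier handling
# ---------------------------------------------------------------------------

def compute_deltas(records: pd.DataFrame) -> pd.DataFrame:
    """Active-minus-sham difference per subject x task x metric x
    concurrency. Subjects missing either arm are excluded from that endpoint
    (logged)."""
    required = {"subject_id", "task", "metric", "stimulation", "concurrency", "value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"behavioral table missing columns: {sorted(missing)}")
    wide = records.pivot_table(
        index=["subject_id", "task", "metric", "concurrency"],
        columns="stimulation", values="value", aggfunc="mean",
    )
    for arm in ("active", "sham"):
        if arm not in wide.columns:
            raise ValueError(f"no {arm!r} records present")
    incomplete = wide["active"].isna() | wide["sham"].isna()
    if incomplete.any():
        logger.info("excluding %d subject-endpoints missing an arm", int(incomplete.sum()))
        wide = wide[~incomplete]
    out = wide.reset_index()
    out["delta"] = out["active"] - out["sham"]
    return out[["subject_id", "task", "metric", "concurrency", "delta"]]


def remove_outliers(values: np.ndarray, c: float = 2.5) -> np.ndarray:
    """Retain-mask: values outside mean +/- c*SD (sample SD of this
    endpoint's deltas) are dropped in a single pass. A zero SD keeps all."""
    values = np.asarray(values, float)
    if len(values) < 3 or not np.isfinite(c):
        return np.ones(len(values), bool)
    sd = values.std(ddof=1)
    if sd == 0:
        return np.ones(len(values), bool)
    mu = values.mean()
    return np.abs(values - mu) <= c * sd


# ---------------------------------------------------------------------------
# Partial Spearman correlation
# ---------------------------------------------------------------------------

def partial_spearman(x: np.ndarray, y: np.ndarray,
                     Z: np.ndarray | None = None) -> tuple[float, float]:
    """Spearman correlation of ``x`` and ``y`` partialled for covariates.

    Both variables are rank-transformed (average ranks for ties), then
    residualized by least squares on an intercept plus the covariate matrix
    ``Z``; rho is the Pearson correlation of the residuals and the p-value
    comes from the t distribution with n - 2 - q degrees of freedom (q
    covariates, two-sided). With no covariates this reduces exactly to the
    ordinary Spearman correlation. Returns (nan, nan) when either variable
    is constant after ranking."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    q = 0 if Z is None or np.size(Z) == 0 else np.atleast_2d(np.asarray(Z, float).T).T.shape[1]
    if n < q + 3:
        raise ValueError(f"need at least {q + 3} observations, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan"), float("nan")
    if q:
        Zm = np.column_stack([np.ones(n), np.asarray(Z, float).reshape(n, -1)])
    else:
        Zm = np.ones((n, 1))
    coef_x, *_ = np.linalg.lstsq(Zm, rx, rcond=None)
    coef_y, *_ = np.linalg.lstsq(Zm, ry, rcond=None)
    ex = rx - Zm @ coef_x
    ey = ry - Zm @ coef_y
    denom = np.sqrt((ex @ ex) * (ey @ ey))
    if denom == 0:
        return float("nan"), float("nan")
    rho = float(np.clip((ex @ ey) / denom, -1.0, 1.0))
    df = n - 2 - q
    if df <= 0:
        return rho, float("nan")
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags.

    adjusted p_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1; a test is
    significant when its adjusted p-value is <= q."""
    p = np.asarray(pvals, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([]), np.array([], bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj, adj <= q


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum confirmation
# ---------------------------------------------------------------------------

def wilcoxon_members_vs_rest(member_values: np.ndarray,
                             rest_values: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum (Mann-Whitney) test of a cluster's deltas against
    all remaining subjects' deltas. The exact null distribution is
    enumerated when the combined sample has at most 12 observations and no
    ties; otherwise the tie-corrected normal approximation is used."""
    member_values = np.asarray(member_values, float)
    rest_values = np.asarray(rest_values, float)
    if len(member_values) == 0 or len(rest_values) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([member_values, rest_values])
    exact = len(combined) <= 12 and len(np.unique(combined)) == len(combined)
    res = stats.mannwhitneyu(member_values, rest_values, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------

def _verdict(metric: str, rho: float) -> str:
    """Sign rule: positive responders show higher accuracy and smaller RTs
    under active stimulation; a positive RT correlation marks a negative
    responder."""
    if metric == "accuracy":
        return "positive" if rho > 0 else "negative"
    return "negative" if rho > 0 else "positive"


def label_clusters(correlations: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Draft verdicts from adjusted correlations (before Wilcoxon
    confirmation); non-significant correlations are 'non'."""
    out = correlations.copy()
    verdicts = []
    for _, row in out.iterrows():
        if np.isfinite(row["p_adj"]) and row["p_adj"] <= alpha:
            verdicts.append(_verdict(row["metric"], row["rho"]))
        else:
            verdicts.append("non")
    out["draft_verdict"] = verdicts
    return out


def label_responders(
    profiles: pd.DataFrame,
    behavior: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    outlier_sd: float = 2.5,
    exclude_subjects: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, list[ResponderLabel]]:
    """Full labeling stage.

    ``profiles``: subject_id, u_1..u_k, hard_cluster (from clustering).
    ``behavior``: long table of task values per stimulation arm.
    ``covariates``: subject_id, group, age, sex, iq, handedness.

    Returns the correlation table (one row per condition x cluster x
    endpoint, with raw and BH-adjusted p-values per condition family) and
    the confirmed responder labels.
    """
    profiles = profiles[~profiles["subject_id"].isin(exclude_subjects)]
    deltas = compute_deltas(behavior)
    cov = covariates.set_index("subject_id")
    k = sum(c.startswith("u_") for c in profiles.columns)
    merged = deltas.merge(profiles, on="subject_id").merge(
        covariates[["subject_id", "group", *COVARIATE_COLUMNS]], on="subject_id"
    )
    merged["sex_code"] = (merged["sex"] == "male").astype(float)

    corr_rows = []
    for (group, concurrency), cond_df in merged.groupby(["group", "concurrency"]):
        family = []
        for (task, metric), ep_df in cond_df.groupby(["task", "metric"]):
            vals = ep_df["delta"].to_numpy()
            keep = remove_outliers(vals, outlier_sd)
            ep_df = ep_df[keep]
            if len(ep_df) < len(COVARIATE_COLUMNS) + 3:
                logger.info("skipping %s/%s %s %s: too few subjects",
                            group, concurrency, task, metric)
                continue
            Z = np.column_stack([
                ep_df["age"], ep_df["sex_code"], ep_df["iq"], ep_df["handedness"],
            ])
            for c in range(1, k + 1):
                rho, p = partial_spearman(ep_df[f"u_{c}"].to_numpy(),
                                          ep_df["delta"].to_numpy(), Z)
                family.append(dict(
                    group=group, concurrency=concurrency, task=task,
                    metric=metric, cluster=c, rho=rho, p_raw=p,
                    n_subjects=len(ep_df),
                ))
        if not family:
            continue
        fam = pd.DataFrame(family)
        finite = np.isfinite(fam["p_raw"].to_numpy())
        adj = np.full(len(fam), np.nan)
        if finite.any():
            adj[finite], _ = bh_fdr(fam["p_raw"].to_numpy()[finite], alpha)
        fam["p_adj"] = adj
        logger.info("condition %s/%s: %d corrections", group, concurrency,
                    int(finite.sum()))
        corr_rows.append(fam)
    correlations = pd.concat(corr_rows, ignore_index=True)
    drafts = label_clusters(correlations, alpha)

    # Wilcoxon confirmation, only for clusters with a significant correlation,
    # BH-corrected within each condition family.
    labels: list[ResponderLabel] = []
    for (group, concurrency), fam in drafts.groupby(["group", "concurrency"]):
        sig = fam[fam["draft_verdict"] != "non"]
        tests = []
        for _, row in sig.iterrows():
            ep_df = merged[(merged["group"] == group)
                           & (merged["concurrency"] == concurrency)
                           & (merged["task"] == row["task"])
                           & (merged["metric"] == row["metric"])]
            keep = remove_outliers(ep_df["delta"].to_numpy(), outlier_sd)
            ep_df = ep_df[keep]
            members = ep_df[ep_df["hard_cluster"] == row["cluster"]]["delta"].to_numpy()
            rest = ep_df[ep_df["hard_cluster"] != row["cluster"]]["delta"].to_numpy()
            if len(members) == 0 or len(rest) == 0:
                continue
            _, p = wilcoxon_members_vs_rest(members, rest)
            tests.append((row, p))
        if tests:
            adj, _ = bh_fdr(np.array([p for _, p in tests]), alpha)
            logger.info("condition %s/%s: %d Wilcoxon corrections",
                        group, concurrency, len(tests))
        for i, (row, _p) in enumerate(tests):
            confirmed = adj[i] <= alpha
            labels.append(ResponderLabel(
                cluster=int(row["cluster"]),
                condition=f"{group}/{concurrency}",
                endpoint=f"{row['task']} {row['metric']}",
                verdict=row["draft_verdict"] if confirmed else "non",
                rho=float(row["rho"]),
                corr_p_adj=float(row["p_adj"]),
                wilcoxon_p_adj=float(adj[i]),
            ))
    return drafts, labels


def confirm_responders(drafts: pd.DataFrame,
                       wilcoxon_p_adj: dict[tuple, float],
                       alpha: float = 0.05) -> list[ResponderLabel]:
    """Combine draft verdicts with adjusted Wilcoxon p-values: a verdict is
    retained only when both adjusted tests pass, otherwise 'non'."""
    labels = []
    for _, row in drafts.iterrows():
        if row["draft_verdict"] == "non":
            continue
        key = (row["group"], row["concurrency"], row["task"], row["metric"],
               row["cluster"])
        wp = wilcoxon_p_adj.get(key)
        verdict = row["draft_verdict"] if wp is not None and wp <= alpha else "non"
        labels.append(ResponderLabel(
            cluster=int(row["cluster"]),
            condition=f"{row['group']}/{row['concurrency']}",
            endpoint=f"{row['task']} {row['metric']}",
            verdict=verdict, rho=float(row["rho"]),
            corr_p_adj=float(row["p_adj"]), wilcoxon_p_adj=wp,
        ))
    return labels
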