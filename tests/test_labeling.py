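"""Response labeling: deltas, outlier filter, partial Spearman, BH-FDR,
rank-sum confirmation, and the sign rules for responder verdicts."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from eegpheno.labeling import (
    ResponderLabel,
    bh_fdr,
    compute_deltas,
    confirm_responders,
    label_clusters,
    partial_spearman,
    remove_outliers,
    wilcoxon_members_vs_rest,
)


def behavior_row(sid, task, metric, stim, conc, value):
    return dict(subject_id=sid, task=task, metric=metric, stimulation=stim,
                concurrency=conc, value=value)


class TestDeltas:
    def test_simple_difference(self):
        records = pd.DataFrame([
            behavior_row("S1", "Flanker", "accuracy", "active", "concurrent", 0.9),
            behavior_row("S1", "Flanker", "accuracy", "sham", "concurrent", 0.8),
        ])
        out = compute_deltas(records)
        assert len(out) == 1
        assert out.delta.iloc[0] == pytest.approx(0.1)

    def test_equal_arms_zero(self):
        records = pd.DataFrame([
            behavior_row("S1", "CPT", "rt", "active", "non-concurrent", 450.0),
            behavior_row("S1", "CPT", "rt", "sham", "non-concurrent", 450.0),
        ])
        assert compute_deltas(records).delta.iloc[0] == 0.0

    def test_three_subject_table_matches_hand_subtraction(self):
        rng = np.random.default_rng(0)
        rows, expected = [], {}
        for sid in ("S1", "S2", "S3"):
            a, s = rng.uniform(0.5, 1.0, 2)
            rows.append(behavior_row(sid, "N-Back", "accuracy", "active", "concurrent", a))
            rows.append(behavior_row(sid, "N-Back", "accuracy", "sham", "concurrent", s))
            expected[sid] = a - s
        out = compute_deltas(pd.DataFrame(rows)).set_index("subject_id")
        for sid, d in expected.items():
            assert out.loc[sid, "delta"] == pytest.approx(d)

    def test_missing_arm_excluded(self):
        records = pd.DataFrame([
            behavior_row("S1", "Flanker", "rt", "active", "concurrent", 400.0),
            behavior_row("S2", "Flanker", "rt", "active", "concurrent", 420.0),
            behavior_row("S2", "Flanker", "rt", "sham", "concurrent", 410.0),
        ])
        out = compute_deltas(records)
        assert list(out.subject_id) == ["S2"]


class TestOutliers:
    def test_all_equal_kept(self):
        keep = remove_outliers(np.full(10, 3.3))
        assert keep.all()

    def test_single_extreme_dropped(self):
        vals = np.array([0.0] * 9 + [100.0])
        keep = remove_outliers(vals, 2.5)
        # mean 10, sample SD 31.6; only 100 lies outside mean +/- 2.5 SD
        np.testing.assert_array_equal(keep, [True] * 9 + [False])

    def test_infinite_threshold_identity(self):
        vals = np.array([0.0, 5.0, 1e6])
        assert remove_outliers(vals, np.inf).all()


class TestPartialSpearman:
    def test_no_covariates_equals_spearman(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p = partial_spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert abs(rho - ref.statistic) < 1e-12

    def test_perfect_monotone_association(self):
        x = np.arange(12.0)
        rho, p = partial_spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_matches_explicit_rank_residual_oracle(self):
        """n=8 with one covariate: rank both variables, project out [1, z]
        by explicit normal equations, correlate residuals."""
        rng = np.random.default_rng(2)
        x, y, z = rng.normal(size=8), rng.normal(size=8), rng.normal(size=8)
        rho, p = partial_spearman(x, y, z)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        Z = np.column_stack([np.ones(8), z])
        H = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
        ex, ey = rx - H @ rx, ry - H @ ry
        expected = (ex @ ey) / np.sqrt((ex @ ex) * (ey @ ey))
        assert rho == pytest.approx(expected, abs=1e-12)
        t = expected * np.sqrt(5 / (1 - expected**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 5), abs=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = pd.DataFrame(dict(x=rng.normal(size=40), y=rng.normal(size=40),
                               a=rng.normal(size=40), b=rng.normal(size=40)))
        df["y"] += 0.5 * df["x"] + 0.3 * df["a"]
        # pingouin rank-transforms the covariates as well; feeding ranked
        # covariates makes the two estimators coincide
        Zr = stats.rankdata(df[["a", "b"]].to_numpy(), axis=0)
        rho, p = partial_spearman(df.x.to_numpy(), df.y.to_numpy(), Zr)
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["a", "b"],
                                    method="spearman")
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=15), rng.normal(size=15)
        z = rng.normal(size=15)
        rho1, _ = partial_spearman(x, y, z)
        rho2, _ = partial_spearman(np.exp(x), y**3 + 2 * y, z)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_constant_input_flagged(self):
        rho, p = partial_spearman(np.ones(10), np.arange(10.0))
        assert np.isnan(rho) and np.isnan(p)


def reference_step_up(pvals, q):
    """Textbook BH: find the largest i with p_(i) <= i*q/m; reject 1..i."""
    m = len(pvals)
    order = np.argsort(pvals)
    reject = np.zeros(m, bool)
    cutoff = -1
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * q / m:
            cutoff = rank
    if cutoff > 0:
        reject[order[:cutoff]] = True
    return reject


class TestBHFDR:
    def test_worked_sequence(self):
        adj, sig = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, 0.04)
        assert sig.all()

    def test_single_p_unchanged(self):
        adj, _ = bh_fdr(np.array([0.37]))
        assert adj[0] == pytest.approx(0.37)

    def test_all_ones(self):
        adj, sig = bh_fdr(np.ones(6))
        np.testing.assert_array_equal(adj, 1.0)
        assert not sig.any()

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=9)
        perm = rng.permutation(9)
        adj1, _ = bh_fdr(p)
        adj2, _ = bh_fdr(p[perm])
        np.testing.assert_allclose(adj1[perm], adj2)

    @pytest.mark.parametrize("m", [1, 2, 3, 4, 5])
    def test_matches_step_up_enumeration(self, m):
        """Significance flags agree with the textbook step-up rule on a
        dense grid of p-value combinations for every family size m <= 5."""
        grid = [0.001, 0.01, 0.04, 0.2, 0.9]
        for combo in itertools.product(grid, repeat=m):
            p = np.array(combo)
            _, sig = bh_fdr(p, q=0.05)
            np.testing.assert_array_equal(sig, reference_step_up(p, 0.05))

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(5)
        p = rng.uniform(size=24)
        adj, sig = bh_fdr(p)
        rej, padj, *_ = sm.multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adj, padj, atol=1e-12)
        np.testing.assert_array_equal(sig, rej)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_dominates_raw(self, pvals):
        p = np.array(pvals)
        adj, _ = bh_fdr(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()


class TestWilcoxon:
    def test_extreme_split_exact_p(self):
        # one-sided tail 1/C(6,3) = 1/20 -> two-sided p = 0.1
        stat, p = wilcoxon_members_vs_rest(np.array([1.0, 2, 3]),
                                           np.array([4.0, 5, 6]))
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = wilcoxon_members_vs_rest(np.array([1.0, 2, 3]),
                                        np.array([1.0, 2, 3]))
        assert p == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        """Exact p equals enumeration of all C(n, m) rank splits."""
        rng = np.random.default_rng(6)
        for _ in range(5):
            x = rng.normal(size=4)
            y = rng.normal(size=6)
            _, p = wilcoxon_members_vs_rest(x, y)
            combined = np.concatenate([x, y])
            ranks = stats.rankdata(combined)
            obs = ranks[:4].sum()
            n = len(combined)
            mean_r = 4 * (n + 1) / 2
            count = 0
            total = comb(n, 4)
            for subset in itertools.combinations(range(n), 4):
                s = ranks[list(subset)].sum()
                if abs(s - mean_r) >= abs(obs - mean_r) - 1e-9:
                    count += 1
            assert p == pytest.approx(count / total, abs=1e-12)

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            wilcoxon_members_vs_rest(np.array([]), np.array([1.0]))


class TestVerdicts:
    def make_corr(self, metric, rho, p_adj):
        return pd.DataFrame([dict(group="B", concurrency="concurrent",
                                  task="Flanker", metric=metric, cluster=1,
                                  rho=rho, p_raw=p_adj / 2, p_adj=p_adj,
                                  n_subjects=20)])

    def test_significant_positive_accuracy(self):
        out = label_clusters(self.make_corr("accuracy", 0.4, 0.01))
        assert out.draft_verdict.iloc[0] == "positive"

    def test_significant_positive_rt_is_negative_responder(self):
        out = label_clusters(self.make_corr("rt", 0.4, 0.01))
        assert out.draft_verdict.iloc[0] == "negative"

    def test_non_significant_is_non(self):
        out = label_clusters(self.make_corr("accuracy", 0.4, 0.2))
        assert out.draft_verdict.iloc[0] == "non"

    def test_confirmation_requires_both_tests(self):
        drafts = label_clusters(self.make_corr("accuracy", 0.4, 0.01))
        key = ("B", "concurrent", "Flanker", "accuracy", 1)
        kept = confirm_responders(drafts, {key: 0.02})
        assert kept[0].verdict == "positive"
        demoted = confirm_responders(drafts, {key: 0.2})
        assert demoted[0].verdict == "non"
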