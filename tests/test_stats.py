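import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from eistrat.calibration import simulate_evaluation
from eistrat.stats import (
    InferenceError,
    auc_variance,
    bh_fdr,
    compare_groups,
    delong_paired,
    fisher_combine,
    gee_binomial,
    pool_fixed_effect,
    roc_auc,
)


def _pair_count_auc(scores, labels):
    """Exhaustive concordant-pair count over positive × negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_equals_exhaustive_pair_counting(self, data):
        n = data.draw(st.integers(4, 50))
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        scores = data.draw(
            st.lists(
                st.floats(0, 1, allow_nan=False, width=32), min_size=n, max_size=n
            )
        )
        assert roc_auc(scores, labels) == pytest.approx(_pair_count_auc(scores, labels))

    def test_requires_both_classes(self):
        with pytest.raises(InferenceError):
            roc_auc([0.1, 0.9], [1, 1])


class TestDeLong:
    def test_identical_perfect_scorers_give_null_result(self):
        scores = [0.9, 0.8, 0.1, 0.2]
        labels = [1, 1, 0, 0]
        res = delong_paired(scores, scores, labels)
        assert (res.auc_a, res.auc_b, res.delta, res.p) == (1.0, 1.0, 0.0, 1.0)

    def test_se_close_to_paired_bootstrap(self):
        rng = np.random.default_rng(31)
        n = 30
        labels = np.array([1] * 15 + [0] * 15)
        sa = rng.normal(labels, 1.0)
        sb = 0.6 * sa + rng.normal(0.6 * labels, 0.8)
        res = delong_paired(sa, sb, labels)

        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            yb = labels[idx]
            if yb.min() == yb.max():
                continue
            boots.append(roc_auc(sa[idx], yb) - roc_auc(sb[idx], yb))
        boot_se = float(np.std(boots, ddof=1))
        assert res.se == pytest.approx(boot_se, rel=0.15)

    def test_delta_and_ci_consistent(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        sa, sb = rng.random(40), rng.random(40)
        res = delong_paired(sa, sb, labels)
        assert res.delta == pytest.approx(roc_auc(sa, labels) - roc_auc(sb, labels))
        assert res.ci == pytest.approx((res.delta - 1.96 * res.se, res.delta + 1.96 * res.se), rel=1e-3)
        assert abs(res.delta) <= 1.0

    def test_single_auc_variance_matches_hanley_mcneil(self):
        """On exponential scores the Hanley–McNeil closed form is accurate."""
        rng = np.random.default_rng(11)
        m = n = 300
        scores = np.concatenate([rng.exponential(2.0, m), rng.exponential(1.0, n)])
        labels = np.array([1] * m + [0] * n)
        a = roc_auc(scores, labels)
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        hm = (a * (1 - a) + (m - 1) * (q1 - a * a) + (n - 1) * (q2 - a * a)) / (m * n)
        assert auc_variance(scores, labels) == pytest.approx(hm, rel=0.15)


class TestFisher:
    def test_all_ones_combine_to_one(self):
        stat, df, p = fisher_combine([1.0, 1.0, 1.0])
        assert (stat, df, p) == (0.0, 6, 1.0)

    def test_single_p_identity(self):
        _, _, p = fisher_combine([0.0421])
        assert p == pytest.approx(0.0421)

    def test_five_repetitions_match_chi_square_oracle(self):
        stat, df, p = fisher_combine([0.05] * 5)
        assert stat == pytest.approx(-2 * 5 * np.log(0.05))
        assert df == 10
        assert p == pytest.approx(float(sps.chi2.sf(stat, 10)))

    def test_permutation_invariant(self):
        ps = [0.01, 0.2, 0.7, 0.04]
        assert fisher_combine(ps) == fisher_combine(ps[::-1])

    def test_zero_p_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            _, _, p = fisher_combine([0.0, 0.5])
        assert 0.0 < p < 1e-100


class TestPooling:
    def test_equal_ses_reduce_to_mean(self):
        est, se, _ = pool_fixed_effect([0.1, 0.3], [0.05, 0.05])
        assert est == pytest.approx(0.2)

    def test_single_repetition_unchanged(self):
        est, se, ci = pool_fixed_effect([0.07], [0.02])
        assert (est, se) == pytest.approx((0.07, 0.02))
        assert ci == pytest.approx((0.07 - 1.96 * 0.02, 0.07 + 1.96 * 0.02), rel=1e-3)

    def test_hand_computed_weights(self):
        est, se, _ = pool_fixed_effect([0.02, 0.04], [0.01, 0.02])
        w = np.array([10000.0, 2500.0])
        assert est == pytest.approx((0.02 * w[0] + 0.04 * w[1]) / w.sum())
        assert se == pytest.approx(w.sum() ** -0.5)

    def test_permutation_invariant(self):
        a = pool_fixed_effect([0.01, 0.05, -0.02], [0.01, 0.03, 0.02])
        b = pool_fixed_effect([-0.02, 0.01, 0.05], [0.02, 0.01, 0.03])
        assert a[0] == pytest.approx(b[0]) and a[1] == pytest.approx(b[1])

    def test_zero_ses_excluded_or_error(self):
        with pytest.warns(UserWarning):
            est, _, _ = pool_fixed_effect([0.1, 0.9], [0.05, 0.0])
        assert est == pytest.approx(0.1)
        with pytest.raises(InferenceError):
            pool_fixed_effect([0.1], [0.0])


def _irls_logistic(X, y, tol=1e-10, iters=100):
    """Hand-rolled Newton/IRLS logistic MLE oracle."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        z = eta + (y - mu) / np.clip(W, 1e-12, None)
        beta_new = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


class TestGee:
    @staticmethod
    def _random_design(rng, n=80):
        group = rng.choice(["High", "Low"], size=n)
        x = (group == "Low").astype(float)
        logit = -0.2 + rng.normal(0.8) * x
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        df = pd.DataFrame(
            {
                "item": [f"i{i}" for i in range(n)],  # singleton clusters
                "group": group,
                "repetition": 1,
                "correct": y,
            }
        )
        return df, np.column_stack([np.ones(n), x]), y

    def test_independence_singleton_clusters_match_logistic_mle(self):
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 100:
            df, X, y = self._random_design(rng)
            if y.min() == y.max() or df.groupby("group")["correct"].nunique().min() < 2:
                continue
            res = gee_binomial(df, contrasts=("Low",), independence=True)[0]
            beta = _irls_logistic(X, y)
            assert np.log(res.odds_ratio) == pytest.approx(beta[1], abs=1e-5)
            checked += 1

    def test_collapsed_two_by_two_equals_cross_product_ratio(self):
        rows = []
        counts = {("High", 1): 30, ("High", 0): 10, ("Low", 1): 20, ("Low", 0): 25}
        i = 0
        for (g, c), k in counts.items():
            for _ in range(k):
                rows.append({"item": f"i{i}", "group": g, "repetition": 1, "correct": c})
                i += 1
        res = gee_binomial(pd.DataFrame(rows), contrasts=("Low",), independence=True)[0]
        odds_high = counts[("High", 1)] / counts[("High", 0)]
        odds_low = counts[("Low", 1)] / counts[("Low", 0)]
        assert res.odds_ratio == pytest.approx(odds_low / odds_high, rel=1e-4)

    def test_exchangeable_correlation_capped_below_one(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(60):
            c = int(rng.random() < 0.5 + 0.3 * (i % 2))  # outcome fixed per item
            for g in ("High", "Low"):
                for rep in (1, 2, 3):
                    rows.append({"item": f"i{i}", "group": g, "repetition": rep, "correct": c})
        res = gee_binomial(pd.DataFrame(rows), contrasts=("Low",))[0]
        assert res.dep_correlation < 1.0
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_constant_outcome_reported_unstable(self):
        df = pd.DataFrame(
            {
                "item": ["a", "b"] * 3,
                "group": ["High", "High", "Low", "Low", "Total", "Total"],
                "repetition": 1,
                "correct": 1,
            }
        )
        with pytest.warns(UserWarning):
            results = gee_binomial(df)
        assert all(r.unstable and r.odds_ratio == 1.0 for r in results)


def _bh_bruteforce(ps):
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) * m / j, capped."""
    m = len(ps)
    order = np.argsort(ps)
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(ps[order[j - 1]] * m / j for j in range(rank_i, m + 1)), 1.0
        )
    return q


class TestBhFdr:
    def test_single_p_per_family_unchanged(self):
        q = bh_fdr([0.03, 0.4], families=["a", "b"])
        assert q == pytest.approx([0.03, 0.4])

    def test_textbook_ladder(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_equal_ps_stay_equal(self):
        q = bh_fdr([0.2, 0.2, 0.2])
        assert q == pytest.approx([0.2, 0.2, 0.2])

    @given(
        ps=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=12)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce_step_up(self, ps):
        np.testing.assert_allclose(bh_fdr(ps), _bh_bruteforce(ps), atol=1e-12)

    def test_q_at_least_p_and_order_preserved(self):
        rng = np.random.default_rng(2)
        ps = rng.random(20)
        fam = rng.choice(["x", "y"], 20)
        q = bh_fdr(ps, fam)
        assert (q >= ps - 1e-15).all()
        order = np.argsort(ps[fam == "x"])
        qx = q[fam == "x"]
        assert (np.diff(qx[order]) >= -1e-15).all()


class TestCompareGroups:
    def test_report_shape_three_conditions_two_tasks_two_contrasts(self):
        table = simulate_evaluation(
            n_items=40, repetitions=3,
            conditions=("baseline", "unambiguous", "ambiguous"), seed=1,
        )
        report = compare_groups(table)
        assert len(report.table) == 3 * 2 * 2 == 12
        assert (report.table["q_delong"] >= report.table["p_delong"] - 1e-15).all()
        assert (report.table["q_gee"] >= report.table["p_gee"] - 1e-15).all()
        assert "odds_ratio" in report.summary()

    def test_mismatched_item_sets_rejected(self):
        table = simulate_evaluation(n_items=20, repetitions=2, tasks=("arousal",), seed=2)
        broken = table.drop(table[(table["group"] == "Low")].index[:1])
        with pytest.raises(InferenceError):
            compare_groups(broken)
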