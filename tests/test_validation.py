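"""Cross-validation bookkeeping, factor cap, and the SEC/SECV formulas."""

import numpy as np
import pytest

from aquanir.validation import (
    calibration_metrics,
    group_holdout_validate,
    loo_crossvalidate,
    max_factors,
    misclassification_summary,
    secv_per_factor,
    select_factors,
)


class TestMaxFactors:
    @pytest.mark.parametrize(
        "n,expected", [(39, 3), (24, 2), (5, 1), (10, 1), (20, 2), (100, 10), (9, 1)]
    )
    def test_one_tenth_rule(self, n, expected):
        assert max_factors(n) == expected


def _nipals_oracle(X, y, k):
    """Self-contained NIPALS PLS1 for the brute-force CV oracle."""
    Xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - Xm, y - ym
    W, P, q = [], [], []
    Xd, yd = Xc.copy(), yc.copy()
    for _ in range(k):
        w = Xd.T @ yd
        w = w / np.linalg.norm(w)
        t = Xd @ w
        tt = t @ t
        p = Xd.T @ t / tt
        qa = (yd @ t) / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - t * qa
        W.append(w), P.append(p), q.append(qa)
    W, P, q = np.array(W).T, np.array(P).T, np.array(q)
    b = W @ np.linalg.solve(P.T @ W, q)
    return lambda Xn: (Xn - Xm) @ b + ym


class TestLOO:
    def test_each_sample_predicted_once_per_factor(self, rng):
        X = rng.normal(size=(12, 9))
        y = rng.normal(size=12)
        cv = loo_crossvalidate("plsr", X, y, 2)
        assert cv.shape == (12, 2)
        assert np.all(np.isfinite(cv))

    def test_noise_free_rank_one_has_vanishing_secv(self, rng):
        p = rng.normal(size=25)
        t = rng.normal(size=15)
        X = np.outer(t, p)
        y = 2.0 * t + 1.0
        cv = loo_crossvalidate("plsr", X, y, 1)
        assert secv_per_factor(y, cv)[0] < 1e-8

    def test_matches_independent_bruteforce_refit_loop(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(20, 50))
        y = X[:, :3] @ np.array([1.0, -2.0, 0.5]) + 0.2 * rng.normal(size=20)
        k_max = 2
        cv = loo_crossvalidate("plsr", X, y, k_max)
        brute = np.empty_like(cv)
        for k in range(1, k_max + 1):
            for i in range(20):
                keep = np.r_[0:i, i + 1 : 20]
                predict = _nipals_oracle(X[keep], y[keep], k)
                brute[i, k - 1] = predict(X[i][None, :])[0]
        np.testing.assert_allclose(
            secv_per_factor(y, cv), secv_per_factor(y, brute), atol=1e-10
        )
        np.testing.assert_allclose(cv, brute, atol=1e-10)

    def test_infeasible_k_rejected(self, rng):
        X = rng.normal(size=(5, 10))
        with pytest.raises(ValueError):
            loo_crossvalidate("plsr", X, rng.normal(size=5), 4)


class TestGroupHoldout:
    def test_per_sample_groups_reduce_to_loo(self, rng):
        X = rng.normal(size=(10, 8))
        y = rng.normal(size=10)
        cv_loo = loo_crossvalidate("plsr", X, y, 2)
        cv_grp = group_holdout_validate("plsr", X, y, [f"g{i}" for i in range(10)], 2)
        np.testing.assert_allclose(cv_loo, cv_grp, atol=1e-12)

    def test_two_groups_two_refits(self, rng):
        X = rng.normal(size=(10, 8))
        y = rng.normal(size=10)
        groups = ["a"] * 5 + ["b"] * 5
        cv = group_holdout_validate("plsr", X, y, groups, 2)
        assert cv.shape == (10, 2)

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError):
            group_holdout_validate(
                "plsr", rng.normal(size=(6, 4)), rng.normal(size=6), ["g"] * 6, 1
            )

    def test_batch_confounding_makes_group_cv_harder(self):
        rng = np.random.default_rng(31)
        n_batch, n = 4, 32
        batches = np.repeat(np.arange(n_batch), n // n_batch)
        batch_shift = rng.normal(size=(n_batch, 20)) * 0.5
        y = rng.normal(size=n)
        X = np.outer(y, rng.normal(size=20)) + batch_shift[batches] + 0.05 * rng.normal(size=(n, 20))
        cv_loo = loo_crossvalidate("plsr", X, y, 2)
        cv_grp = group_holdout_validate("plsr", X, y, batches, 2)
        assert secv_per_factor(y, cv_grp)[1] >= secv_per_factor(y, cv_loo)[1]


class TestMetrics:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = calibration_metrics(y, y, y, 1)
        assert res.r_cal == pytest.approx(1.0)
        assert res.sec == pytest.approx(0.0)
        assert res.secv == pytest.approx(0.0)

    def test_sec_formula_with_alternating_residuals(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        resid = np.array([1.0, -1.0, 1.0, -1.0])
        res = calibration_metrics(y, y - resid, y - resid, 1)
        assert res.sec == pytest.approx(np.sqrt(4.0 / 2.0))  # n-k-1 = 2
        assert res.secv == pytest.approx(1.0)  # divisor n = 4

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError):
            calibration_metrics(np.ones(5), np.ones(5), None, 1)

    def test_order_permutation_invariance(self, rng):
        y = rng.normal(size=14)
        yc = y + 0.1 * rng.normal(size=14)
        yv = y + 0.2 * rng.normal(size=14)
        perm = rng.permutation(14)
        a = calibration_metrics(y, yc, yv, 2)
        b = calibration_metrics(y[perm], yc[perm], yv[perm], 2)
        assert a.sec == pytest.approx(b.sec)
        assert a.secv == pytest.approx(b.secv)
        assert a.r_cal == pytest.approx(b.r_cal)

    def test_sec_not_above_secv_on_average(self):
        """SEC uses the fitted model, SECV the held-out one: over seeded
        replicates the CV error dominates on average."""
        diffs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(15, 10))
            y = X[:, 0] + 0.5 * rng.normal(size=15)
            cv = loo_crossvalidate("plsr", X, y, 1)
            from aquanir.core import fit_calibration

            fit = fit_calibration(X, y, "plsr", 1)
            res = calibration_metrics(y, fit.predict(X), cv[:, 0], 1)
            diffs.append(res.secv - res.sec)
        assert np.mean(diffs) > 0


class TestSelectFactors:
    @pytest.mark.parametrize(
        "secv,expected",
        [((3.0, 1.0, 2.0), 2), ((1.0, 1.0, 1.0), 1), ((3.0, 2.0, 1.0), 3)],
    )
    def test_argmin_with_tie_to_smallest(self, secv, expected):
        assert select_factors(np.array(secv), 3) == expected


class TestMisclassification:
    def test_all_correct(self):
        s = misclassification_summary(["a", "b"], ["a", "b"])
        assert s.ratio_correct == 1.0

    def test_fourteen_of_sixteen(self):
        truth = ["a"] * 8 + ["b"] * 8
        pred = ["a"] * 7 + ["b"] + ["b"] * 7 + ["a"]
        assert misclassification_summary(truth, pred).ratio_correct == 0.875

    def test_all_unassigned_is_zero(self):
        s = misclassification_summary(["a", "b"], [None, set()])
        assert s.ratio_correct == 0.0 and s.n_unassigned == 2

    def test_multi_assignment_counts_incorrect(self):
        s = misclassification_summary(["a"], [{"a", "b"}])
        assert s.ratio_correct == 0.0 and s.n_multi_assigned == 1
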