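"""Unit and oracle tests for the from-scratch survival estimators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from survtransfer.exceptions import DegenerateGroupingError, DesignError, InputError
from survtransfer.survival import (
    CovariateMatrix,
    SurvivalOutcome,
    arrays_to_outcomes,
    cox_fit,
    cox_linear_predictor,
    km_estimate,
    log_rank_test,
    survival_tree_fit,
    tree_incidence_rate,
)

from conftest import random_censored_outcomes


# ---------------------------------------------------------------------------
# Kaplan-Meier


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimate(arrays_to_outcomes([1, 2, 3], [1, 0, 1]))
        assert km(1) == pytest.approx(2 / 3)
        assert km(2.5) == pytest.approx(2 / 3)
        assert km(3) == pytest.approx(0.0)
        assert km(0) == 1.0

    def test_all_censored_is_flat_one(self):
        km = km_estimate(arrays_to_outcomes([1, 2, 3], [0, 0, 0]))
        assert np.all(km(np.array([0.5, 1, 5, 100])) == 1.0)

    def test_non_increasing_and_matches_ecdf_without_censoring(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(1.0, 50) + 1e-3
        km = km_estimate(arrays_to_outcomes(times, np.ones(50)))
        grid = np.linspace(0, times.max() * 1.1, 200)
        s = km(grid)
        assert np.all(np.diff(s) <= 1e-12)
        # with no censoring 1 - S is the empirical CDF
        ecdf = np.searchsorted(np.sort(times), grid, side="right") / 50
        assert np.allclose(1 - s, ecdf)

    def test_empty_input_raises(self):
        with pytest.raises(InputError):
            km_estimate([])


# ---------------------------------------------------------------------------
# Log-rank


class TestLogRank:
    def test_hand_hypergeometric_toy(self, toy_outcomes):
        outcomes, groups = toy_outcomes
        chi2, p = log_rank_test(outcomes, groups)
        # hand accumulation of (O-E) and hypergeometric variance per event
        # time for group 0: t=1: E=1/2, V=1/4; t=2: E=2/5, V=6/25;
        # t=3: E=1/4, V=3/16; later times contribute nothing to group 0.
        o_minus_e = (1 - 0.5) + (1 - 2 / 5) + (1 - 1 / 4)
        v = 0.25 + 6 / 25 + 3 / 16
        assert chi2 == pytest.approx(o_minus_e**2 / v, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(o_minus_e**2 / v, 1), rel=1e-12)

    def test_identical_groups_give_zero(self):
        outcomes = arrays_to_outcomes([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        chi2, p = log_rank_test(outcomes, [0, 0, 0, 1, 1, 1])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(7)
        outcomes = random_censored_outcomes(rng, 40)
        groups = rng.integers(0, 2, 40)
        if groups.min() == groups.max():
            groups[0] = 1 - groups[0]
        a = log_rank_test(outcomes, groups)
        b = log_rank_test(outcomes, 1 - groups)
        assert a[0] == pytest.approx(b[0], rel=1e-10)

    def test_matches_cox_score_direction(self):
        # on tie-free data the log-rank statistic approximates the Cox score
        # test on the group indicator: same order of magnitude and p
        rng = np.random.default_rng(12)
        n = 80
        g = rng.integers(0, 2, n)
        times = rng.exponential(np.exp(-0.8 * g)) + 1e-6
        outcomes = arrays_to_outcomes(times, np.ones(n))
        chi2, p_lr = log_rank_test(outcomes, g)
        fit = cox_fit(g.astype(float)[:, None], outcomes)
        assert np.sign(fit.beta[0]) == 1
        assert p_lr == pytest.approx(fit.wald_p[0], rel=0.25)

    def test_single_group_raises(self):
        outcomes = arrays_to_outcomes([1, 2], [1, 1])
        with pytest.raises(DegenerateGroupingError):
            log_rank_test(outcomes, [0, 0])


# ---------------------------------------------------------------------------
# Cox partial likelihood


def breslow_partial_loglik(beta, x, times, events):
    """Independent, explicitly coded partial likelihood (p=1, no ties)."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            risk = [j for j in range(len(times)) if times[j] >= times[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


class TestCoxFit:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_1d_oracle(self, seed):
        """beta-hat equals direct maximisation of the explicitly coded
        partial likelihood on tiny tie-free datasets (p=1, n <= 12)."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 13))
        x = rng.normal(size=n)
        times = rng.exponential(np.exp(-0.5 * x))
        times += rng.uniform(0, 1e-4, n)  # guarantee no ties
        events = rng.integers(0, 2, n)
        events[rng.integers(0, n)] = 1
        outcomes = arrays_to_outcomes(times, events)
        fit = cox_fit(x[:, None], outcomes)
        if not fit.converged:
            pytest.skip("separation on a tiny draw; oracle undefined too")
        res = minimize_scalar(
            lambda b: -breslow_partial_loglik(b, x, times, events),
            bounds=(-20, 20),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.beta[0] == pytest.approx(res.x, abs=1e-6)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_parameter_recovery_hazard_ratio_two(self):
        rng = np.random.default_rng(5)
        n = 1000
        g = rng.integers(0, 2, n).astype(float)
        times = rng.exponential(1.0 / (0.05 * np.exp(np.log(2) * g)))
        cens = rng.exponential(40.0, n)
        t = np.maximum(np.minimum(times, cens), 1e-8)
        e = (times <= cens).astype(int)
        fit = cox_fit(g[:, None], arrays_to_outcomes(t, e))
        assert abs(fit.beta[0] - np.log(2)) < 3 * fit.se[0]

    def test_null_covariate_near_zero(self):
        rng = np.random.default_rng(6)
        n = 500
        x = rng.normal(size=n)
        outcomes = random_censored_outcomes(rng, n)
        fit = cox_fit(x[:, None], outcomes)
        assert abs(fit.beta[0]) < 3 * fit.se[0]

    def test_centering_invariance(self):
        rng = np.random.default_rng(8)
        n = 60
        X = rng.normal(size=(n, 2))
        outcomes = random_censored_outcomes(rng, n)
        f1 = cox_fit(X, outcomes)
        f2 = cox_fit(X + np.array([100.0, -7.0]), outcomes)
        assert np.allclose(f1.beta, f2.beta, atol=1e-6)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)

    def test_loglik_dominates_null_and_se_positive(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(100, 3))
        outcomes = random_censored_outcomes(rng, 100)
        fit = cox_fit(X, outcomes)
        assert fit.loglik >= fit.loglik_null
        assert fit.converged
        assert np.all(fit.se > 0)

    def test_efron_ties_match_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(10)
        n = 120
        X = rng.normal(size=(n, 2))
        times = np.ceil(rng.exponential(np.exp(-X[:, 0] * 0.7)) * 4) / 4  # heavy ties
        times = np.maximum(times, 0.25)
        events = rng.integers(0, 2, n)
        events[:10] = 1
        fit = cox_fit(X, arrays_to_outcomes(times, events))
        df = pd.DataFrame(X, columns=["a", "b"])
        df["T"], df["E"] = times, events
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(fit.beta, cph.params_.values, atol=1e-4)
        assert np.allclose(fit.se, cph.standard_errors_.values, atol=1e-4)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-4)

    def test_constant_column_raises(self):
        outcomes = arrays_to_outcomes([1, 2, 3, 4], [1, 1, 0, 1])
        with pytest.raises(DesignError, match="constant"):
            cox_fit(np.ones((4, 1)), outcomes)

    def test_separation_flagged_not_raised(self):
        # perfectly separating covariate: likelihood is monotone in beta
        times = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        fit = cox_fit(x[:, None], arrays_to_outcomes(times, np.ones(6)))
        assert not fit.converged


class TestLinearPredictor:
    def test_hand_dot_product(self):
        scores = cox_linear_predictor(np.array([1.0, -2.0]), np.array([[3.0, 1.0]]))
        assert scores[0] == pytest.approx(1.0)

    def test_zero_beta_gives_zero_scores(self):
        X = np.arange(12.0).reshape(4, 3)
        assert np.all(cox_linear_predictor(np.zeros(3), X) == 0)

    def test_column_shift_preserves_ranking(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 2))
        beta = np.array([0.7, -1.2])
        s1 = cox_linear_predictor(beta, X)
        s2 = cox_linear_predictor(beta, X + np.array([5.0, 0.0]))
        assert np.allclose(s2 - s1, 0.7 * 5.0)
        assert np.array_equal(np.argsort(s1), np.argsort(s2))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(DesignError):
            cox_linear_predictor(np.ones(3), np.ones((5, 2)))


# ---------------------------------------------------------------------------
# Survival tree


def _planted_tree_data(seed=0, n=400, hr=5.0):
    rng = np.random.default_rng(seed)
    risk = rng.integers(0, 2, n).astype(float)
    noise = rng.normal(size=n)
    times = rng.exponential(1.0 / (0.1 * hr**risk)) + 1e-6
    frame = pd.DataFrame({"risk": risk, "noise": noise})
    return CovariateMatrix(frame), arrays_to_outcomes(times, np.ones(n))


class TestSurvivalTree:
    def test_planted_split_found_at_root(self):
        X, outcomes = _planted_tree_data(seed=1)
        tree = survival_tree_fit(X, outcomes, min_leaf=20, max_depth=2)
        assert not tree.root.is_leaf
        assert tree.root.feature == "risk"

    def test_no_signal_gives_single_leaf(self):
        rng = np.random.default_rng(2)
        n = 200
        frame = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        outcomes = random_censored_outcomes(rng, n)
        tree = survival_tree_fit(CovariateMatrix(frame), outcomes, p_enter=1e-4)
        assert tree.n_leaves == 1

    def test_min_leaf_respected_everywhere(self):
        X, outcomes = _planted_tree_data(seed=3)
        tree = survival_tree_fit(X, outcomes, min_leaf=30, max_depth=3)
        assert all(leaf.n >= 30 for leaf in tree.leaves())

    def test_small_n_returns_single_leaf(self):
        X, outcomes = _planted_tree_data(seed=4, n=30)
        tree = survival_tree_fit(X, outcomes, min_leaf=20)
        assert tree.n_leaves == 1

    def test_deterministic(self):
        X, outcomes = _planted_tree_data(seed=5)
        t1 = survival_tree_fit(X, outcomes)
        t2 = survival_tree_fit(X, outcomes)
        assert (t1.root.feature, t1.root.threshold) == (t2.root.feature, t2.root.threshold)
        assert [l.incidence_rate for l in t1.leaves()] == [l.incidence_rate for l in t2.leaves()]

    def test_deeper_tree_does_not_lose_grouping_signal(self):
        X, outcomes = _planted_tree_data(seed=6)
        chis = []
        for depth in (1, 2, 3):
            tree = survival_tree_fit(X, outcomes, min_leaf=20, max_depth=depth)
            rates = tree_incidence_rate(tree, X)
            labels = np.unique(rates, return_inverse=True)[1]
            if len(np.unique(labels)) < 2:
                chis.append(0.0)
            else:
                chis.append(log_rank_test(outcomes, labels)[0])
        assert chis[0] <= chis[1] + 1e-9 and chis[1] <= chis[2] + 1e-9

    def test_incidence_rate_hand_value(self):
        # one leaf: 2 events over 10 units of total follow-up -> rate 0.2
        frame = pd.DataFrame({"x": [0.0, 0.0, 0.0, 0.0]})
        outcomes = arrays_to_outcomes([2, 3, 1, 4], [1, 0, 1, 0])
        tree = survival_tree_fit(CovariateMatrix(frame), outcomes, min_leaf=2)
        rates = tree_incidence_rate(tree, CovariateMatrix(frame))
        assert np.allclose(rates, 0.2)

    def test_all_censored_leaf_rate_zero(self):
        frame = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        outcomes = arrays_to_outcomes([5, 6, 7], [0, 0, 0])
        tree = survival_tree_fit(CovariateMatrix(frame), outcomes, min_leaf=1)
        assert np.allclose(tree_incidence_rate(tree, CovariateMatrix(frame)), 0.0)

    def test_categorical_split_and_unseen_level(self):
        from survtransfer.exceptions import RoutingError

        rng = np.random.default_rng(7)
        n = 300
        grp = rng.choice(["u", "v", "w"], n)
        times = rng.exponential(np.where(grp == "u", 0.2, 2.0)) + 1e-6
        frame = pd.DataFrame({"g": grp})
        cm = CovariateMatrix(frame, categorical={"g": "u"})
        tree = survival_tree_fit(cm, arrays_to_outcomes(times, np.ones(n)), min_leaf=20)
        assert tree.root.feature == "g"
        new = CovariateMatrix(pd.DataFrame({"g": ["zzz"]}), categorical={"g": "u"})
        with pytest.raises(RoutingError, match="zzz"):
            tree_incidence_rate(tree, new)
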