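"""Concordance index, normalization, feature selection and CV tuning."""

import itertools
import warnings

import numpy as np
import pytest

from bpsurv import (
    ModelSpec,
    Normalizer,
    concordance_index,
    cv_tune,
    fit,
    mi_kbest,
    overfit_gap,
    risk_score,
    simulate_survival,
    split_train_test,
)


def brute_force_cindex(times, events, risks):
    """Quadratic pair enumeration with Harrell's conventions."""
    num = den = 0.0
    for i, j in itertools.permutations(range(len(times)), 2):
        if times[i] < times[j] and events[i] == 1:
            den += 1
            if risks[i] > risks[j]:
                num += 1
            elif risks[i] == risks[j]:
                num += 0.5
    return num / den if den else 0.5


class TestConcordanceIndex:
    def test_perfect_reverse_ordering(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_index(t, np.ones(4), -t) == 1.0

    def test_all_tied_risks_give_half(self):
        assert concordance_index([1, 2, 3], [1, 1, 1], [5, 5, 5]) == 0.5

    def test_hand_counted_example(self):
        # comparable pairs: (1,2),(1,3),(1,4) concordant; (3,4) discordant
        ci = concordance_index([1, 2, 3, 4], [1, 0, 1, 1], [4, 1, 2, 3])
        assert ci == 0.75

    def test_all_censored_warns_and_returns_half(self):
        with pytest.warns(UserWarning, match="comparable"):
            assert concordance_index([1, 2], [0, 0], [1, 2]) == 0.5

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        t = rng.integers(1, 15, n).astype(float)  # integer times force ties
        e = rng.integers(0, 2, n)
        r = rng.integers(0, 6, n).astype(float)   # tied risks too
        assert concordance_index(t, e, r) == pytest.approx(
            brute_force_cindex(t, e, r), abs=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        t, e, r = rng.exponential(1, 40), rng.integers(0, 2, 40), rng.normal(size=40)
        ci = concordance_index(t, e, r)
        assert concordance_index(t, e, np.exp(3 * r) + 7) == pytest.approx(ci)

    def test_agrees_with_lifelines_without_ties(self):
        from lifelines.utils import concordance_index as ll_cindex

        rng = np.random.default_rng(8)
        t = rng.exponential(1, 60)  # continuous: no tied times
        e = rng.integers(0, 2, 60)
        r = rng.normal(size=60)
        # lifelines ranks by predicted survival time (low risk = long survival)
        assert concordance_index(t, e, r) == pytest.approx(ll_cindex(t, -r, e), abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(50):
            t = rng.exponential(1, 200)
            e = rng.integers(0, 2, 200)
            vals.append(concordance_index(t, e, rng.normal(size=200)))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)


class TestRiskScore:
    def test_intercept_only_constant_scores(self, exp_cohort, quick_cfg):
        data, _ = exp_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = fit(ModelSpec("exponential"), data.select_features([]),
                       sampler_config=quick_cfg)
        scores = risk_score(post, np.zeros((4, 0)))
        assert np.ptp(scores) == 0.0

    def test_rate_and_median_scores_rank_identically(self, exp_posterior, exp_cohort):
        from bpsurv.inference import posterior_params_for, predict_median_survival

        data, _ = exp_cohort
        X = data.covariates[:30]
        lam = posterior_params_for(exp_posterior, X).lam.mean(axis=0)
        neg_med = -predict_median_survival(exp_posterior, X).mean(axis=0)
        ci_a = concordance_index(data.times[:30], data.events[:30], lam)
        ci_b = concordance_index(data.times[:30], data.events[:30], neg_med)
        assert ci_a == pytest.approx(ci_b, abs=1e-12)

    def test_strong_covariate_discriminates(self, quick_cfg):
        # effect size 1.2 targets discrimination comfortably above 0.7
        data, _ = simulate_survival(
            300, [np.log(0.5), 1.2],
            censoring={"mode": "administrative", "target_frac": 0.3}, seed=11,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = fit(ModelSpec("exponential"), data, sampler_config=quick_cfg)
        ci = concordance_index(data.times, data.events, risk_score(post, data.covariates))
        assert ci >= 0.7


class TestOverfitGap:
    @pytest.mark.parametrize("train, test, gap", [
        (0.80, 0.75, 0.05), (0.7, 0.7, 0.0), (0.6, 0.65, -0.05),
    ])
    def test_gap(self, train, test, gap):
        assert overfit_gap(train, test) == pytest.approx(gap)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            overfit_gap(1.2, 0.5)


class TestNormalizer:
    def test_train_columns_standardized(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.normal(5, 3, 200), rng.integers(0, 2, 200)])
        norm = Normalizer(["continuous", "binary"]).fit(X)
        Z = norm.transform(X)
        assert Z[:, 0].mean() == pytest.approx(0.0, abs=1e-12)
        assert Z[:, 0].std() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_array_equal(Z[:, 1], X[:, 1])  # binary untouched

    def test_test_set_uses_training_statistics(self):
        train = np.array([[0.0], [2.0]])
        test = np.array([[10.0], [12.0]])
        Z = Normalizer(["continuous"]).fit(train).transform(test)
        assert Z.mean() != pytest.approx(0.0, abs=0.5)  # not re-centred on test
        np.testing.assert_allclose(Z.ravel(), [9.0, 11.0])

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(2)
        X = rng.normal(2, 7, (50, 3))
        norm = Normalizer(["continuous"] * 3).fit(X)
        np.testing.assert_allclose(norm.inverse_transform(norm.transform(X)), X,
                                   atol=1e-10)

    def test_zero_variance_column_warns(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            Normalizer(["continuous"]).fit(np.ones((10, 1)))


class TestMiKbest:
    def test_k_equals_all_preserves_order(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 4))
        t = rng.exponential(1, 100)
        np.testing.assert_array_equal(
            mi_kbest(X, t, np.ones(100), 4), [0, 1, 2, 3]
        )

    def test_label_itself_ranks_first(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(1, 300)
        label = (t > np.median(t)).astype(float)
        X = np.column_stack([rng.normal(size=300), label, rng.normal(size=300)])
        assert 1 in mi_kbest(X, t, np.ones(300), 1)

    def test_informative_beats_noise(self):
        """A survival-shifting feature outranks pure noise nearly always."""
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=250)
            t = rng.exponential(np.exp(-1.0 * x))
            X = np.column_stack([x, rng.normal(size=250)])
            wins += mi_kbest(X, t, np.ones(250), 1, seed=0)[0] == 0
        assert wins >= 95

    def test_k_out_of_range(self):
        with pytest.raises(ValueError, match="k must"):
            mi_kbest(np.zeros((10, 2)), np.ones(10), np.ones(10), 3)


class TestSplitTrainTest:
    def test_sizes_and_disjoint(self, exp_cohort):
        data, _ = exp_cohort
        train, test = split_train_test(data, 0.2, seed=1)
        assert (train.n, test.n) == (240, 60)
        assert not set(zip(train.times, train.covariates[:, 0])) & \
            set(zip(test.times, test.covariates[:, 0]))

    def test_seed_reproducible_and_sensitive(self, exp_cohort):
        data, _ = exp_cohort
        a1, _ = split_train_test(data, 0.2, seed=5)
        a2, _ = split_train_test(data, 0.2, seed=5)
        b, _ = split_train_test(data, 0.2, seed=6)
        np.testing.assert_array_equal(a1.times, a2.times)
        assert not np.array_equal(a1.times, b.times)


class TestCvTune:
    def test_single_configuration_returned(self, exp_cohort):
        data, _ = exp_cohort
        calls = []

        def scorer(d, tr, te, spec, hp, cfg):
            calls.append(1)
            return 0.6

        res = cv_tune(data, ModelSpec("exponential"),
                      space={"prior_sd": 1.0, "k": 1}, budget=1, scorer=scorer)
        assert res.best == {"prior_sd": 1.0, "k": 1}
        assert len(calls) == 5  # five folds

    def test_dominated_configuration_loses(self, exp_cohort):
        data, _ = exp_cohort

        def search(space, rng, budget):
            return [{"dummy": True}, {"dummy": False}]

        def scorer(d, tr, te, spec, hp, cfg):
            return 0.5 if hp["dummy"] else 0.7

        res = cv_tune(data, ModelSpec("exponential"), space={}, budget=2,
                      search=search, scorer=scorer)
        assert res.best == {"dummy": False}
        assert res.best_score == pytest.approx(0.7)

    def test_selects_small_k_with_noise_features(self, quick_cfg):
        """With 2 informative + 8 noise features, tuning favours k <= 6."""
        hits = 0
        runs = 10
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(150, 10))
            lam = np.exp(np.log(0.5) + 0.9 * X[:, 0] - 0.9 * X[:, 1])
            t = rng.exponential(1.0 / lam)
            from bpsurv import SurvivalData

            data = SurvivalData(times=t, events=np.ones(150), covariates=X)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = cv_tune(data, ModelSpec("exponential"), budget=4,
                              seed=seed, sampler_config={"tune": 150, "draws": 100,
                                                         "seed": seed})
            hits += res.best["k"] <= 6
        assert hits > runs / 2


def test_budget_must_be_positive(exp_cohort):
    data, _ = exp_cohort
    with pytest.raises(ValueError, match="budget"):
        cv_tune(data, ModelSpec("exponential"), budget=0)
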