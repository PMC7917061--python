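"""Core model machinery: profiles, item models, likelihood, EM, criteria."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cdmdim.core import (
    FitResult,
    InvalidParameterError,
    ItemParams,
    LatentClassSpace,
    QMatrix,
    deltas_to_probs,
    dina_prob,
    enumerate_profiles,
    fit_em,
    gdina_prob,
    information_criteria,
    marginal_loglik,
    probs_to_deltas,
)
from cdmdim.simulate import SimCondition, generate_dataset


class TestEnumerateProfiles:
    def test_complete_enumeration_small_k(self):
        assert enumerate_profiles(1).profiles.tolist() == [[0], [1]]
        p2 = enumerate_profiles(2).profiles
        assert len(p2) == 4
        assert [0, 0] in p2.tolist() and [1, 1] in p2.tolist()
        p3 = enumerate_profiles(3).profiles
        assert len({tuple(row) for row in p3.tolist()}) == 8

    def test_canonical_order_first_attribute_fastest(self):
        p = enumerate_profiles(3).profiles
        assert p[1].tolist() == [1, 0, 0]
        assert p[2].tolist() == [0, 1, 0]
        assert p[4].tolist() == [0, 0, 1]

    def test_uniform_weights(self):
        space = enumerate_profiles(3)
        np.testing.assert_allclose(space.weights, 1 / 8)

    @pytest.mark.parametrize("K", [0, -1, 16])
    def test_bounds(self, K):
        with pytest.raises(ValueError):
            enumerate_profiles(K)


class TestItemResponseModels:
    def test_dina_worked_probabilities(self):
        # an item with g = 0.1, s = 0.2: masters succeed with 0.8, others guess
        assert dina_prob(0.1, 0.2, 1) == pytest.approx(0.8)
        assert dina_prob(0.1, 0.2, 0) == pytest.approx(0.1)

    def test_dina_deterministic_item(self):
        assert dina_prob(0.0, 0.0, 1) == 1.0
        assert dina_prob(0.0, 0.0, 0) == 0.0

    def test_gdina_worked_probabilities(self):
        # intercept 0.1, mains 0.25/0.35, interaction 0.1
        deltas = np.array([0.1, 0.25, 0.35, 0.1])
        assert gdina_prob(deltas, [1, 1]) == pytest.approx(0.80)
        assert gdina_prob(deltas, [0, 1]) == pytest.approx(0.45)
        assert gdina_prob(deltas, [0, 0]) == pytest.approx(0.10)

    def test_gdina_rejects_malformed_deltas(self):
        with pytest.raises(InvalidParameterError):
            gdina_prob(np.array([0.5, 0.4, 0.4, 0.4]), [1, 1])  # sums to 1.7

    def test_delta_probability_round_trip(self, rng):
        for kstar in (1, 2, 3):
            for _ in range(25):
                probs = rng.uniform(0, 1, size=2**kstar)
                back = deltas_to_probs(probs_to_deltas(probs))
                np.testing.assert_allclose(back, probs, atol=1e-12)

    def test_deltas_are_difference_contrasts(self):
        probs = np.array([0.1, 0.35, 0.45, 0.80])
        d = probs_to_deltas(probs)
        np.testing.assert_allclose(d, [0.1, 0.25, 0.35, 0.1], atol=1e-12)


def brute_force_loglik(X, Q, params, weights):
    """Independent full-enumeration oracle for the marginal likelihood."""
    N, J = X.shape
    K = Q.K
    total = 0.0
    for i in range(N):
        person = 0.0
        for l in range(2**K):  # class l has alpha_k = (l >> k) & 1
            lik = weights[l]
            for j in range(J):
                req = [k for k in range(K) if Q.entries[j, k]]
                if params.model == "DINA":
                    eta = int(all(((l >> k) & 1) for k in req))
                    p = params.probs[j][eta]
                else:
                    mask = sum((1 << b) for b, k in enumerate(req) if (l >> k) & 1)
                    p = params.probs[j][mask]
                lik *= p if X[i, j] else (1 - p)
            person += lik
        total += math.log(person)
    return total


class TestMarginalLoglik:
    def test_single_item_coin_flip(self):
        Q = QMatrix(np.array([[1]]))
        params = ItemParams("DINA", [np.array([0.5, 0.5])])
        for x in (0, 1):
            ll = marginal_loglik(np.array([[x]]), Q, params, np.array([0.4, 0.6]))
            assert ll == pytest.approx(math.log(0.5))

    @pytest.mark.parametrize("model", ["DINA", "GDINA"])
    def test_matches_enumeration_oracle(self, model, rng):
        Q = QMatrix(np.array([[1, 0], [0, 1], [1, 1], [1, 0]]))
        probs = []
        for j in range(4):
            kstar = int(Q.entries[j].sum())
            n = 2 if model == "DINA" else 2**kstar
            p = np.sort(rng.uniform(0.05, 0.95, size=n))
            probs.append(p)
        params = ItemParams(model, probs)
        w = rng.dirichlet(np.ones(4))
        X = rng.integers(0, 2, size=(6, 4))
        ours = marginal_loglik(X, Q, params, w)
        oracle = brute_force_loglik(X, Q, params, w)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_additivity_under_duplication(self, rng):
        Q = QMatrix(np.array([[1], [1], [1]]))
        params = ItemParams("DINA", [np.array([0.2, 0.9])] * 3)
        w = np.array([0.5, 0.5])
        X = rng.integers(0, 2, size=(4, 3))
        ll1 = marginal_loglik(X, Q, params, w)
        ll2 = marginal_loglik(np.vstack([X, X]), Q, params, w)
        assert ll2 == pytest.approx(2 * ll1, abs=1e-9)

    def test_contradiction_returns_neg_inf(self):
        # deterministic item (g = s = 0): a master-free population cannot
        # produce a correct response, so the likelihood collapses
        Q = QMatrix(np.array([[1]]))
        params = ItemParams("DINA", [np.array([0.0, 1.0])])
        ll = marginal_loglik(np.array([[1]]), Q, params, np.array([1.0, 0.0]))
        assert ll == -np.inf


class TestFitEM:
    def test_recovers_deterministic_dina(self, rng):
        cond = SimCondition(K=4, IQ=0.80, N=2000, JK=4, AC=0.0, AT=0.0, M="DINA")
        ds = generate_dataset(cond, 77)
        # overwrite with noiseless responses: x = eta exactly
        params0 = ItemParams("DINA", [np.array([0.0, 1.0])] * ds.Q_true.J)
        from cdmdim.simulate import gen_responses

        X = gen_responses(ds.profiles_true, ds.Q_true, params0, rng)
        fit = fit_em(X, ds.Q_true, model="DINA")
        g = np.array([p[0] for p in fit.item_params.probs])
        s = 1 - np.array([p[1] for p in fit.item_params.probs])
        assert np.all(g <= 0.01) and np.all(s <= 0.01)

    def test_gdina_parameter_recovery(self):
        # two attributes, sixteen items (singles plus both-attribute items)
        from cdmdim.simulate import (
            gen_attribute_profiles,
            gen_item_params,
            gen_responses,
        )

        rng = np.random.default_rng(11)
        Q = QMatrix(np.array([[1, 0], [0, 1]] * 5 + [[1, 1]] * 6))
        params = gen_item_params(Q, 0.80, "GDINA", rng)
        profiles = gen_attribute_profiles(2000, 2, 0.0, 0.0, rng)
        X = gen_responses(profiles, Q, params, rng)
        fit = fit_em(X, Q, model="GDINA")
        err = np.concatenate(
            [est - tru for est, tru in zip(fit.item_params.probs, params.probs)]
        )
        assert np.sqrt((err**2).mean()) < 0.05

    def test_monotone_loglik_path(self, rng):
        for seed in range(3):
            cond = SimCondition(K=4, IQ=0.60, N=500, JK=4, AC=0.30, AT=0.5, M="GDINA")
            ds = generate_dataset(cond, 100 + seed)
            fit = fit_em(ds.responses, ds.Q_true, model="GDINA")
            assert np.all(np.diff(fit.loglik_path) > -1e-8)

    def test_final_loglik_matches_marginal(self, easy_gdina_dataset):
        ds = easy_gdina_dataset
        fit = fit_em(ds.responses, ds.Q_true, model="GDINA")
        ll = marginal_loglik(
            ds.responses, ds.Q_true, fit.item_params, fit.class_space.weights
        )
        assert fit.loglik == pytest.approx(ll, abs=1e-6)

    def test_posterior_rows_sum_to_one(self, easy_gdina_dataset):
        ds = easy_gdina_dataset
        fit = fit_em(ds.responses, ds.Q_true, model="GDINA", max_iter=50)
        np.testing.assert_allclose(fit.posterior.sum(axis=1), 1.0, atol=1e-8)

    def test_gdina_subsumes_dina(self):
        cond = SimCondition(K=4, IQ=0.60, N=500, JK=4, AC=0.0, AT=0.0, M="DINA")
        ds = generate_dataset(cond, 7)
        fit_d = fit_em(ds.responses, ds.Q_true, model="DINA")
        fit_g = fit_em(ds.responses, ds.Q_true, model="GDINA")
        assert fit_g.loglik >= fit_d.loglik - 1e-6

    def test_rejects_single_respondent(self):
        with pytest.raises(ValueError):
            fit_em(np.array([[1]]), QMatrix(np.array([[1]])))


class TestInformationCriteria:
    @staticmethod
    def _stub_fit(loglik, n_params):
        return FitResult(
            item_params=ItemParams("DINA", []),
            class_space=enumerate_profiles(1),
            loglik=loglik,
            n_params=n_params,
            posterior=np.ones((1, 2)) / 2,
            n_iter=1,
            converged=True,
        )

    def test_worked_example(self):
        # -2LL = 8441 with 97 parameters: AIC 8635; BIC at N = 400 is 9022
        fit = self._stub_fit(loglik=-8441 / 2, n_params=97)
        aic, bic = information_criteria(fit, N=400)
        assert round(aic) == 8635
        assert round(bic) == 9022

    def test_zero_params_reduces_to_deviance(self):
        fit = self._stub_fit(loglik=-123.456, n_params=0)
        aic, _ = information_criteria(fit, N=50)
        assert aic == pytest.approx(246.912)


class TestQMatrixType:
    def test_rejects_zero_rows_and_bad_entries(self):
        with pytest.raises(ValueError):
            QMatrix(np.array([[1, 0], [0, 0]]))
        with pytest.raises(ValueError):
            QMatrix(np.array([[1, 2], [0, 1]]))

    def test_latent_class_space_weight_validation(self):
        with pytest.raises(ValueError):
            LatentClassSpace(enumerate_profiles(2).profiles, np.array([0.5, 0.5, 0.5, 0.5]))
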