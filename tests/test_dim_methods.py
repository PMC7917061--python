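"""Dimensionality-assessment statistics: PA, MAP, VSS, DETECT, EKC."""

import numpy as np
import pytest

from cdmdim.dim_methods import (
    conditional_covariances,
    detect,
    detect_index,
    ekc,
    leading_count,
    map_velicer,
    parallel_analysis,
    vss,
    vss_index,
)
from cdmdim.factors import sample_eigenvalues
from cdmdim.tetrachoric import TetrachoricMatrix, tetrachoric_matrix


def binary_factor_data(rng, N, loadings):
    """Dichotomised linear factor model: x_j = 1{ lam_j' f + e_j > 0 }."""
    loadings = np.atleast_2d(loadings)  # (J, m)
    J, m = loadings.shape
    f = rng.standard_normal((N, m))
    uniq = np.sqrt(np.clip(1 - (loadings**2).sum(axis=1), 0.05, None))
    y = f @ loadings.T + rng.standard_normal((N, J)) * uniq
    return (y > 0).astype(np.int8)


class TestParallelAnalysis:
    def test_leading_run_counting_rule(self):
        assert leading_count(np.array([2.5, 1.2, 0.8]), np.array([1.4, 1.0, 0.9])) == 2
        # a later exceedance after the first failure does not count
        assert leading_count(np.array([2.5, 0.9, 1.2]), np.array([1.4, 1.0, 0.9])) == 1

    def test_one_factor_binary_data(self, rng):
        hits = 0
        for _ in range(20):
            X = binary_factor_data(rng, 2000, np.full((16, 1), 0.8))
            sugg = parallel_analysis(X, "pearson", "mean", rng=rng)
            hits += sugg.khat == 1
        assert hits >= 19

    def test_independent_items_rarely_exceed_p95(self, rng):
        zeros = 0
        for _ in range(30):
            X = (rng.random((500, 12)) < 0.5).astype(np.int8)
            sugg = parallel_analysis(X, "pearson", "p95", rng=rng)
            zeros += sugg.khat == 0
        assert zeros >= 24

    def test_independent_items_mean_criterion_majority_at_most_noise(self, rng):
        khats = []
        for _ in range(10):
            X = (rng.random((500, 12)) < 0.5).astype(np.int8)
            khats.append(parallel_analysis(X, "pearson", "mean", rng=rng).khat)
        assert np.median(khats) <= 1

    def test_item_order_invariance(self, rng):
        X = binary_factor_data(rng, 800, np.full((10, 1), 0.7))
        a = parallel_analysis(X, "pearson", "mean", rng=np.random.default_rng(9))
        perm = rng.permutation(10)
        b = parallel_analysis(X[:, perm], "pearson", "mean", rng=np.random.default_rng(9))
        assert a.khat == b.khat

    def test_invariance_to_joint_relabeling(self, rng):
        X = binary_factor_data(rng, 800, np.full((10, 1), 0.7))
        flipped = X.copy()
        flipped[:, :4] = 1 - flipped[:, :4]
        a = parallel_analysis(X, "pearson", "mean", rng=np.random.default_rng(4))
        b = parallel_analysis(flipped, "pearson", "mean", rng=np.random.default_rng(4))
        assert a.khat == b.khat

    def test_tetrachoric_variant_runs(self, rng):
        X = binary_factor_data(rng, 400, np.full((8, 1), 0.8))
        sugg = parallel_analysis(X, "tetrachoric", "mean", n_perm=20, rng=rng)
        assert sugg.khat == 1

    def test_self_consistency_with_curve(self, rng):
        X = binary_factor_data(rng, 500, np.full((8, 1), 0.6))
        sugg = parallel_analysis(X, "pearson", "mean", rng=rng)
        assert sugg.khat == leading_count(sugg.curve["sample"], sugg.curve["reference"])


class TestMap:
    def test_identity_matrix_suggests_zero(self):
        sugg = map_velicer(TetrachoricMatrix(np.eye(10)), max_K=5)
        assert sugg.khat == 0

    def test_one_factor_structure(self, rng):
        X = binary_factor_data(rng, 2000, np.full((16, 1), 0.8))
        sugg = map_velicer(tetrachoric_matrix(X))
        assert sugg.khat == 1

    def test_matches_regression_partialling_oracle(self, rng):
        # partialling out m components == residualising on their scores:
        # partial corr from the regression identity with explicit solves
        A = rng.standard_normal((8, 8))
        R = A @ A.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        sugg = map_velicer(TetrachoricMatrix(R), max_K=4)
        vals, vecs = np.linalg.eigh(R)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        off = ~np.eye(8, dtype=bool)
        for m in range(0, 5):
            if m == 0:
                partial = R
            else:
                L = vecs[:, :m] * np.sqrt(vals[:m])
                # cov(x, scores) = L, var(scores) = I: residual covariance
                C = R - L @ np.linalg.solve(np.eye(m), L.T)
                dd = np.sqrt(np.diag(C))
                partial = C / np.outer(dd, dd)
            oracle = (partial[off] ** 2).mean()
            assert sugg.curve["map"][m] == pytest.approx(oracle, abs=1e-10)

    def test_khat_is_argmin_of_curve(self, rng):
        X = binary_factor_data(rng, 800, np.full((12, 1), 0.7))
        sugg = map_velicer(tetrachoric_matrix(X))
        assert sugg.khat == int(np.argmin(sugg.curve["map"]))


class TestVss:
    def test_index_is_one_for_exact_reproduction(self):
        L = np.zeros((6, 2))
        L[:3, 0] = 0.8
        L[3:, 1] = 0.7
        Phi = np.eye(2)
        R = L @ L.T
        np.fill_diagonal(R, 1.0)
        assert vss_index(R, L, Phi, v=1) == pytest.approx(1.0)

    def test_index_is_zero_for_null_loadings(self, rng):
        A = rng.standard_normal((5, 5))
        R = np.corrcoef(A)
        assert vss_index(R, np.zeros((5, 2)), np.eye(2), v=1) == pytest.approx(0.0)

    def test_two_factor_simple_structure(self, rng):
        L = np.zeros((16, 2))
        L[:8, 0] = 0.8
        L[8:, 1] = 0.8
        X = binary_factor_data(rng, 2000, L)
        sugg = vss(X, v=1, max_K=6)
        assert sugg.khat == 2

    def test_khat_is_argmax_of_curve(self, rng):
        X = binary_factor_data(rng, 600, np.full((10, 1), 0.7))
        sugg = vss(X, v=1, max_K=5)
        curve = sugg.curve["vss"]
        assert sugg.khat == max(curve, key=curve.get)


class TestDetect:
    def test_index_hand_arithmetic(self):
        C = np.zeros((4, 4))
        pairs = {(0, 1): 0.04, (0, 2): -0.01, (0, 3): -0.02,
                 (1, 2): -0.03, (1, 3): 0.00, (2, 3): 0.05}
        for (a, b), v in pairs.items():
            C[a, b] = C[b, a] = v
        clusters = np.array([1, 1, 2, 2])
        # within: (0,1), (2,3); between: the rest
        plain = (0.04 + 0.05 + 0.01 + 0.02 + 0.03 - 0.00) / 6
        assert detect_index(C, clusters) == pytest.approx(plain)
        cbar = (0.04 - 0.01 - 0.02 - 0.03 + 0.00 + 0.05) / 6
        centred = ((0.04 - cbar) + (0.05 - cbar)
                   - (-0.01 - cbar) - (-0.02 - cbar) - (-0.03 - cbar) - (0.00 - cbar)) / 6
        assert detect_index(C, clusters, center=True) == pytest.approx(centred)

    def test_two_independent_blocks(self, rng):
        L = np.zeros((12, 2))
        L[:6, 0] = 0.8
        L[6:, 1] = 0.8
        X = binary_factor_data(rng, 3000, L)
        sugg = detect(X, max_K=6)
        assert sugg.khat == 2

    def test_unidimensional_rest_score_covariances_near_zero(self, rng):
        X = binary_factor_data(rng, 4000, np.full((36, 1), 0.8))
        C = conditional_covariances(X, conditioning="rest")
        off = C[~np.eye(36, dtype=bool)]
        assert np.abs(off).mean() < 0.01

    def test_khat_is_argmax_of_curve(self, rng):
        X = binary_factor_data(rng, 800, np.full((10, 1), 0.7))
        sugg = detect(X)
        curve = sugg.curve["detect"]
        assert sugg.khat == max(curve, key=curve.get)


class TestEkc:
    def test_reference_formula_closed_form(self, rng):
        X = binary_factor_data(rng, 1600, np.full((16, 1), 0.7))
        corr = tetrachoric_matrix(X)
        sugg = ekc(corr, N=1600)
        sample = sample_eigenvalues(corr.values)
        J = 16
        edge = (1 + np.sqrt(J / 1600)) ** 2
        cum = 0.0
        for k in range(J):
            expected = max(1.0, (J - cum) / (J - k) * edge)
            assert sugg.curve["reference"][k] == pytest.approx(expected, abs=1e-12)
            cum += sample[k]
        assert sugg.curve["reference"][0] == pytest.approx(edge)

    def test_references_coerced_to_at_least_one(self, rng):
        X = (rng.random((300, 10)) < 0.5).astype(np.int8)
        sugg = ekc(tetrachoric_matrix(X), N=300)
        assert (sugg.curve["reference"] >= 1.0).all()

    def test_reduces_to_kaiser_at_population_scale(self, rng):
        X = binary_factor_data(rng, 1000, np.full((8, 1), 0.8))
        corr = tetrachoric_matrix(X)
        sugg = ekc(corr, N=10**12)
        sample = sample_eigenvalues(corr.values)
        kaiser = leading_count(sample, np.ones(8))
        assert sugg.khat == kaiser
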