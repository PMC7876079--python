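import numpy as np
import pytest

from mikern import (
    AbundanceTable,
    KernelMatrix,
    center_kernel,
    check_psd,
    clin_kernel,
    clr_transform,
    cosine_normalize_kernel,
    crbf_kernel,
    jsk_kernel,
    kernel_matrix_similarity,
    qjac_kernel,
    replace_zeros,
)

from conftest import make_count_table, make_positive_table

LN2 = np.log(2.0)


@pytest.fixture
def toy():
    return AbundanceTable([[1, 2, 4], [4, 2, 1], [1, 1, 1]],
                          ["a", "b", "c"], ["t1", "t2", "t3"])


class TestClin:
    def test_hand_value_and_uniform_row(self, toy):
        K = clin_kernel(toy)
        assert K.values[0, 1] == pytest.approx(-2 * LN2**2, abs=1e-12)
        np.testing.assert_allclose(K.values[2], 0.0, atol=1e-12)  # clr(1,1,1)=0

    def test_equals_clr_gram_matrix(self, positive_table):
        K = clin_kernel(positive_table)
        clr = clr_transform(positive_table)
        np.testing.assert_allclose(K.values, clr @ clr.T, atol=1e-10)

    def test_diagonal_is_squared_clr_norm(self, positive_table):
        K = clin_kernel(positive_table)
        clr = clr_transform(positive_table)
        np.testing.assert_allclose(np.diag(K.values), (clr**2).sum(axis=1), atol=1e-10)
        assert np.all(np.diag(K.values) >= 0)


class TestCrbf:
    def test_hand_value(self, toy):
        K = crbf_kernel(toy, 1.0)
        assert K.values[0, 1] == pytest.approx(np.exp(-8 * LN2**2), abs=1e-12)

    def test_diagonal_one_and_scaled_sample_similarity_one(self, toy):
        scaled = toy.with_values(toy.values * np.array([[1.0], [1.0], [5.0]]))
        K = crbf_kernel(scaled, 0.7)
        np.testing.assert_allclose(np.diag(K.values), 1.0)
        # row c is a rescaling of (1,1,1); clr identical to uniform row
        Ku = crbf_kernel(toy, 0.7)
        np.testing.assert_allclose(K.values, Ku.values, atol=1e-12)

    def test_matches_exp_of_squared_clr_distances(self, positive_table):
        gamma = 0.3
        clr = clr_transform(positive_table)
        d2 = ((clr[:, None, :] - clr[None, :, :]) ** 2).sum(axis=2)
        K = crbf_kernel(positive_table, gamma)
        np.testing.assert_allclose(K.values, np.exp(-gamma * d2), atol=1e-12)

    def test_rejects_non_positive_gamma(self, toy):
        with pytest.raises(ValueError, match="gamma"):
            crbf_kernel(toy, 0.0)


class TestCompositionalInvariance:
    def test_clin_crbf_invariant_to_per_sample_rescaling(self, rng):
        t = make_positive_table(rng, n=15, d=40)
        c = rng.uniform(0.1, 10.0, size=(t.n_samples, 1))
        scaled = t.with_values(t.values * c)
        np.testing.assert_allclose(clin_kernel(t).values, clin_kernel(scaled).values,
                                   atol=1e-10)
        np.testing.assert_allclose(crbf_kernel(t, 0.5).values,
                                   crbf_kernel(scaled, 0.5).values, atol=1e-10)


class TestJsk:
    def test_hand_values_and_bounds(self):
        t = AbundanceTable([[1, 0], [0, 1], [0.5, 0.5]], ["a", "b", "c"],
                           ["x", "y"], scale="relative")
        K = jsk_kernel(t)
        assert K.values[0, 1] == pytest.approx(1 - LN2, abs=1e-12)
        assert K.values[0, 2] == pytest.approx(1 - 1.5 * np.log(4 / 3) / 2, abs=1e-5)
        np.testing.assert_allclose(np.diag(K.values), 1.0)
        assert np.all(K.values >= 1 - LN2 - 1e-12) and np.all(K.values <= 1 + 1e-12)

    def test_matches_straight_line_reimplementation(self, rng):
        t = make_count_table(rng, n=10, d=15, zero_fraction=0.3).to_relative()
        K = jsk_kernel(t).values
        x = t.values
        for i in range(10):
            for j in range(10):
                total = 0.0
                for k in range(15):
                    s = x[i, k] + x[j, k]
                    if x[i, k] > 0:
                        total += x[i, k] * np.log(2 * x[i, k] / s)
                    if x[j, k] > 0:
                        total += x[j, k] * np.log(2 * x[j, k] / s)
                assert K[i, j] == pytest.approx(1 - total / 2, abs=1e-10)

    def test_count_input_is_closed_with_warning(self, count_table):
        with pytest.warns(UserWarning, match="relative"):
            K = jsk_kernel(count_table)
        np.testing.assert_allclose(K.values, jsk_kernel(count_table.to_relative()).values)


class TestQjac:
    def test_hand_values(self):
        t = AbundanceTable([[1, 2], [2, 1], [1, 0], [0, 1]],
                           ["a", "b", "c", "d"], ["x", "y"])
        K = qjac_kernel(t)
        assert K.values[0, 1] == pytest.approx(0.5)
        assert K.values[2, 3] == pytest.approx(0.0)
        np.testing.assert_allclose(np.diag(K.values), 1.0)

    def test_matches_min_max_loop_oracle(self, count_table):
        K = qjac_kernel(count_table).values
        x = count_table.values
        n = x.shape[0]
        for i in range(n):
            for j in range(n):
                num = np.minimum(x[i], x[j]).sum()
                den = np.maximum(x[i], x[j]).sum()
                expected = 1.0 if den == 0 else num / den
                assert K[i, j] == pytest.approx(expected, abs=1e-10)
        assert np.all(K >= 0) and np.all(K <= 1 + 1e-12)

    def test_all_zero_pair_is_one_with_warning(self):
        t = AbundanceTable([[0, 0], [0, 0], [1, 2]], ["a", "b", "c"], ["x", "y"])
        with pytest.warns(UserWarning, match="all-zero"):
            K = qjac_kernel(t)
        assert K.values[0, 1] == 1.0


class TestPsdSuite:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_four_kernels_are_psd(self, seed):
        t = make_count_table(None, n=30, d=40, zero_fraction=0.3, seed=seed)
        pos = replace_zeros(t, 0.5)
        mats = [clin_kernel(pos), crbf_kernel(pos, 0.5),
                jsk_kernel(t.to_relative()), qjac_kernel(t)]
        for K in mats:
            report = check_psd(K, tol=1e-8)
            assert report.passed, (K.meta["name"], report)

    def test_check_psd_identity_passes_indefinite_fails(self):
        assert check_psd(np.eye(4)).passed
        rep = check_psd(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert not rep.passed
        assert rep.min_eigenvalue == pytest.approx(-1.0)
        assert rep.max_eigenvalue == pytest.approx(3.0)

    def test_check_psd_rejects_non_square(self):
        with pytest.raises(ValueError, match="square"):
            check_psd(np.ones((2, 3)))


class TestKernelMatrixUtilities:
    def test_constructor_rejects_asymmetry(self):
        with pytest.raises(ValueError, match="symmetric"):
            KernelMatrix([[1.0, 0.5], [0.2, 1.0]], ["a", "b"])

    def test_center_constant_matrix_is_zero_and_idempotent(self, positive_table):
        C = KernelMatrix(np.full((4, 4), 3.0), list("abcd"))
        np.testing.assert_allclose(center_kernel(C).values, 0.0, atol=1e-12)
        K = clin_kernel(positive_table)
        Kc = center_kernel(K)
        np.testing.assert_allclose(center_kernel(Kc).values, Kc.values, atol=1e-10)
        np.testing.assert_allclose(Kc.values.sum(axis=0), 0.0, atol=1e-8)

    def test_center_equals_projector_product(self, rng):
        a = rng.normal(size=(10, 6))
        K = KernelMatrix(a @ a.T, [f"s{i}" for i in range(10)])
        J = np.eye(10) - np.ones((10, 10)) / 10
        np.testing.assert_allclose(center_kernel(K).values, J @ K.values @ J,
                                   atol=1e-10)

    def test_cosine_normalization(self, rng):
        K = KernelMatrix([[4.0, 3.0], [3.0, 9.0]], ["a", "b"])
        Kn = cosine_normalize_kernel(K)
        assert Kn.values[0, 1] == pytest.approx(0.5)
        np.testing.assert_allclose(np.diag(Kn.values), 1.0)
        # Cauchy-Schwarz on a random Gram matrix
        a = rng.normal(size=(12, 5))
        G = cosine_normalize_kernel(KernelMatrix(a @ a.T, [f"s{i}" for i in range(12)]))
        assert np.all(np.abs(G.values) <= 1 + 1e-12)

    def test_cosine_normalization_names_zero_diagonal_sample(self):
        K = KernelMatrix(np.diag([1.0, 0.0]), ["ok", "degenerate"])
        with pytest.raises(ValueError, match="degenerate"):
            cosine_normalize_kernel(K)

    def test_similarity_self_and_scale_invariance(self, positive_table):
        K = clin_kernel(positive_table)
        K5 = KernelMatrix(5.0 * K.values, K.sample_ids)
        sim = kernel_matrix_similarity([K, K5])
        np.testing.assert_allclose(sim, 1.0, atol=1e-10)

    def test_similarity_of_independent_kernels_is_low(self):
        sims = []
        for seed in range(5):
            t1 = make_positive_table(None, n=100, d=30, seed=seed)
            t2 = make_positive_table(None, n=100, d=30, seed=seed + 100)
            K2 = KernelMatrix(clin_kernel(t2).values, t1.sample_ids)
            sims.append(kernel_matrix_similarity([clin_kernel(t1), K2])[0, 1])
        assert np.median(sims) < 0.5

    def test_similarity_rejects_mismatched_ids(self, positive_table):
        K = clin_kernel(positive_table)
        other = KernelMatrix(K.values, [f"x{i}" for i in range(K.n_samples)])
        with pytest.raises(ValueError, match="sample_ids"):
            kernel_matrix_similarity([K, other])
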