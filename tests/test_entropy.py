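"""Differential/relative entropy estimators and the stimulation experiment."""

import numpy as np
import pytest
from math import e, log2, pi

from braindmf.entropy import (
    gaussian_entropy,
    kld_gaussian,
    knn_entropy,
    random_stimulation_entropy,
    svd_entropy,
)
from braindmf.errors import ValidationError

H1 = 0.5 * log2(2 * pi * e)  # entropy of a 1-D unit-variance Gaussian


class TestGaussianEntropy:
    def test_unit_variance_closed_form(self):
        assert gaussian_entropy(np.array([[1.0]])) == pytest.approx(H1, rel=1e-12)
        assert gaussian_entropy(np.eye(5)) == pytest.approx(5 * H1, rel=1e-12)

    def test_scaling_law(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((4, 4))
        cov = a @ a.T + 4 * np.eye(4)
        alpha = 3.7
        assert gaussian_entropy(alpha * cov) - gaussian_entropy(cov) == pytest.approx(
            4 / 2 * log2(alpha), rel=1e-10
        )

    def test_block_diagonal_additivity(self):
        rng = np.random.default_rng(1)
        blocks = []
        for d in (2, 3):
            a = rng.standard_normal((d, d))
            blocks.append(a @ a.T + d * np.eye(d))
        from scipy.linalg import block_diag

        total = gaussian_entropy(block_diag(*blocks))
        assert total == pytest.approx(sum(map(gaussian_entropy, blocks)), rel=1e-10)

    def test_singular_covariance_redirects(self):
        with pytest.raises(ValidationError, match="svd_entropy"):
            gaussian_entropy(np.ones((3, 3)))


class TestSvdEntropy:
    def test_full_rank_matches_gaussian_entropy(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((500, 4)) @ rng.standard_normal((4, 4))
        h, k = svd_entropy(x)
        assert k == 4
        assert h == pytest.approx(gaussian_entropy(np.cov(x, rowvar=False)), rel=1e-9)

    @pytest.mark.parametrize("r", [1, 2, 4])
    def test_rank_deficient_data_reports_k(self, r):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((200, r)) @ rng.standard_normal((r, 6))
        _, k = svd_entropy(x)
        assert k == r

    def test_invariant_to_variable_ordering(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((300, 5)) @ rng.standard_normal((5, 5))
        perm = rng.permutation(5)
        h1, k1 = svd_entropy(x)
        h2, k2 = svd_entropy(x[:, perm])
        assert (h1, k1) == (pytest.approx(h2, rel=1e-10), k2)

    def test_constant_data_rejected(self):
        from braindmf.errors import DegenerateDataError

        with pytest.raises(DegenerateDataError):
            svd_entropy(np.ones((10, 3)))


class TestKnnEntropy:
    def test_gaussian_ground_truth(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((10_000, 2))
        assert knn_entropy(x) == pytest.approx(2 * H1, abs=0.1)

    def test_affine_transformation_law(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((6000, 3))
        m = np.array([[2.0, 0.3, 0.0], [0.0, 1.5, -0.2], [0.1, 0.0, 0.8]])
        shift = knn_entropy(x @ m.T) - knn_entropy(x)
        assert shift == pytest.approx(log2(abs(np.linalg.det(m))), abs=0.15)

    def test_bias_shrinks_with_sample_size(self):
        rng = np.random.default_rng(7)
        truth = 3 * H1
        errs = [
            abs(knn_entropy(rng.standard_normal((n, 3))) - truth)
            for n in (500, 2000, 10_000)
        ]
        assert errs[2] < errs[0]

    def test_duplicates_need_jitter(self):
        x = np.zeros((20, 2))
        with pytest.raises(ValidationError):
            knn_entropy(x)
        assert np.isfinite(knn_entropy(x, jitter=1e-9))

    def test_cross_checks_parametric_estimator(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((3, 3))
        cov = a @ a.T + np.eye(3)
        x = rng.multivariate_normal(np.zeros(3), cov, size=20_000)
        assert knn_entropy(x) == pytest.approx(gaussian_entropy(cov), abs=0.15)


class TestKldGaussian:
    def test_zero_at_equality(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal((4, 4))
        cov = a @ a.T + np.eye(4)
        assert kld_gaussian(cov, cov) == pytest.approx(0.0, abs=1e-10)

    def test_commuting_closed_form(self):
        d = 6
        q = np.eye(d)
        expected = 0.5 * (2 * d - d * np.log(2.0) - d) / np.log(2.0)
        assert kld_gaussian(2 * q, q) == pytest.approx(expected, rel=1e-12)

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            a = rng.standard_normal((5, 5))
            b = rng.standard_normal((5, 5))
            kl = kld_gaussian(a @ a.T + np.eye(5), b @ b.T + np.eye(5))
            assert kl >= -1e-12

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            kld_gaussian(np.eye(3), np.eye(4))


class TestRandomStimulationEntropy:
    def test_zero_amplitude_changes_nothing(self, small_conn, small_params):
        rep = random_stimulation_entropy(
            small_conn, small_params, n_stims=3, n_targets=2, amplitude=0.0, seed=1
        )
        np.testing.assert_allclose(rep.H_task_E, rep.H_spont_E, rtol=1e-9)
        np.testing.assert_allclose(rep.KLD_task_I, rep.KLD_spont_I, rtol=1e-9)

    def test_entropy_drop_invariant_to_noise_amplitude(self, small_conn, small_params):
        """H_spont - H_task cancels any common rescaling of the intrinsic
        noise (both entropies shift by the same n/2 * log2 c)."""
        from dataclasses import replace

        drops = []
        for beta in (0.01, 0.02):
            rep = random_stimulation_entropy(
                small_conn, replace(small_params, beta=beta),
                n_stims=4, n_targets=2, amplitude=0.02, seed=2,
            )
            drops.append(rep.entropy_drop_E)
        np.testing.assert_allclose(drops[0], drops[1], rtol=1e-7)

    def test_deterministic_given_seed(self, small_conn, small_params):
        kw = dict(n_stims=3, n_targets=2, amplitude=0.02, seed=6)
        a = random_stimulation_entropy(small_conn, small_params, **kw)
        b = random_stimulation_entropy(small_conn, small_params, **kw)
        np.testing.assert_array_equal(a.H_task_E, b.H_task_E)
        assert a.protocols == b.protocols

    def test_correlated_noise_variant(self, small_conn, small_params):
        from braindmf.synthetic import generate_correlated_noise_covariance

        n2 = 2 * small_conn.n_regions
        ref = (small_params.beta * small_params.dt) ** 2
        qn = generate_correlated_noise_covariance(n2, 500, ref, seed=3)
        rep = random_stimulation_entropy(
            small_conn, small_params, n_stims=4, n_targets=2,
            amplitude=0.02, seed=4, Qn_mode="correlated", Qn=qn,
        )
        assert np.all(rep.entropy_drop_E > 0)
        assert np.all(rep.KLD_spont_E > rep.KLD_task_E)
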