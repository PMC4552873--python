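"""Moment solutions, autocovariance/ACF, spectra, and response metrics."""

import numpy as np
import pytest

from braindmf.errors import StabilityError, ValidationError
from braindmf.lna import (
    LYAPUNOV_RESIDUAL_TOL,
    MomentSolution,
    autocovariance,
    cross_spectrum,
    ellipsoid_volume,
    poincare_covariance,
    response_metrics,
    solve_moments,
    solve_moments_transient,
    synaptic_covariance,
)


def _ou_solution(a=3.0, q=2.0):
    """Two independent scalar Ornstein-Uhlenbeck processes dressed as a
    MomentSolution (one "node": an E and an I channel with identical a, q)."""
    A = -a * np.eye(2)
    Qn = q * np.eye(2)
    P = Qn / (2 * a)  # Lyapunov: -2 a P + q = 0
    return MomentSolution(
        mu=np.zeros(2), P=P, A=A, Qn=Qn, I_ext=np.zeros(2), u=np.zeros(2)
    )


class TestStationaryMoments:
    def test_lyapunov_residual_and_psd_covariance(self, small_conn, small_params):
        sol = solve_moments(small_conn, small_params)
        resid = np.linalg.norm(sol.A @ sol.P + sol.P @ sol.A.T + sol.Qn)
        assert resid / np.linalg.norm(sol.Qn) < LYAPUNOV_RESIDUAL_TOL
        np.testing.assert_allclose(sol.P, sol.P.T, atol=1e-18)
        assert np.linalg.eigvalsh(sol.P).min() > 0

    def test_unstable_operating_point_raises(self, ref_conn):
        from braindmf.fic import calibrate_fic, fixed_point_targets
        from braindmf.presets import default_params

        # beyond the regulable range the calibrated low-activity point
        # still exists algebraically but is linearly unstable
        params = default_params(G=8.0)
        res = calibrate_fic(ref_conn, params, verify=False)
        params = params.with_w_EI(res.w_EI)
        s_e, _, s_i = fixed_point_targets(params, 3.0)
        n = ref_conn.n_regions
        mu = np.concatenate([np.full(n, s_e), np.full(n, s_i)])
        with pytest.raises(StabilityError):
            solve_moments(ref_conn, params, S0=mu)

    def test_qn_rescaling_scales_covariance_linearly(self, small_conn, small_params):
        n2 = 2 * small_conn.n_regions
        sol1 = solve_moments(small_conn, small_params)
        sol4 = solve_moments(
            small_conn, small_params, Qn=4 * small_params.beta**2 * np.eye(n2)
        )
        np.testing.assert_allclose(sol4.P, 4 * sol1.P, rtol=1e-8)


class TestSynapticCovariance:
    def test_identity_map_returns_P(self, small_spont):
        n2 = small_spont.P.shape[0]
        np.testing.assert_allclose(
            synaptic_covariance(small_spont, np.eye(n2)), small_spont.P
        )

    def test_diagonal_nonnegative(self, small_spont, small_W):
        cv = synaptic_covariance(small_spont, small_W)
        assert np.all(np.diag(cv) >= 0)

    def test_dimension_mismatch_rejected(self, small_spont):
        with pytest.raises(ValidationError):
            synaptic_covariance(small_spont, np.eye(3))


class TestAutocovariance:
    def test_lag_zero_returns_P(self, small_spont):
        n2 = small_spont.P.shape[0]
        res = autocovariance(small_spont, np.eye(n2), np.arange(0.0, 4.0, 0.01))
        np.testing.assert_allclose(res.F_u_diag[0], np.diag(small_spont.P))
        np.testing.assert_allclose(res.acf[0], 1.0)

    def test_scalar_ou_closed_form(self):
        a = 4.0
        sol = _ou_solution(a=a)
        tau = np.arange(0.0, 1.5, 0.001)
        res = autocovariance(sol, np.eye(2), tau)
        np.testing.assert_allclose(res.acf[:, 0], np.exp(-a * tau), rtol=1e-6)
        # T95: exp(-a t) = 0.05  =>  t = ln(20)/a
        assert res.T95_E == pytest.approx(np.log(20.0) / a, rel=1e-3)

    def test_grid_too_short_raises(self):
        sol = _ou_solution(a=0.5)
        with pytest.raises(ValidationError):
            autocovariance(sol, np.eye(2), np.arange(0.0, 0.2, 0.01))

    def test_decays_to_zero_for_stable_dynamics(self, small_spont, small_W):
        tau = np.arange(0.0, 4.0, 0.004)
        res = autocovariance(small_spont, small_W, tau)
        assert np.max(np.abs(res.acf[-1])) < 0.01


class TestCrossSpectrum:
    def test_scalar_ou_lorentzian(self):
        a, q = 3.0, 2.0
        sol = _ou_solution(a=a, q=q)
        freqs = np.linspace(0.01, 50, 200)
        spec = cross_spectrum(sol, np.eye(2), freqs)
        omega = 2 * np.pi * freqs
        np.testing.assert_allclose(
            spec.psd_u[:, 0], q / (a**2 + omega**2), rtol=1e-10
        )

    def test_parseval_variance_recovery(self):
        """(1/2pi) Integral S(w) dw over the real line equals the variance."""
        a, q = 5.0, 3.0
        sol = _ou_solution(a=a, q=q)
        freqs = np.logspace(-4, 4, 4000)
        spec = cross_spectrum(sol, np.eye(2), freqs)
        var = 2.0 * np.trapezoid(spec.psd_u[:, 0], freqs)  # two-sided, even
        assert var == pytest.approx(q / (2 * a), rel=0.01)

    def test_parseval_on_network(self, small_spont, small_W):
        freqs = np.logspace(-3, 4, 3000)
        spec = cross_spectrum(small_spont, small_W, freqs)
        var = 2.0 * np.trapezoid(spec.psd_u, freqs, axis=0)
        cv = np.diag(synaptic_covariance(small_spont, small_W))
        np.testing.assert_allclose(var, cv, rtol=0.01)

    def test_hermitian_cross_spectra(self, small_spont, small_W):
        spec = cross_spectrum(
            small_spont, small_W, np.array([0.1, 1.0, 10.0]), keep_cross=True
        )
        for mat in spec.cross_u:
            np.testing.assert_allclose(mat, mat.conj().T, atol=1e-18)
        assert np.all(spec.psd_u >= 0)


class TestResponseMetrics:
    def test_zero_input_gives_zero_deltas(self, small_conn, small_params, small_W):
        a = solve_moments(small_conn, small_params)
        b = solve_moments(small_conn, small_params)
        m = response_metrics(a, b, small_W)
        np.testing.assert_allclose(m.delta_m, 0.0, atol=1e-8)
        np.testing.assert_allclose(m.delta_sigma2, 0.0, atol=1e-6)

    def test_noise_rescaling_leaves_relative_metrics_invariant(
        self, small_conn, small_params, small_W
    ):
        n2 = 2 * small_conn.n_regions
        i_ext = np.zeros(small_conn.n_regions)
        i_ext[:2] = 0.02
        freqs = np.logspace(-2, 2, 80)
        tau = np.arange(0.0, 3.0, 0.003)
        results = []
        for c in (1.0, 4.0):
            qn = c * small_params.beta**2 * np.eye(n2)
            spont = solve_moments(small_conn, small_params, Qn=qn)
            task = solve_moments(small_conn, small_params, I_ext=i_ext, Qn=qn,
                                 S0=spont.mu)
            m = response_metrics(
                spont, task, small_W,
                cross_spectrum(spont, small_W, freqs),
                cross_spectrum(task, small_W, freqs),
                direct_nodes=np.array([0, 1]),
            )
            ac = autocovariance(spont, small_W, tau)
            results.append((m.delta_sigma2, m.delta_psd, ac.acf, ac.T95_E,
                            m.fc_similarity))
        for x, y in zip(results[0], results[1]):
            np.testing.assert_allclose(x, y, rtol=1e-6, atol=1e-9)

    def test_mismatched_spectral_grids_rejected(self, small_spont, small_W):
        s1 = cross_spectrum(small_spont, small_W, np.array([1.0, 2.0]))
        s2 = cross_spectrum(small_spont, small_W, np.array([1.0, 3.0]))
        with pytest.raises(ValidationError):
            response_metrics(small_spont, small_spont, small_W, s1, s2)


class TestTransientMoments:
    def test_zero_input_stays_stationary(self, small_conn, small_params, small_W):
        spont = solve_moments(small_conn, small_params)
        t_grid = np.linspace(0.0, 0.3, 7)
        tm = solve_moments_transient(
            small_conn, small_params, lambda t: np.zeros(small_conn.n_regions),
            t_grid, init=spont,
        )
        var0 = np.diag(synaptic_covariance(spont, small_W))
        for k in range(t_grid.size):
            np.testing.assert_allclose(tm.var_u[k], var0, rtol=1e-4)
            np.testing.assert_allclose(tm.mu[k], spont.mu, atol=1e-8)

    def test_constant_input_relaxes_to_task_stationary(
        self, small_conn, small_params, small_W
    ):
        i_ext = np.zeros(small_conn.n_regions)
        i_ext[0] = 0.02
        spont = solve_moments(small_conn, small_params)
        task = solve_moments(small_conn, small_params, I_ext=i_ext, S0=spont.mu)
        tm = solve_moments_transient(
            small_conn, small_params, lambda t: i_ext,
            np.linspace(0.0, 3.0, 4), init=spont,
        )
        np.testing.assert_allclose(tm.mu[-1], task.mu, atol=1e-6)
        np.testing.assert_allclose(
            tm.var_u[-1], np.diag(synaptic_covariance(task, small_W)), rtol=1e-3
        )


class TestOccupancyVolumes:
    def test_ellipsoid_volume_unit_sphere(self):
        from math import pi
        from scipy.stats import chi2

        # 3-D identity covariance: V = (4/3) pi r^3 with r^2 = chi2_3(0.95)
        r3 = chi2.ppf(0.95, df=3) ** 1.5
        assert ellipsoid_volume(np.eye(3)) == pytest.approx(4 / 3 * pi * r3)

    def test_volume_shrinks_with_covariance(self):
        cov = np.diag([1.0, 2.0, 3.0])
        assert ellipsoid_volume(0.5 * cov) < ellipsoid_volume(cov)

    def test_poincare_covariance_is_toeplitz_psd(self, small_spont, small_W):
        c = poincare_covariance(small_spont, small_W, node=0, tau=0.2)
        assert c.shape == (3, 3)
        assert c[0, 1] == pytest.approx(c[1, 2])
        assert np.linalg.eigvalsh(c).min() > 0
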