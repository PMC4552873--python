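"""Linear noise approximation (LNA) around the deterministic fixed point.

For weak intrinsic noise the gating fluctuations dS around the stationary
mean mu obey a multivariate Ornstein-Uhlenbeck process governed by the
Jacobian A of the drift, so all second-order statistics are available in
closed form:

* stationary covariance P from the algebraic Lyapunov equation
  A P + P A^T + Qn = 0, with Qn the intrinsic-noise covariance;
* synaptic-current covariance Cv = W P W^T (currents are a linear map of
  gating states);
* stationary autocovariance F_S(tau) = exp(tau A) P, hence
  F_u(tau) = W F_S(tau) W^T, the per-node autocorrelation
  ACF_i(tau) = F_u,ii(tau) / F_u,ii(0), and the temporal-memory scale T95
  (first lag at which the population-averaged ACF decays to 0.05);
* cross-spectra Pi_S(w) = (A + iw)^-1 Qn (A^T - iw)^-1 and
  Pi_u(w) = W Pi_S(w) W^dagger, whose real diagonal is the synaptic PSD.

Fourier convention: two-sided angular-frequency spectra with
variance = (1/2pi) Integral S(w) dw; all public grids are in Hz.

A time-varying-mean extension integrates dP/dt = A(mu(t)) P + P A(mu(t))^T
+ Qn jointly with the mean equations to follow the transient after
stimulus onset/offset.

Stimulus-response metrics (percent changes of mean, variance and PSD, the
FC similarity, and pairwise covariance/correlation changes) compare a task
solution against the spontaneous one on identical grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm, solve_continuous_lyapunov
from scipy.optimize import root
from scipy.stats import chi2, pearsonr

from .data_io import Connectome
from .errors import StabilityError, ValidationError
from .model import (
    DMFParams,
    background_current,
    coupling_matrix,
    drift,
    expand_external,
    jacobian,
    synaptic_currents,
)

__all__ = [
    "MomentSolution",
    "SpectralSolution",
    "AutocovResult",
    "TransientMoments",
    "ResponseMetrics",
    "solve_fixed_point",
    "solve_moments",
    "solve_moments_transient",
    "synaptic_covariance",
    "autocovariance",
    "cross_spectrum",
    "response_metrics",
    "ellipsoid_volume",
    "poincare_covariance",
]

LYAPUNOV_RESIDUAL_TOL = 1e-8


@dataclass
class MomentSolution:
    """Stationary first and second moments for one condition."""

    mu: np.ndarray          # 2N stationary gating means
    P: np.ndarray           # 2N x 2N gating covariance
    A: np.ndarray           # Jacobian at mu
    Qn: np.ndarray          # noise covariance
    I_ext: np.ndarray       # applied external input (2N)
    u: np.ndarray           # stationary synaptic currents (2N)
    converged: bool = True

    @property
    def n_regions(self) -> int:
        return self.mu.size // 2


@dataclass
class SpectralSolution:
    freqs_hz: np.ndarray
    psd_u: np.ndarray                     # (n_freq, 2N), real, >= 0
    cross_u: np.ndarray | None = None     # (n_freq, 2N, 2N) complex, optional


@dataclass
class AutocovResult:
    tau: np.ndarray
    F_u_diag: np.ndarray   # (n_tau, 2N) autocovariance of currents
    acf: np.ndarray        # (n_tau, 2N) per-node ACF
    T95_E: float
    T95_I: float


@dataclass
class TransientMoments:
    t: np.ndarray
    mu: np.ndarray         # (T, 2N)
    var_u: np.ndarray      # (T, 2N) instantaneous current variances
    mean_u: np.ndarray     # (T, 2N) instantaneous mean currents
    P: np.ndarray | None = None  # (T, 2N, 2N) when stored


@dataclass
class ResponseMetrics:
    delta_m: np.ndarray            # (2N,) percent change of mean currents
    delta_sigma2: np.ndarray       # (2N,) percent change of current variance
    delta_psd: np.ndarray | None   # (n_freq, 2N) percent change of PSD
    freqs_hz: np.ndarray | None
    corr_dm_dsigma2_E: float
    corr_dm_dsigma2_I: float
    fc_similarity: float
    cov_rel_change: np.ndarray     # upper-triangle E-pairs, percent
    corr_diff: np.ndarray          # upper-triangle E-pairs, spont - task
    dpsd_min_freq: dict | None     # {"direct_E":..., "indirect_E":..., ...}


def _qn_default(params: DMFParams, n: int) -> np.ndarray:
    return params.beta**2 * np.eye(2 * n)


def solve_fixed_point(
    conn: Connectome,
    params: DMFParams,
    I_ext: np.ndarray | None = None,
    S0: np.ndarray | None = None,
    warmup: float = 2.0,
) -> np.ndarray:
    """Deterministic fixed point via Euler warm-up plus Newton polishing."""
    n = conn.n_regions
    I_full = np.zeros(2 * n) if I_ext is None else expand_external(I_ext, n)
    W = coupling_matrix(conn, params)
    I_const = background_current(params, n) + I_full
    if S0 is None:
        s = np.full(2 * n, 0.1)
        steps = int(round(warmup / params.dt))
        for _ in range(steps):
            s = s + params.dt * drift(s, conn, params, W=W, I_const=I_const)
    else:
        s = np.array(S0, dtype=float)

    sol = root(
        lambda x: drift(x, conn, params, W=W, I_const=I_const),
        s,
        jac=lambda x: jacobian(x, conn, params, I_ext=I_full),
        method="hybr",
        tol=1e-13,
    )
    s_star = sol.x
    res = np.max(np.abs(drift(s_star, conn, params, W=W, I_const=I_const)))
    if not (np.all(np.isfinite(s_star)) and res < 1e-8):
        raise StabilityError(f"fixed-point search failed (residual {res:.2e})")
    return s_star


def solve_moments(
    conn: Connectome,
    params: DMFParams,
    I_ext: np.ndarray | None = None,
    mode: str = "stationary",
    t_grid: np.ndarray | None = None,
    Qn: np.ndarray | None = None,
    S0: np.ndarray | None = None,
) -> MomentSolution | TransientMoments:
    """Moments of the linearized dynamics under a (possibly zero) input.

    Stationary mode evaluates the fixed point, its Jacobian, and the
    Lyapunov covariance; transient mode delegates to
    :func:`solve_moments_transient` with a constant input on ``t_grid``.
    """
    n = conn.n_regions
    if Qn is None:
        Qn = _qn_default(params, n)
    if mode == "transient":
        if t_grid is None:
            raise ValidationError("transient mode requires t_grid")
        I_full = np.zeros(2 * n) if I_ext is None else expand_external(I_ext, n)
        return solve_moments_transient(conn, params, lambda t: I_full, t_grid, Qn=Qn)
    if mode != "stationary":
        raise ValidationError(f"unknown mode {mode!r}")

    I_full = np.zeros(2 * n) if I_ext is None else expand_external(I_ext, n)
    mu = solve_fixed_point(conn, params, I_ext=I_full, S0=S0)
    A = jacobian(mu, conn, params, I_ext=I_full)
    lam_max = np.max(np.linalg.eigvals(A).real)
    if lam_max >= 0:
        raise StabilityError(f"Jacobian has eigenvalue with Re = {lam_max:.3e} >= 0")
    P = solve_continuous_lyapunov(A, -Qn)
    P = 0.5 * (P + P.T)
    resid = np.linalg.norm(A @ P + P @ A.T + Qn) / np.linalg.norm(Qn)
    if resid > LYAPUNOV_RESIDUAL_TOL:
        raise StabilityError(f"Lyapunov residual {resid:.2e} exceeds tolerance")
    u = synaptic_currents(mu, conn, params, I_ext=I_full)
    return MomentSolution(mu=mu, P=P, A=A, Qn=Qn, I_ext=I_full, u=u)


def solve_moments_transient(
    conn: Connectome,
    params: DMFParams,
    I_ext_fn,
    t_grid: np.ndarray,
    Qn: np.ndarray | None = None,
    init: MomentSolution | None = None,
    store_P: bool = False,
) -> TransientMoments:
    """Integrate mean and covariance ODEs with the Jacobian re-evaluated
    along the instantaneous mean (dP/dt = A(mu)P + PA(mu)^T + Qn).

    ``I_ext_fn(t)`` returns the external input (length N or 2N) at time t.
    Starts from ``init`` (default: the spontaneous stationary solution) and
    reports means/variances of the synaptic currents on ``t_grid``.
    """
    n = conn.n_regions
    if Qn is None:
        Qn = _qn_default(params, n)
    if init is None:
        init = solve_moments(conn, params, I_ext=None, Qn=Qn)
    t_grid = np.asarray(t_grid, dtype=float)
    mu = init.mu.copy()
    P = init.P.copy()
    W = coupling_matrix(conn, params)
    I0 = background_current(params, n)
    dt = params.dt

    out_mu = np.empty((t_grid.size, 2 * n))
    out_var = np.empty((t_grid.size, 2 * n))
    out_mean_u = np.empty((t_grid.size, 2 * n))
    out_P = np.empty((t_grid.size, 2 * n, 2 * n)) if store_P else None

    t = t_grid[0]
    for k, t_next in enumerate(t_grid):
        while t < t_next - 1e-12:
            h = min(dt, t_next - t)
            I_full = expand_external(np.asarray(I_ext_fn(t)), n)
            A = jacobian(mu, conn, params, I_ext=I_full)
            mu = mu + h * drift(mu, conn, params, W=W, I_const=I0 + I_full)
            P = P + h * (A @ P + P @ A.T + Qn)
            t += h
        I_full = expand_external(np.asarray(I_ext_fn(t)), n)
        out_mu[k] = mu
        out_mean_u[k] = W @ mu + I0 + I_full
        out_var[k] = np.einsum("ij,jk,ik->i", W, P, W)
        if store_P:
            out_P[k] = P.copy()
    return TransientMoments(t=t_grid, mu=out_mu, var_u=out_var, mean_u=out_mean_u, P=out_P)


def synaptic_covariance(sol: MomentSolution, W: np.ndarray) -> np.ndarray:
    """Covariance of synaptic currents, Cv = W P W^T."""
    if W.shape[0] != sol.P.shape[0]:
        raise ValidationError(
            f"W is {W.shape}, P is {sol.P.shape}: dimensions do not match"
        )
    cv = W @ sol.P @ W.T
    return 0.5 * (cv + cv.T)


def _t95(tau: np.ndarray, acf_avg: np.ndarray, level: float = 0.05) -> float:
    below = np.flatnonzero(acf_avg <= level)
    if below.size == 0:
        raise ValidationError(
            "population ACF never decays to the 0.05 level within the tau "
            "grid; extend the grid"
        )
    j = below[0]
    if j == 0:
        return float(tau[0])
    # linear interpolation between the bracketing grid points
    t0, t1 = tau[j - 1], tau[j]
    a0, a1 = acf_avg[j - 1], acf_avg[j]
    return float(t0 + (a0 - level) / (a0 - a1) * (t1 - t0))


def autocovariance(
    sol: MomentSolution,
    W: np.ndarray,
    tau_grid: np.ndarray,
    level: float = 0.05,
) -> AutocovResult:
    """Stationary autocovariance of currents on a uniform lag grid.

    Propagates F_S(tau) = exp(tau A) P by repeated application of the
    single-step matrix exponential, and reports the per-node current
    autocovariance diag(W F_S W^T), per-node ACFs, and the population
    T95 timescales computed on the node-averaged ACF of each population.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid[0] != 0:
        raise ValidationError("tau grid must start at 0")
    steps = np.diff(tau_grid)
    if steps.size and not np.allclose(steps, steps[0], rtol=1e-9):
        raise ValidationError("tau grid must be uniform")
    n2 = sol.P.shape[0]
    n = n2 // 2
    F = sol.P.copy()
    E1 = expm(steps[0] * sol.A) if steps.size else None
    diag_u = np.empty((tau_grid.size, n2))
    for k in range(tau_grid.size):
        diag_u[k] = np.einsum("ij,jk,ik->i", W, F, W)
        if E1 is not None and k < tau_grid.size - 1:
            F = E1 @ F
    acf = diag_u / diag_u[0]
    t95_e = _t95(tau_grid, acf[:, :n].mean(axis=1), level)
    t95_i = _t95(tau_grid, acf[:, n:].mean(axis=1), level)
    return AutocovResult(tau=tau_grid, F_u_diag=diag_u, acf=acf, T95_E=t95_e, T95_I=t95_i)


def default_freq_grid(f_min: float = 0.01, f_max: float = 200.0, n: int = 400) -> np.ndarray:
    """Logarithmic frequency grid (Hz) resolving the ~9 Hz PSD minimum."""
    return np.logspace(np.log10(f_min), np.log10(f_max), n)


def cross_spectrum(
    sol: MomentSolution,
    W: np.ndarray,
    freqs_hz: np.ndarray,
    keep_cross: bool = False,
) -> SpectralSolution:
    """Cross-spectral matrices of synaptic currents on a frequency grid."""
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    n2 = sol.A.shape[0]
    eye = np.eye(n2)
    # Qn = L L^T so that diag(W Pi_S W^T) = || W (A+iw)^-1 L ||^2 row-wise,
    # which is exactly non-negative at every frequency
    L = np.linalg.cholesky(sol.Qn + 0.0 * eye)
    psd = np.empty((freqs_hz.size, n2))
    cross = np.empty((freqs_hz.size, n2, n2), dtype=complex) if keep_cross else None
    for k, f in enumerate(freqs_hz):
        w = 2.0 * np.pi * f
        M = sol.A + 1j * w * eye
        B = W @ np.linalg.solve(M, L)
        psd[k] = np.sum(B.real**2 + B.imag**2, axis=1)
        if keep_cross:
            cross[k] = B @ B.conj().T
    return SpectralSolution(freqs_hz=freqs_hz, psd_u=psd, cross_u=cross)


def _refined_argmin(logf: np.ndarray, y: np.ndarray) -> float:
    """Parabolic refinement of the minimum location on a log-frequency axis."""
    j = int(np.nanargmin(y))
    if j == 0 or j == y.size - 1:
        return float(10 ** logf[j])
    x0, x1, x2 = logf[j - 1 : j + 2]
    y0, y1, y2 = y[j - 1 : j + 2]
    denom = (y0 - 2 * y1 + y2)
    if denom <= 0:
        return float(10 ** x1)
    x_min = x1 + 0.5 * (y0 - y2) / denom * (x2 - x0) / 2.0
    return float(10 ** x_min)


def _corr_from_cov(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def response_metrics(
    spont: MomentSolution,
    task: MomentSolution,
    W: np.ndarray,
    spec_spont: SpectralSolution | None = None,
    spec_task: SpectralSolution | None = None,
    direct_nodes: np.ndarray | None = None,
) -> ResponseMetrics:
    """Percent-change statistics of the task condition vs the spontaneous one.

    ``direct_nodes`` lists the indices of regions receiving the external
    input ("direct"); all other regions count as "indirect" when locating
    the frequency of maximal PSD reduction.
    """
    n2 = spont.mu.size
    n = n2 // 2
    cv_s = synaptic_covariance(spont, W)
    cv_t = synaptic_covariance(task, W)
    delta_m = 100.0 * (task.u / spont.u - 1.0)
    var_s, var_t = np.diag(cv_s), np.diag(cv_t)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta_sigma2 = np.where(var_s > 0, 100.0 * (var_t / var_s - 1.0), np.nan)

    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        if np.allclose(a, a[0]) or np.allclose(b, b[0]):
            return float("nan")
        return float(pearsonr(a, b)[0])

    corr_e = _corr(delta_m[:n], delta_sigma2[:n])
    corr_i = _corr(delta_m[n:], delta_sigma2[n:])

    iu = np.triu_indices(n, k=1)
    r_s = _corr_from_cov(cv_s[:n, :n])[iu]
    r_t = _corr_from_cov(cv_t[:n, :n])[iu]
    fc_sim = _corr(r_s, r_t) if r_s.size > 1 else float("nan")
    cov_rel = 100.0 * (cv_t[:n, :n][iu] / cv_s[:n, :n][iu] - 1.0)
    corr_diff = r_s - r_t

    delta_psd = None
    freqs = None
    minima = None
    if spec_spont is not None and spec_task is not None:
        if spec_spont.freqs_hz.shape != spec_task.freqs_hz.shape or not np.allclose(
            spec_spont.freqs_hz, spec_task.freqs_hz
        ):
            raise ValidationError("spectral grids of the two conditions differ")
        freqs = spec_spont.freqs_hz
        with np.errstate(divide="ignore", invalid="ignore"):
            delta_psd = np.where(
                spec_spont.psd_u > 0,
                100.0 * (spec_task.psd_u / spec_spont.psd_u - 1.0),
                np.nan,
            )
        if direct_nodes is not None:
            direct = np.asarray(direct_nodes, dtype=int)
            indirect = np.setdiff1d(np.arange(n), direct)
            logf = np.log10(freqs)
            minima = {
                "direct_E": _refined_argmin(logf, delta_psd[:, direct].mean(axis=1)),
                "indirect_E": _refined_argmin(logf, delta_psd[:, indirect].mean(axis=1)),
                "direct_I": _refined_argmin(logf, delta_psd[:, n + direct].mean(axis=1)),
                "indirect_I": _refined_argmin(logf, delta_psd[:, n + indirect].mean(axis=1)),
            }
    return ResponseMetrics(
        delta_m=delta_m,
        delta_sigma2=delta_sigma2,
        delta_psd=delta_psd,
        freqs_hz=freqs,
        corr_dm_dsigma2_E=corr_e,
        corr_dm_dsigma2_I=corr_i,
        fc_similarity=fc_sim,
        cov_rel_change=cov_rel,
        corr_diff=corr_diff,
        dpsd_min_freq=minima,
    )


def ellipsoid_volume(cov: np.ndarray, confidence: float = 0.95) -> float:
    """Volume of the multivariate-normal confidence ellipsoid.

    For an n-dimensional Gaussian the region of probability ``confidence``
    is the ellipsoid x^T cov^-1 x <= chi2_n(confidence), with volume
    V = V_n(unit ball) * chi2^(n/2) * sqrt(det cov).
    """
    from math import gamma, pi

    cov = np.asarray(cov, dtype=float)
    d = cov.shape[0]
    r2 = chi2.ppf(confidence, df=d)
    unit = pi ** (d / 2) / gamma(d / 2 + 1)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValidationError("covariance must be positive definite")
    return float(unit * r2 ** (d / 2) * np.exp(0.5 * logdet))


def poincare_covariance(
    sol: MomentSolution, W: np.ndarray, node: int, tau: float, order: int = 3
) -> np.ndarray:
    """Covariance of the delay-embedded current (u(t), u(t+tau), ...).

    The stationary lagged covariances F_u(k*tau) of one node fill a Toeplitz
    matrix — the second-moment description of the Poincare-map cloud used
    to visualise temporal state-space occupancy.
    """
    E = expm(tau * sol.A)
    F = sol.P.copy()
    lags = []
    for _ in range(order):
        lags.append(float(W[node] @ F @ W[node]))
        F = E @ F
    out = np.empty((order, order))
    for i in range(order):
        for j in range(order):
            out[i, j] = lags[abs(i - j)]
    return out
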