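"""Differential entropy, relative entropy, and the model-side entropy
experiments.

For an n-dimensional Gaussian with covariance Sigma the differential
entropy in bits is H = (1/2) log2((2*pi*e)^n det Sigma); rank-deficient
sample covariances are handled by restricting the determinant to the k
non-zero singular values.  A nonparametric nearest-neighbour estimator is
provided as a normality-free cross-check.  The relative entropy (KLD)
between the intrinsic-noise Gaussian and the synaptic-activity Gaussian
quantifies how much uncertainty the network dynamics add on top of the
noise that drives them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import e, lgamma, log, pi

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial import cKDTree
from scipy.special import digamma

from .data_io import Connectome
from .errors import DegenerateDataError, ValidationError
from .lna import MomentSolution, solve_moments, synaptic_covariance
from .model import DMFParams, coupling_matrix

__all__ = [
    "gaussian_entropy",
    "svd_entropy",
    "knn_entropy",
    "kld_gaussian",
    "EntropyReport",
    "random_stimulation_entropy",
]

LN2 = log(2.0)


def gaussian_entropy(cov: np.ndarray) -> float:
    """Differential entropy (bits) of a Gaussian with covariance ``cov``.

    Computed through the Cholesky log-determinant; raises on non-positive-
    definite input (use :func:`svd_entropy` for rank-deficient sample
    covariances).
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim == 0 or cov.size == 1:
        cov = cov.reshape(1, 1)
    n = cov.shape[0]
    try:
        c, _ = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "covariance is not positive definite; for rank-deficient sample "
            "covariances use svd_entropy"
        ) from exc
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    return float((n * log(2.0 * pi * e) + logdet) / (2.0 * LN2))


def svd_entropy(
    data: np.ndarray, rank_tol_factor: float = 1e6
) -> tuple[float, int]:
    """Gaussian entropy (bits) of sample data via rank-truncated spectrum.

    Forms the sample covariance of the (samples x variables) matrix and
    replaces its determinant by the product of the k singular values above
    the tolerance max(lambda) * n * eps * rank_tol_factor, eluding exact or
    near singularity (short windows, preprocessing-induced rank loss).
    Returns (H, k).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("need a 2-D (samples x variables) matrix, >= 2 samples")
    cov = np.cov(x, rowvar=False)
    cov = np.atleast_2d(cov)
    lam = np.linalg.svd(cov, compute_uv=False)
    if lam[0] <= 0:
        raise DegenerateDataError("data carries no variance")
    tol = lam[0] * cov.shape[0] * np.finfo(float).eps * rank_tol_factor
    keep = lam > tol
    k = int(np.count_nonzero(keep))
    h = (k * (1.0 + log(2.0 * pi)) + np.sum(np.log(lam[keep]))) / (2.0 * LN2)
    return float(h), k


def knn_entropy(
    data: np.ndarray, k_neighbors: int = 1, jitter: float = 0.0, seed: int = 0
) -> float:
    """Nearest-neighbour differential-entropy estimate in bits.

    The classical k-NN estimator: with eps_i the distance from sample i to
    its k-th neighbour among the m samples in d dimensions,

        H_nats = psi(m) - psi(k) + log V_d + (d/m) * sum_i log eps_i,

    V_d the unit-ball volume.  Duplicated points give log 0; pass a small
    ``jitter`` to break ties, otherwise a tie error is raised.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValidationError("need a 2-D (samples x variables) matrix")
    m, d = x.shape
    if m <= k_neighbors:
        raise ValidationError(f"{m} samples cannot support k = {k_neighbors}")
    if jitter > 0:
        x = x + np.random.default_rng(seed).normal(0.0, jitter, size=x.shape)
    tree = cKDTree(x)
    dist, _ = tree.query(x, k=k_neighbors + 1)
    eps = dist[:, -1]
    if np.any(eps == 0):
        raise ValidationError(
            "duplicate points: nearest-neighbour distance is 0 (pass jitter>0)"
        )
    log_vd = (d / 2.0) * log(pi) - lgamma(d / 2.0 + 1.0)
    h_nats = digamma(m) - digamma(k_neighbors) + log_vd + d * np.mean(np.log(eps))
    return float(h_nats / LN2)


def kld_gaussian(Cv: np.ndarray, Qn: np.ndarray) -> float:
    """KL divergence (bits) from N(0, Cv) to N(0, Qn).

    KLD = (1/2) [trace(Qn^-1 Cv) - ln(det Cv / det Qn) - d] / ln 2 — the
    relative entropy between the observed-activity Gaussian and the
    intrinsic-noise Gaussian.  Uses Cholesky solves; never forms explicit
    inverses.
    """
    Cv = np.atleast_2d(np.asarray(Cv, dtype=float))
    Qn = np.atleast_2d(np.asarray(Qn, dtype=float))
    if Cv.shape != Qn.shape:
        raise ValidationError(f"dimension mismatch: {Cv.shape} vs {Qn.shape}")
    d = Cv.shape[0]
    try:
        cq = cho_factor(Qn, lower=True)
        cc = cho_factor(Cv, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("both covariances must be positive definite") from exc
    tr = float(np.trace(cho_solve(cq, Cv)))
    logdet_c = 2.0 * np.sum(np.log(np.diag(cc[0])))
    logdet_q = 2.0 * np.sum(np.log(np.diag(cq[0])))
    return float(0.5 * (tr - (logdet_c - logdet_q) - d) / LN2)


@dataclass
class EntropyReport:
    """Per-stimulation entropies and relative entropies, split by population."""

    H_spont_E: float
    H_spont_I: float
    H_task_E: np.ndarray
    H_task_I: np.ndarray
    KLD_spont_E: float
    KLD_spont_I: float
    KLD_task_E: np.ndarray
    KLD_task_I: np.ndarray
    protocols: list = field(default_factory=list)
    estimator: str = "gaussian"

    @property
    def entropy_drop_E(self) -> np.ndarray:
        return self.H_spont_E - self.H_task_E

    @property
    def entropy_drop_I(self) -> np.ndarray:
        return self.H_spont_I - self.H_task_I


def random_stimulation_entropy(
    conn: Connectome,
    params: DMFParams,
    n_stims: int = 500,
    n_targets: int = 8,
    amplitude: float = 0.02,
    seed: int = 0,
    Qn_mode: str = "diagonal",
    Qn: np.ndarray | None = None,
) -> EntropyReport:
    """Entropy and relative entropy across many random stimulation patterns.

    Each "task" imposes ``amplitude`` nA on the excitatory populations of
    ``n_targets`` randomly selected regions; for each, the stationary
    synaptic-current covariance is split into its excitatory and inhibitory
    blocks and compared with the spontaneous condition.

    Noise conventions.  One covariance SHAPE plays two roles at two scales:
    the dynamical noise driving the Lyapunov equation has intensity beta^2
    (consistent with the Euler discretization of the simulator), while the
    intrinsic-noise distribution referenced by the relative entropy is the
    per-step noise with covariance (beta*dt)^2 * shape.  Entropy
    differences are invariant to this split; the KLD ordering is not,
    which is why the reference scale is fixed explicitly.  ``Qn_mode``
    either keeps the noise uncorrelated ("diagonal") or takes a supplied
    non-diagonal ``Qn`` ("correlated", e.g. a finite-sample scatter
    matrix) interpreted at the reference scale.  Deterministic given
    ``seed``.
    """
    n = conn.n_regions
    if Qn_mode not in ("diagonal", "correlated"):
        raise ValidationError(f"unknown Qn_mode {Qn_mode!r}")
    ref_scale = (params.beta * params.dt) ** 2
    if Qn_mode == "correlated":
        if Qn is None:
            raise ValidationError("Qn_mode='correlated' requires a Qn matrix")
        qn_ref = np.asarray(Qn, dtype=float)
    else:
        qn_ref = ref_scale * np.eye(2 * n)
    qn_dyn = qn_ref * (params.beta**2 / ref_scale)
    rng = np.random.default_rng(seed)
    W = coupling_matrix(conn, params)

    spont = solve_moments(conn, params, Qn=qn_dyn)
    cv0 = synaptic_covariance(spont, W)
    qe, qi = qn_ref[:n, :n], qn_ref[n:, n:]
    h0_e = gaussian_entropy(cv0[:n, :n])
    h0_i = gaussian_entropy(cv0[n:, n:])
    k0_e = kld_gaussian(cv0[:n, :n], qe)
    k0_i = kld_gaussian(cv0[n:, n:], qi)

    h_e = np.empty(n_stims)
    h_i = np.empty(n_stims)
    kl_e = np.empty(n_stims)
    kl_i = np.empty(n_stims)
    protocols = []
    for s in range(n_stims):
        targets = np.sort(rng.choice(n, size=n_targets, replace=False))
        i_ext = np.zeros(n)
        i_ext[targets] = amplitude
        task = solve_moments(conn, params, I_ext=i_ext, Qn=qn_dyn, S0=spont.mu)
        cv = synaptic_covariance(task, W)
        h_e[s] = gaussian_entropy(cv[:n, :n])
        h_i[s] = gaussian_entropy(cv[n:, n:])
        kl_e[s] = kld_gaussian(cv[:n, :n], qe)
        kl_i[s] = kld_gaussian(cv[n:, n:], qi)
        protocols.append(targets.tolist())
    return EntropyReport(
        H_spont_E=h0_e,
        H_spont_I=h0_i,
        H_task_E=h_e,
        H_task_I=h_i,
        KLD_spont_E=k0_e,
        KLD_spont_I=k0_i,
        KLD_task_E=kl_e,
        KLD_task_I=kl_i,
        protocols=protocols,
        estimator="gaussian",
    )
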