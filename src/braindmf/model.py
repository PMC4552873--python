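"""The reduced Wong-Wang dynamic mean-field model of coupled E-I nodes.

Each brain region is a pair of neural populations — one excitatory (E, NMDA
kinetics) and one inhibitory (I, GABA kinetics) — whose state is the mean
synaptic gating fraction S in [0, 1].  Population firing rates are a
soft-threshold sigmoid of the total input current u (in nA):

    phi(u) = (a*u - b) / (1 - exp(-d*(a*u - b)))

and the gating variables follow

    dS_E/dt = -S_E/tau_E + (1 - S_E) * gamma * phi_E(u_E) + beta*eta(t)
    dS_I/dt = -S_I/tau_I +                 phi_I(u_I)     + beta*eta(t)

Long-range coupling enters the excitatory currents through the structural
connectivity matrix C scaled by the global coupling G and the NMDA synaptic
efficacy J_NMDA (the unit-bearing constant, 0.15 nA).  The full linear
current map is a 2N x 2N block matrix

    W = [[w_EE*I + G*J_NMDA*C, -diag(w_EI)],
         [w_IE*I,              -w_II*I   ]]

so that u = W @ S + I0 + I_ext.  The state vector ordering is all E nodes
followed by all I nodes throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import Connectome
from .errors import ParameterError, ValidationError

__all__ = [
    "DMFParams",
    "transfer_rate",
    "transfer_gain",
    "coupling_matrix",
    "background_current",
    "synaptic_currents",
    "drift",
    "jacobian",
]

# Series window for the removable singularity of phi at a*u == b.  Inside
# |z| < _SING_TOL (z = d*(a*u - b)) a quadratic expansion replaces the
# direct formula, keeping phi and its derivative smooth.
_SING_TOL = 1e-8


@dataclass
class DMFParams:
    """All scalar constants of the model plus the per-node FIC weights.

    Transfer-function constants (a in 1/nC i.e. Hz/nA, b in Hz, d in s) and
    the kinetic constants follow the reduced mean-field formulation the
    model derives from; local coupling weights, the noise amplitude beta
    and the Euler step are the values used throughout the study.
    """

    a_E: float = 310.0
    b_E: float = 125.0
    d_E: float = 0.16
    a_I: float = 615.0
    b_I: float = 177.0
    d_I: float = 0.087
    tau_E: float = 0.1
    tau_I: float = 0.01
    gamma: float = 0.641
    I0_E: float = 0.382
    I0_I: float = 0.2674
    w_EE: float = 0.21
    w_IE: float = 0.15
    w_II: float = 1.0
    G: float = 2.15
    J_NMDA: float = 0.15
    beta: float = 0.01
    dt: float = 1e-4
    w_EI: np.ndarray | float = 1.0

    def __post_init__(self):
        if self.tau_E <= 0 or self.tau_I <= 0 or self.dt <= 0:
            raise ParameterError("tau_E, tau_I and dt must be positive")
        if self.beta < 0:
            raise ParameterError("noise amplitude beta must be >= 0")

    def abd(self, population: str) -> tuple[float, float, float]:
        if population == "E":
            return self.a_E, self.b_E, self.d_E
        if population == "I":
            return self.a_I, self.b_I, self.d_I
        raise ValidationError(f"population must be 'E' or 'I', got {population!r}")

    def w_EI_vector(self, n: int) -> np.ndarray:
        w = np.asarray(self.w_EI, dtype=float)
        if w.ndim == 0:
            return np.full(n, float(w))
        if w.shape != (n,):
            raise ValidationError(f"w_EI has shape {w.shape}, expected ({n},)")
        return w

    def with_w_EI(self, w_EI: np.ndarray) -> "DMFParams":
        return replace(self, w_EI=np.asarray(w_EI, dtype=float))


def _phi(x: np.ndarray, d: float) -> np.ndarray:
    """x / (1 - exp(-d*x)) with the removable singularity filled in."""
    x = np.asarray(x, dtype=float)
    z = d * x
    small = np.abs(z) < _SING_TOL
    zs = np.where(small, 1.0, z)  # keep the denominator away from 0
    with np.errstate(over="ignore"):
        denom = -np.expm1(-np.clip(zs, -700.0, None))
    direct = np.where(np.isfinite(denom) & (denom != 0), x / np.where(denom == 0, 1.0, denom), 0.0)
    # overflow of exp(-z) (z very negative) => phi -> -x * exp(z) -> 0+
    overflowed = ~np.isfinite(denom)
    if np.any(overflowed):
        direct = np.where(overflowed, -x * np.exp(np.clip(z, None, 0.0)), direct)
    series = 1.0 / d + x / 2.0 + d * x * x / 12.0
    return np.where(small, series, direct)


def _phi_gain(x: np.ndarray, d: float) -> np.ndarray:
    """d(phi)/dx: (1 - e^{-dx}(1 + dx)) / (1 - e^{-dx})^2, smooth at x = 0."""
    x = np.asarray(x, dtype=float)
    z = d * x
    small = np.abs(z) < _SING_TOL
    zs = np.where(small, 1.0, z)
    with np.errstate(over="ignore"):
        e = np.exp(-np.clip(zs, -700.0, 700.0))
        denom = (1.0 - e) ** 2
        direct = np.where(
            np.isfinite(denom) & (denom != 0),
            (1.0 - e * (1.0 + zs)) / np.where(denom == 0, 1.0, denom),
            0.0,
        )
    overflowed = ~np.isfinite(denom) | (denom == 0) & ~small
    if np.any(overflowed):
        # z << 0: gain ~ -(1 + z) e^{z} -> 0+
        direct = np.where(overflowed, -(1.0 + z) * np.exp(np.clip(z, None, 0.0)), direct)
    series = 0.5 + z / 6.0 - z**3 / 180.0
    return np.where(small, series, direct)


def transfer_rate(u, population: str, params: DMFParams):
    """Population firing rate (Hz) for input current ``u`` (nA).

    Total, non-negative, strictly increasing; the removable singularity at
    a*u == b evaluates to 1/d through a local series expansion.
    """
    a, b, d = params.abd(population)
    u = np.asarray(u, dtype=float)
    out = _phi(a * u - b, d)
    return out if out.ndim else float(out)


def transfer_gain(u, population: str, params: DMFParams):
    """d(rate)/du in Hz/nA, smooth across the singularity."""
    a, b, d = params.abd(population)
    u = np.asarray(u, dtype=float)
    out = a * _phi_gain(a * u - b, d)
    return out if out.ndim else float(out)


def coupling_matrix(conn: Connectome, params: DMFParams) -> np.ndarray:
    """The 2N x 2N linear map W from gating vector to synaptic currents.

    Long-range coupling enters as G * J_NMDA * C: the dimensionless fiber
    densities C are converted to currents by the synaptic efficacy J_NMDA
    (nA) — the same constant that sets the local E->I weight — so that G
    keeps its published dimensionless meaning and the low-activity fixed
    point stays regulable over the documented G range.
    """
    n = conn.n_regions
    w_ei = params.w_EI_vector(n)
    eye = np.eye(n)
    top = np.hstack(
        [params.w_EE * eye + params.G * params.J_NMDA * conn.weights, -np.diag(w_ei)]
    )
    bottom = np.hstack([params.w_IE * eye, -params.w_II * eye])
    return np.vstack([top, bottom])


def background_current(params: DMFParams, n: int) -> np.ndarray:
    """Constant input vector I0 (length 2N)."""
    return np.concatenate([np.full(n, params.I0_E), np.full(n, params.I0_I)])


def _as_state(state: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(state, dtype=float)
    if s.shape[-1] != 2 * n:
        raise ValidationError(f"state has {s.shape[-1]} entries, expected {2 * n}")
    return s[..., :n], s[..., n:]


def synaptic_currents(
    state: np.ndarray,
    conn: Connectome,
    params: DMFParams,
    I_ext: np.ndarray | None = None,
) -> np.ndarray:
    """Total input currents u = W @ S + I0 + I_ext (length 2N, E then I).

    ``state`` may be a single 2N vector or a (..., 2N) batch; ``I_ext`` is a
    length-N (excitatory only) or length-2N external input in nA.
    """
    n = conn.n_regions
    s = np.asarray(state, dtype=float)
    _as_state(s, n)  # shape check
    W = coupling_matrix(conn, params)
    u = s @ W.T + background_current(params, n)
    if I_ext is not None:
        u = u + expand_external(I_ext, n)
    return u


def expand_external(I_ext: np.ndarray, n: int) -> np.ndarray:
    """Promote an N-vector (E-only input) to the full 2N current vector."""
    v = np.asarray(I_ext, dtype=float)
    if v.shape == (n,):
        return np.concatenate([v, np.zeros(n)])
    if v.shape == (2 * n,):
        return v
    raise ValidationError(f"I_ext has shape {v.shape}, expected ({n},) or ({2 * n},)")


def drift(
    state: np.ndarray,
    conn: Connectome,
    params: DMFParams,
    I_ext: np.ndarray | None = None,
    W: np.ndarray | None = None,
    I_const: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic time derivative dS/dt of the 2N gating vector.

    ``W`` and ``I_const`` (W @ S constant part, I0 + I_ext) may be passed to
    avoid rebuilding them inside integration loops.
    """
    n = conn.n_regions
    s = np.asarray(state, dtype=float)
    s_e, s_i = _as_state(s, n)
    if W is None:
        W = coupling_matrix(conn, params)
    if I_const is None:
        I_const = background_current(params, n)
        if I_ext is not None:
            I_const = I_const + expand_external(I_ext, n)
    u = s @ W.T + I_const
    u_e, u_i = u[..., :n], u[..., n:]
    r_e = _phi(params.a_E * u_e - params.b_E, params.d_E)
    r_i = _phi(params.a_I * u_i - params.b_I, params.d_I)
    ds_e = -s_e / params.tau_E + (1.0 - s_e) * params.gamma * r_e
    ds_i = -s_i / params.tau_I + r_i
    return np.concatenate([ds_e, ds_i], axis=-1)


def jacobian(
    mu: np.ndarray,
    conn: Connectome,
    params: DMFParams,
    I_ext: np.ndarray | None = None,
) -> np.ndarray:
    """Analytic Jacobian A = df/dS of the drift, evaluated at ``mu``.

    Chain rule through the transfer functions and the W blocks:

        A_EE = -(1/tau_E + gamma*r_E) * I + (1-S_E)*gamma*phi'_E * (w_EE*I + G*C)
        A_EI = -(1-S_E)*gamma*phi'_E * diag(w_EI)
        A_IE =  phi'_I * w_IE * I
        A_II = -(1/tau_I) * I - phi'_I * w_II * I
    """
    n = conn.n_regions
    mu = np.asarray(mu, dtype=float)
    mu_e, _ = _as_state(mu, n)
    u = synaptic_currents(mu, conn, params, I_ext)
    u_e, u_i = u[:n], u[n:]
    r_e = transfer_rate(u_e, "E", params)
    g_e = transfer_gain(u_e, "E", params)
    g_i = transfer_gain(u_i, "I", params)
    w_ei = params.w_EI_vector(n)

    pref_e = (1.0 - mu_e) * params.gamma * g_e  # per-node gain onto E currents
    a_ee = np.diag(-1.0 / params.tau_E - params.gamma * r_e) + pref_e[:, None] * (
        params.w_EE * np.eye(n) + params.G * params.J_NMDA * conn.weights
    )
    a_ei = np.diag(-pref_e * w_ei)
    a_ie = np.diag(g_i * params.w_IE)
    a_ii = np.diag(-1.0 / params.tau_I - g_i * params.w_II)
    return np.block([[a_ee, a_ei], [a_ie, a_ii]])
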