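"""Feedback inhibition control (FIC).

Each node's inhibitory-to-excitatory weight w_EI,i is tuned so that the
deterministic stationary firing rate of every excitatory population sits at
a common target (3 Hz by default), whether or not the node receives
long-range input.  At the target rate the calibration is algebraically
determined: the stationary E gating value follows from the E kinetics,

    S_E* = gamma * r* * tau_E / (1 + gamma * r* * tau_E),

the E current u_E* is the (unique, by monotonicity) preimage of r* under
the excitatory transfer function, the I subsystem reduces to one scalar
fixed-point equation

    S_I* = tau_I * phi_I(I0_I + w_IE * S_E* - w_II * S_I*)

shared by all nodes, and the current-balance equation of each node then
yields its weight exactly:

    w_EI,i = (I0_E + w_EE * S_E* + G * J_NMDA * S_E* * sum_j C_ij - u_E*) / S_I*.

The result is verified independently by integrating the deterministic mean
equations to steady state and checking the achieved rates and the local
stability of the Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .data_io import Connectome
from .errors import CalibrationError
from .model import DMFParams, drift, jacobian, transfer_rate

__all__ = ["FICResult", "calibrate_fic", "stationary_state", "fixed_point_targets"]


@dataclass
class FICResult:
    w_EI: np.ndarray
    achieved_rates: np.ndarray
    iterations: int
    converged: bool


def fixed_point_targets(params: DMFParams, target_rate: float) -> tuple[float, float, float]:
    """(S_E*, u_E*, S_I*) implied by clamping every E rate at ``target_rate``."""
    g = params.gamma * target_rate * params.tau_E
    s_e = g / (1.0 + g)
    u_e = brentq(
        lambda u: transfer_rate(u, "E", params) - target_rate,
        -5.0,
        5.0,
        xtol=1e-14,
    )
    base_i = params.I0_I + params.w_IE * s_e

    def residual(s_i: float) -> float:
        return params.tau_I * transfer_rate(base_i - params.w_II * s_i, "I", params) - s_i

    s_i = brentq(residual, 0.0, 1.0, xtol=1e-14)
    return s_e, u_e, s_i


def stationary_state(
    conn: Connectome,
    params: DMFParams,
    I_ext: np.ndarray | None = None,
    S0: np.ndarray | None = None,
    t_max: float = 10.0,
    settle_tol: float = 1e-9,
) -> np.ndarray:
    """Deterministic steady state by Euler integration of the mean equations.

    Integrates at ``params.dt`` until max |dS/dt| < ``settle_tol`` holds for a
    full second of model time, or ``t_max`` is reached.
    """
    n = conn.n_regions
    if S0 is None:
        s = np.full(2 * n, 0.1)
    else:
        s = np.array(S0, dtype=float)
    from .model import background_current, coupling_matrix, expand_external

    W = coupling_matrix(conn, params)
    I_const = background_current(params, n)
    if I_ext is not None:
        I_const = I_const + expand_external(I_ext, n)
    dt = params.dt
    quiet = 0.0
    t = 0.0
    while t < t_max:
        ds = drift(s, conn, params, W=W, I_const=I_const)
        s = s + dt * ds
        if not np.all(np.isfinite(s)):
            raise CalibrationError(f"mean dynamics diverged at t = {t:.3f} s")
        t += dt
        quiet = quiet + dt if np.max(np.abs(ds)) < settle_tol else 0.0
        if quiet >= 1.0:
            break
    return s


def calibrate_fic(
    conn: Connectome,
    params: DMFParams,
    target_rate: float = 3.0,
    tol: float = 0.05,
    max_iter: int = 50,
    verify: bool = True,
) -> FICResult:
    """Set per-node w_EI so stationary excitatory rates equal ``target_rate``.

    Returns the calibrated weights together with the achieved rates measured
    by independent integration of the deterministic equations.  Raises
    :class:`CalibrationError`, naming the worst node, when the fixed point
    is not reached within ``tol`` Hz (e.g. when long-range coupling is too
    strong for inhibition to compensate).
    """
    n = conn.n_regions
    s_e, u_e, s_i = fixed_point_targets(params, target_rate)
    row = conn.weights.sum(axis=1)
    w_ei = (
        params.I0_E + params.w_EE * s_e + params.G * params.J_NMDA * s_e * row - u_e
    ) / s_i
    calibrated = params.with_w_EI(w_ei)

    mu = np.concatenate([np.full(n, s_e), np.full(n, s_i)])
    if not verify:
        return FICResult(w_EI=w_ei, achieved_rates=np.full(n, target_rate),
                         iterations=1, converged=True)

    # independent verification: integrate from a perturbed state and check
    # that the dynamics return to the prescribed rates
    s_star = stationary_state(conn, calibrated, S0=mu * 0.9 + 0.01)
    from .model import synaptic_currents

    u = synaptic_currents(s_star, conn, calibrated)
    rates = np.asarray(transfer_rate(u[:n], "E", calibrated))
    err = np.abs(rates - target_rate)
    worst = int(np.argmax(err))
    converged = bool(err[worst] <= tol)
    if not converged:
        raise CalibrationError(
            f"FIC did not converge: node {worst} at {rates[worst]:.3f} Hz "
            f"(target {target_rate} Hz, tol {tol} Hz)",
            worst_node=worst,
        )
    A = jacobian(s_star, conn, calibrated)
    if np.max(np.linalg.eigvals(A).real) >= 0:
        raise CalibrationError(
            "calibrated fixed point is not linearly stable", worst_node=worst
        )
    return FICResult(w_EI=w_ei, achieved_rates=rates, iterations=1, converged=True)
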