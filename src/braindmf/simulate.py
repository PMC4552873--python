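"""Euler-Maruyama integration of the stochastic model over trial ensembles.

A "trial" is one realization of the stochastic differential equations; the
ensemble statistics (trial-by-trial variance, autocovariance, time-resolved
percent changes) are averages across trials at fixed time points, matching
how evoked-response variability is quantified experimentally.

The noise term beta * eta(t) is discretized as beta * sqrt(dt) * N(0, 1)
per Euler step, which corresponds to the continuous-time noise covariance
Qn = beta^2 * I used by the LNA — the simulator and the analytic moments
are mutually consistent and are cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import Connectome
from .errors import SimulationError, ValidationError
from .model import (
    DMFParams,
    background_current,
    coupling_matrix,
    drift,
    expand_external,
)

__all__ = [
    "StimulusProtocol",
    "TrialEnsemble",
    "simulate",
    "ensemble_variance",
    "ensemble_autocovariance",
    "delta_timecourses",
]


@dataclass
class StimulusProtocol:
    """External input to the excitatory populations of selected regions."""

    target_nodes: list[int] = field(default_factory=list)
    amplitude: float = 0.02
    onset: float = 0.0
    offset: float = np.inf

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValidationError("stimulus amplitude must be >= 0")
        if not self.onset < self.offset:
            raise ValidationError("onset must precede offset")

    def current(self, n: int, t: float) -> np.ndarray:
        """Length-N excitatory input vector at time t."""
        v = np.zeros(n)
        if self.target_nodes and self.onset <= t < self.offset:
            idx = np.asarray(self.target_nodes, dtype=int)
            if idx.min() < 0 or idx.max() >= n:
                raise ValidationError("protocol targets out of range")
            v[idx] = self.amplitude
        return v

    def constant_current(self, n: int) -> np.ndarray:
        """The input vector during the stimulation period."""
        v = np.zeros(n)
        if self.target_nodes:
            v[np.asarray(self.target_nodes, dtype=int)] = self.amplitude
        return v


@dataclass
class TrialEnsemble:
    trajectories: np.ndarray  # (n_trials, n_times, 2N)
    t: np.ndarray             # (n_times,) seconds, 0 = protocol reference
    dt: float                 # recording step
    protocol: StimulusProtocol
    record: str = "gating"

    @property
    def n_trials(self) -> int:
        return self.trajectories.shape[0]


def simulate(
    conn: Connectome,
    params: DMFParams,
    protocol: StimulusProtocol,
    duration: float,
    n_trials: int,
    seed: int,
    record: str = "gating",
    record_every: int = 10,
    burn_in: float = 2.0,
    start_state: np.ndarray | None = None,
    clip_gating: bool = True,
) -> TrialEnsemble:
    """Integrate ``n_trials`` independent realizations for ``duration`` s.

    Trials start from the spontaneous stationary distribution: every trial
    is burned in for ``burn_in`` seconds of noisy spontaneous dynamics from
    ``start_state`` (default: deterministic spontaneous fixed point) before
    t = 0.  States are recorded every ``record_every`` Euler steps either as
    gating fractions or as synaptic currents; gating states are clamped to
    [0, 1] after each noisy step.
    """
    if record not in ("gating", "current"):
        raise ValidationError(f"record must be gating|current, got {record!r}")
    n = conn.n_regions
    rng = np.random.default_rng(seed)
    W = coupling_matrix(conn, params)
    I0 = background_current(params, n)
    dt = params.dt
    sq = params.beta * np.sqrt(dt)

    if start_state is None:
        from .lna import solve_fixed_point

        start_state = solve_fixed_point(conn, params)
    s = np.tile(np.asarray(start_state, dtype=float), (n_trials, 1))

    def step(s: np.ndarray, I_const: np.ndarray, k: int) -> np.ndarray:
        ds = drift(s, conn, params, W=W, I_const=I_const)
        s = s + dt * ds + sq * rng.standard_normal(s.shape)
        if clip_gating:
            np.clip(s, 0.0, 1.0, out=s)
        if not np.all(np.isfinite(s)):
            raise SimulationError("simulation produced non-finite state", step=k)
        return s

    I_spont = I0.copy()
    for k in range(int(round(burn_in / dt))):
        s = step(s, I_spont, k)

    n_steps = int(round(duration / dt))
    rec_idx = np.arange(0, n_steps + 1, record_every)
    t_rec = rec_idx * dt
    out = np.empty((n_trials, rec_idx.size, 2 * n))
    # precompute the two input regimes (protocol is piecewise constant)
    I_on = I0 + expand_external(protocol.constant_current(n), n)
    ptr = 0
    if rec_idx[0] == 0:
        out[:, 0] = _record(s, W, I0, protocol, n, 0.0, record)
        ptr = 1
    for k in range(1, n_steps + 1):
        t = k * dt
        on = protocol.onset <= (t - dt) < protocol.offset and bool(protocol.target_nodes)
        s = step(s, I_on if on else I_spont, k)
        if ptr < rec_idx.size and k == rec_idx[ptr]:
            out[:, ptr] = _record(s, W, I0, protocol, n, t, record)
            ptr += 1
    return TrialEnsemble(
        trajectories=out, t=t_rec, dt=record_every * dt, protocol=protocol, record=record
    )


def _record(s, W, I0, protocol, n, t, record):
    if record == "gating":
        return s
    I_full = I0 + expand_external(protocol.current(n, t), n)
    return s @ W.T + I_full


def ensemble_variance(ens: TrialEnsemble) -> np.ndarray:
    """Unbiased across-trial variance at each time point, (n_times, 2N)."""
    if ens.n_trials < 2:
        raise ValidationError("ensemble variance needs at least 2 trials")
    return ens.trajectories.var(axis=0, ddof=1)


def ensemble_autocovariance(
    ens: TrialEnsemble, t_ref: float, lags: np.ndarray
) -> np.ndarray:
    """Across-trial covariance between t_ref + lag and t_ref, (n_lags, 2N)."""
    lags = np.asarray(lags, dtype=float)
    i_ref = int(round((t_ref - ens.t[0]) / ens.dt))
    if not (0 <= i_ref < ens.t.size):
        raise ValidationError(f"t_ref = {t_ref} outside recorded window")
    x0 = ens.trajectories[:, i_ref] - ens.trajectories[:, i_ref].mean(axis=0)
    out = np.empty((lags.size, ens.trajectories.shape[2]))
    for j, lag in enumerate(lags):
        i = i_ref + int(round(lag / ens.dt))
        if not (0 <= i < ens.t.size):
            raise ValidationError(f"lag {lag} falls outside recorded window")
        x1 = ens.trajectories[:, i] - ens.trajectories[:, i].mean(axis=0)
        out[j] = (x0 * x1).sum(axis=0) / (ens.n_trials - 1)
    return out


def delta_timecourses(
    ens_task: TrialEnsemble,
    ens_spont: TrialEnsemble | None = None,
    baseline_window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node, per-time percent change of ensemble mean and variance.

    The spontaneous reference is either a separate ensemble on the same
    time grid, or — when ``ens_spont`` is None — the task ensemble's own
    pre-onset ``baseline_window`` averaged over time.  Zero-variance
    baselines yield NaN rather than raising.
    """
    m_t = ens_task.trajectories.mean(axis=0)
    v_t = ensemble_variance(ens_task)
    if ens_spont is not None:
        if ens_spont.t.shape != ens_task.t.shape or not np.allclose(
            ens_spont.t, ens_task.t
        ):
            raise ValidationError("ensembles are not aligned on the same time grid")
        m_0 = ens_spont.trajectories.mean(axis=0)
        v_0 = ensemble_variance(ens_spont)
    else:
        if baseline_window is None:
            baseline_window = (ens_task.t[0], ens_task.protocol.onset)
        sel = (ens_task.t >= baseline_window[0]) & (ens_task.t < baseline_window[1])
        if not np.any(sel):
            raise ValidationError("empty baseline window")
        m_0 = m_t[sel].mean(axis=0, keepdims=True)
        v_0 = v_t[sel].mean(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta_m = np.where(m_0 != 0, 100.0 * (m_t / m_0 - 1.0), np.nan)
        delta_v = np.where(v_0 > 0, 100.0 * (v_t / v_0 - 1.0), np.nan)
    return delta_m, delta_v
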