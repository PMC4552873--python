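"""Synthetic connectomes and surrogate ROI time series.

Two generators make every downstream stage testable without external files:

* modular random binary graphs parameterized by the overall link density
  ``q`` and the proportion ``p`` of links placed within modules — the same
  two-parameter family used to probe how network clustering shapes the
  stimulus response;
* surrogate multivariate-Gaussian ROI time series with a known covariance
  (hence known ground-truth differential entropy), organised exactly like
  the empirical recordings (subjects x runs x frames x ROIs, TR 2.16 s,
  stimulus onsets with inter-stimulus intervals uniform in 17.3-30.2 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import Connectome, FMRIDataset
from .errors import ParameterError

__all__ = [
    "ModularGraphSpec",
    "SurrogateFMRISpec",
    "module_assignment",
    "generate_modular_connectome",
    "generate_surrogate_fmri",
    "generate_correlated_noise_covariance",
]


@dataclass
class ModularGraphSpec:
    n_nodes: int = 66
    n_modules: int = 5
    q: float = 0.14
    p: float = 0.5
    scale: float = 1.0
    seed: int = 0
    symmetric: bool = False
    # "constant" -> all placed links get weight `scale`;
    # "lognormal" -> heavy-tailed weights (log-sd `weight_sigma`) whose mean
    # over placed links is `scale`, mimicking tractography fiber densities.
    weight_style: str = "constant"
    weight_sigma: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.q <= 1.0 and 0.0 <= self.p <= 1.0):
            raise ParameterError("q and p must lie in [0, 1]")
        if self.n_nodes < 2 or self.n_modules < 1:
            raise ParameterError("need n_nodes >= 2 and n_modules >= 1")
        if self.weight_style not in ("constant", "lognormal"):
            raise ParameterError(f"unknown weight_style {self.weight_style!r}")


@dataclass
class SurrogateFMRISpec:
    covariance: np.ndarray = field(default_factory=lambda: np.eye(33))
    n_frames: int = 194
    n_runs: int = 4
    n_subjects: int = 17
    tr_seconds: float = 2.16
    isi_range: tuple[float, float] = (17.3, 30.2)
    seed: int = 0
    mean: np.ndarray | None = None
    # optional injected post-onset variance modulation (task only): sample
    # deviations in the `post_onset_frames` frames after each onset are
    # multiplied by `post_onset_scale` (1.0 = stationary surrogate).
    post_onset_scale: float = 1.0
    post_onset_frames: int = 0

    def __post_init__(self):
        c = np.asarray(self.covariance, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ParameterError("covariance must be square")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ParameterError("covariance must be symmetric")
        if np.linalg.eigvalsh(c).min() < -1e-10 * max(1.0, np.abs(c).max()):
            raise ParameterError("covariance must be positive semidefinite")
        if self.isi_range[0] > self.isi_range[1] or self.isi_range[0] <= 0:
            raise ParameterError("isi_range must satisfy 0 < min <= max")
        self.covariance = c


def module_assignment(n_nodes: int, n_modules: int) -> np.ndarray:
    """Contiguous, as-even-as-possible split of nodes into modules."""
    sizes = np.full(n_modules, n_nodes // n_modules)
    sizes[: n_nodes % n_modules] += 1
    return np.repeat(np.arange(n_modules), sizes)


def generate_modular_connectome(spec: ModularGraphSpec) -> Connectome:
    """Random modular graph with density q and within-module link share p.

    The total number of links is fixed at round(q * S) where S is the number
    of available slots (ordered off-diagonal pairs, or unordered pairs in
    symmetric mode); round(p * L) of them are drawn uniformly without
    replacement among within-module slots, the rest among between-module
    slots.  Deterministic given ``spec.seed``.
    """
    n, rng = spec.n_nodes, np.random.default_rng(spec.seed)
    modules = module_assignment(n, spec.n_modules)
    same = modules[:, None] == modules[None, :]
    off = ~np.eye(n, dtype=bool)
    if spec.symmetric:
        sel = np.triu(off, k=1)
    else:
        sel = off
    within_slots = np.argwhere(sel & same)
    between_slots = np.argwhere(sel & ~same)
    total_slots = len(within_slots) + len(between_slots)
    n_links = int(round(spec.q * total_slots))
    n_within = int(round(spec.p * n_links))
    n_between = n_links - n_within
    if n_within > len(within_slots) or n_between > len(between_slots):
        raise ParameterError(
            f"cannot place {n_within} within / {n_between} between links: only "
            f"{len(within_slots)} within and {len(between_slots)} between slots"
        )
    w = np.zeros((n, n))
    chosen_w = within_slots[rng.choice(len(within_slots), n_within, replace=False)]
    chosen_b = between_slots[rng.choice(len(between_slots), n_between, replace=False)]
    for chosen in (chosen_w, chosen_b):
        if len(chosen) == 0:
            continue
        if spec.weight_style == "lognormal":
            raw = rng.lognormal(mean=0.0, sigma=spec.weight_sigma, size=len(chosen))
            vals = spec.scale * raw / np.exp(spec.weight_sigma**2 / 2.0)
        else:
            vals = np.full(len(chosen), spec.scale)
        w[chosen[:, 0], chosen[:, 1]] = vals
        if spec.symmetric:
            w[chosen[:, 1], chosen[:, 0]] = vals
    return Connectome(weights=w)


def generate_surrogate_fmri(spec: SurrogateFMRISpec, condition: str = "rest") -> FMRIDataset:
    """Draw i.i.d. zero-mean multivariate-normal frames with the spec covariance.

    For the task condition, onset frames are placed run by run with
    inter-stimulus intervals uniform in ``spec.isi_range`` seconds (rounded
    to frames).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_rois = spec.covariance.shape[0]
    # eigh-based factor: tolerant of exactly singular target covariances
    evals, evecs = np.linalg.eigh(spec.covariance)
    factor = evecs * np.sqrt(np.clip(evals, 0.0, None))
    mean = np.zeros(n_rois) if spec.mean is None else np.asarray(spec.mean, float)

    series: dict[int, list[np.ndarray]] = {}
    onsets: dict[int, list[list[int]]] = {}
    for subj in range(1, spec.n_subjects + 1):
        runs, run_onsets = [], []
        for _ in range(spec.n_runs):
            z = rng.standard_normal((spec.n_frames, n_rois))
            x = z @ factor.T
            ons: list[int] = []
            if condition == "task":
                t = rng.uniform(*spec.isi_range)
                while t / spec.tr_seconds < spec.n_frames - 1:
                    ons.append(int(round(t / spec.tr_seconds)))
                    t += rng.uniform(*spec.isi_range)
                if spec.post_onset_scale != 1.0 and spec.post_onset_frames > 0:
                    for o in ons:
                        stop = min(o + spec.post_onset_frames, spec.n_frames)
                        x[o:stop] *= spec.post_onset_scale
            runs.append(mean + x)
            run_onsets.append(ons)
        series[subj] = runs
        if condition == "task":
            onsets[subj] = run_onsets
    return FMRIDataset(
        series=series,
        roi_labels=[f"ROI{i + 1:02d}" for i in range(n_rois)],
        condition=condition,
        tr_seconds=spec.tr_seconds,
        onsets=onsets if condition == "task" else None,
    )


def generate_correlated_noise_covariance(
    n_vars: int, n_samples: int, base_intensity: float, seed: int = 0
) -> np.ndarray:
    """Random non-diagonal noise covariance from finite-sample scatter.

    Draws ``n_samples`` i.i.d. samples from N(0, base_intensity * I) and
    returns their sample covariance: symmetric, PSD, equal to the diagonal
    base in the infinite-sample limit but non-diagonal at finite n — the
    construction used for the correlated-intrinsic-noise variant of the
    entropy experiment.
    """
    if n_samples <= 1:
        raise ParameterError("n_samples must exceed 1")
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, np.sqrt(base_intensity), size=(n_samples, n_vars))
    return np.cov(x, rowvar=False)
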