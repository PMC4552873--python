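"""Canned study configurations.

The reference connectome built here is a SYNTHETIC stand-in for a
DSI-derived 66-region human connectome.  It reproduces that matrix's
summary statistics and — through choices fixed once, on anatomical
grounds — its dynamical regime:

* link density q = 0.14 and mean nonzero coupling weight m = 0.025;
* five modules with a moderate within-module link share (p = 0.5);
* symmetric adjacency with heavy-tailed (log-normal, sigma = 0.75)
  weights, mimicking reciprocal tractography fiber densities;
* the eight visual-system regions (r/lLOCC, r/lMT, r/lPCAL, r/lST) are
  connection hubs (strength scaled x2.5), reflecting the documented fact
  that medial occipito-parietal regions carry the largest fiber strengths
  in the human connectome.

Under these choices the feedback-inhibition-controlled network keeps a
stable low-activity fixed point up to a global coupling of G ~ 4.6 and
destabilizes beyond — the regulable range documented for the empirical
matrix.  The stand-in is NOT empirical data; numbers derived from it
describe the model on this synthetic substrate.
"""

from __future__ import annotations

import numpy as np

from .data_io import Connectome
from .model import DMFParams
from .simulate import StimulusProtocol
from .synthetic import ModularGraphSpec, generate_modular_connectome

__all__ = [
    "VISUAL_LABELS",
    "reference_connectome",
    "visual_protocol",
    "default_params",
]

# node indices of the visual-system stand-ins: right-hemisphere labels in
# the first module, mirrored left-hemisphere labels offset by N/2
_VISUAL_NODES = {
    "rLOCC": 2, "rMT": 5, "rPCAL": 8, "rST": 11,
    "lLOCC": 35, "lMT": 38, "lPCAL": 41, "lST": 44,
}
VISUAL_LABELS = tuple(_VISUAL_NODES)

REFERENCE_DENSITY = 0.14
REFERENCE_MEAN_WEIGHT = 0.025  # mean over nonzero (placed-link) entries
_HUB_FACTOR = 2.5
_WEIGHT_SIGMA = 0.75


def reference_connectome(seed: int = 66, n_nodes: int = 66) -> Connectome:
    """Synthetic 66-region stand-in connectome (see module docstring)."""
    spec = ModularGraphSpec(
        n_nodes=n_nodes,
        n_modules=5,
        q=REFERENCE_DENSITY,
        p=0.5,
        scale=1.0,
        seed=seed,
        symmetric=True,
        weight_style="lognormal",
        weight_sigma=_WEIGHT_SIGMA,
    )
    w = generate_modular_connectome(spec).weights.copy()
    labels = [f"R{i + 1:03d}" for i in range(n_nodes)]
    if n_nodes == 66:
        hub = np.ones(n_nodes)
        for name, idx in _VISUAL_NODES.items():
            labels[idx] = name
            hub[idx] = _HUB_FACTOR
        w *= np.sqrt(np.outer(hub, hub))
        np.fill_diagonal(w, 0.0)
    w *= REFERENCE_MEAN_WEIGHT / w[w > 0].mean()
    return Connectome(weights=w, labels=labels)


def visual_protocol(
    conn: Connectome,
    amplitude: float = 0.02,
    onset: float = 0.0,
    offset: float = np.inf,
) -> StimulusProtocol:
    """External input to the eight visual-system regions."""
    targets = [conn.node_index(lbl) for lbl in VISUAL_LABELS]
    return StimulusProtocol(
        target_nodes=targets, amplitude=amplitude, onset=onset, offset=offset
    )


def surrogate_fmri_study(seed: int = 0):
    """Synthetic stand-in for the rest/task ROI fMRI study (17 subjects,
    4 runs x 194 frames x 33 ROIs per condition, TR 2.16 s).

    Frames are multivariate Gaussian with a rank-29 covariance (ROI
    preprocessing removes four dimensions of variance, so per-subject
    covariances carry 29 non-zero singular values).  Subjects differ by a
    log-normal volume jitter (sd 0.15 in log, ~6 bits of between-subject
    entropy spread).  The task condition shares the resting covariance but
    attenuates fluctuations to 85% amplitude for 4 frames (~8.6 s) after
    each stimulus onset — stimulus-evoked variability quenching as the
    sole rest/task difference, producing a ~2 bit run-wide entropy
    reduction that recovers ~8-9 s after onset.  Returns (rest, task).
    """
    from .synthetic import SurrogateFMRISpec, generate_surrogate_fmri

    rng = np.random.default_rng(seed)
    basis = rng.standard_normal((33, 29))
    cov_base = basis @ basis.T / 29.0
    rest_series: dict[int, list[np.ndarray]] = {}
    task_series: dict[int, list[np.ndarray]] = {}
    task_onsets: dict[int, list[list[int]]] = {}
    for subj in range(1, 18):
        scale = float(np.exp(rng.normal(0.0, 0.15)))
        cov = scale**2 * cov_base
        sub_seed = int(rng.integers(0, 2**31 - 1))
        rest = generate_surrogate_fmri(
            SurrogateFMRISpec(covariance=cov, n_subjects=1, seed=sub_seed), "rest"
        )
        task = generate_surrogate_fmri(
            SurrogateFMRISpec(
                covariance=cov,
                n_subjects=1,
                seed=sub_seed + 1,
                post_onset_scale=0.85,
                post_onset_frames=4,
            ),
            "task",
        )
        rest_series[subj] = rest.series[1]
        task_series[subj] = task.series[1]
        task_onsets[subj] = task.onsets[1]
    from .data_io import FMRIDataset

    labels = [f"ROI{i + 1:02d}" for i in range(33)]
    return (
        FMRIDataset(series=rest_series, roi_labels=labels, condition="rest"),
        FMRIDataset(
            series=task_series, roi_labels=labels, condition="task", onsets=task_onsets
        ),
    )


def default_params(G: float = 2.15, **overrides) -> DMFParams:
    """Model constants of the study with the global coupling of the headline
    analyses (G = 2.15)."""
    return DMFParams(G=G, **overrides)
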