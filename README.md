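# braindmf

Whole-brain dynamic mean-field modeling and entropy analysis of
spontaneous vs task-driven cortical activity.

One of the most robust signatures of task engagement in the brain is a
*decrease* of variability relative to rest, seen from membrane potentials
to fMRI.  `braindmf` implements a mechanistic account of this effect at
the whole-cortex scale: N brain regions, each a coupled
excitatory–inhibitory (E–I) mean-field node with synaptic gating dynamics

    dS_E/dt = −S_E/τ_E + (1 − S_E)·γ·φ_E(u_E) + β·η(t)
    dS_I/dt = −S_I/τ_I + φ_I(u_I) + β·η(t)
    u = W·S + I₀ + I_ext,   W = [[w_EE·I + G·J·C, −diag(w_EI)],
                                 [w_IE·I,         −w_II·I    ]]

interconnected through a structural connectome **C** scaled by a global
coupling G.  Per-node feedback inhibition weights w_EI are calibrated so
every excitatory population rests at 3 Hz (Feedback Inhibition Control).
Because the intrinsic noise β is weak, the full second-order statistics
are available analytically through the linear noise approximation:
stationary covariance from the Lyapunov equation A·P + P·Aᵀ + Qn = 0,
autocovariance F_u(τ) = W e^{τA} P Wᵀ with its memory scale T95, and
cross-spectra Π_u(ω) = W(A+iω)⁻¹Qn(Aᵀ−iω)⁻¹Wᵀ.

On top of that the package provides:

* a stochastic (Euler–Maruyama) trial-ensemble simulator, cross-checked
  against the analytic moments;
* a Balloon–Windkessel forward model from total synaptic activity to
  BOLD, with trial-resolved mean/variance statistics;
* differential entropy (Gaussian log-det, rank-truncated SVD form, and a
  nonparametric nearest-neighbour estimator) and Gaussian relative
  entropy (KLD) — quantifying how external inputs *contract* the
  multidimensional activity space;
* an empirical pipeline for rest-vs-task ROI fMRI tables (per-subject
  entropy, exact Wilcoxon tests, peristimulus sliding-window entropy,
  functional-connectivity comparison);
* synthetic-data generators (modular random connectomes; Gaussian
  surrogate fMRI with known covariance) so every stage runs and is
  tested without any external file.

Who it is for: computational neuroscientists studying large-scale brain
dynamics, stimulus-evoked variability quenching, and information-
theoretic characterizations of cortical state.

## Worked example

```python
import numpy as np
from braindmf import (
    reference_connectome, default_params, visual_protocol,
    calibrate_fic, solve_moments, coupling_matrix,
    autocovariance, random_stimulation_entropy,
)

conn = reference_connectome()           # synthetic 66-region stand-in
params = default_params()               # G = 2.15, published constants
fic = calibrate_fic(conn, params)       # clamp all E rates at 3 Hz
params = params.with_w_EI(fic.w_EI)
print(f"rates: {fic.achieved_rates.min():.3f}-{fic.achieved_rates.max():.3f} Hz")

W = coupling_matrix(conn, params)
spont = solve_moments(conn, params)     # stationary rest statistics
prot = visual_protocol(conn)            # 0.02 nA to r/lLOCC, r/lMT, r/lPCAL, r/lST
task = solve_moments(conn, params, I_ext=prot.constant_current(66), S0=spont.mu)

tau = np.arange(0.0, 3.0001, 0.002)
print(f"T95 (excitatory): rest {1e3*autocovariance(spont, W, tau).T95_E:.0f} ms, "
      f"task {1e3*autocovariance(task, W, tau).T95_E:.0f} ms")

rep = random_stimulation_entropy(conn, params, n_stims=50, seed=7)
print(f"entropy drop: {rep.entropy_drop_E.min():.2f}-{rep.entropy_drop_E.max():.2f} bits")
```

prints

```
rates: 3.000-3.000 Hz
T95 (excitatory): rest 256 ms, task 265 ms
entropy drop: 1.74-2.42 bits
```

Feedback inhibition holds every region at the 3 Hz target; the
spontaneous excitatory synaptic activity forgets its past after roughly a
quarter second; and each random 8-region stimulation at 0.02 nA lowers
the differential entropy of the excitatory synaptic activity by one to
three bits — the network settles into a smaller region of its activity
space under drive.

A command-line interface mirrors these recipes
(`braindmf fic|lna|simulate|bold|entropy-model|entropy-fmri|synth`),
writing TSV reports plus a provenance stamp per run; see
`braindmf --help`.

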