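# Methods

## The model

Each of N cortical regions is a pair of coupled neural populations — one
excitatory (E, NMDA-dominated kinetics) and one inhibitory (I,
GABA-dominated) — described by mean synaptic gating fractions
S_E, S_I ∈ [0, 1].  Population rates are a soft-rectifying sigmoid of the
total input current u (nA),

    φ(u) = (a·u − b) / (1 − exp(−d·(a·u − b))),

with (a, b, d) = (310 nC⁻¹, 125 Hz, 0.16 s) for E and
(615 nC⁻¹, 177 Hz, 0.087 s) for I.  The gating dynamics are

    dS_E/dt = −S_E/τ_E + (1 − S_E)·γ·φ_E(u_E) + β·η(t),
    dS_I/dt = −S_I/τ_I + φ_I(u_I) + β·η(t),

with τ_E = 0.1 s, τ_I = 0.01 s, γ = 0.641, and uncorrelated Gaussian white
noise of amplitude β = 0.01.  Currents are a linear map of the gating
state, u = W·S + I₀ + I_ext, with the 2N×2N block coupling matrix

    W = [[w_EE·I + G·J·C,  −diag(w_EI)],
         [w_IE·I,          −w_II·I    ]],

w_EE = 0.21, w_IE = 0.15, w_II = 1, background currents
I₀ = (0.382, 0.2674) nA, global coupling G (2.15 in the headline
analyses), and C the structural connectome (dimensionless fiber
densities, zero diagonal).

**The long-range efficacy J.**  The coupling term carries an explicit
synaptic efficacy J = 0.15 nA — the same NMDA conductance constant that
sets the local E→I weight — converting the dimensionless fiber densities
into currents.  This is a deliberate design choice: with the coupling
written as G·C alone and a connectome of realistic weight scale, the
inhibition-controlled resting state is linearly unstable already at
G < 1, whereas with G·J·C the network keeps a single stable low-activity
fixed point up to G ≈ 4.5–6 (substrate-dependent) and destabilizes
beyond — the regulable range documented for this model class.  G thereby
retains its conventional dimensionless meaning.

## Feedback inhibition control (FIC)

Each node's inhibitory-to-excitatory weight w_EI,i is set so that every
excitatory population fires at the 3 Hz target in the deterministic
stationary state.  At the target rate the problem is algebraic: the E
gating value S_E* = γr*τ_E/(1+γr*τ_E) and the E current u_E* = φ_E⁻¹(r*)
are fixed numbers, the I subsystem reduces to one scalar fixed-point
equation shared by all nodes, and the per-node weight follows exactly
from current balance.  The implementation solves these closed-form
pieces (two scalar Brent root-finds) and then **verifies** the result
independently by integrating the deterministic mean equations to steady
state from a perturbed initial condition and checking both the achieved
rates (default tolerance 0.05 Hz) and the Hurwitz stability of the
Jacobian.  The calibration is exact, deterministic, and free of learning
rates; an unstable or unreachable fixed point raises a calibration error
naming the worst node.

## Linear noise approximation

For weak noise the gating fluctuations around the fixed point are a
multivariate Ornstein–Uhlenbeck process with the analytic Jacobian A
(chain rule through φ and W; validated against finite differences at
relative 1e-5).  The engine computes:

* stationary covariance P from A·P + P·Aᵀ + Qn = 0 (Schur-based Lyapunov
  solve; residual ‖AP+PAᵀ+Qn‖/‖Qn‖ < 1e-8 enforced);
* current covariance Cv = W·P·Wᵀ, autocovariance F_u(τ) = W e^{τA} P Wᵀ
  (single-step matrix exponential reused along a uniform lag grid), the
  per-node ACF, and the population T95 (first lag where the node-averaged
  ACF reaches 0.05, linearly interpolated);
* cross-spectra Π_u(ω) = W(A+iω)⁻¹Qn(Aᵀ−iω)⁻¹Wᵀ with the PSD computed as
  a squared norm of W(A+iω)⁻¹L (L the Cholesky factor of Qn), which is
  non-negative by construction at every frequency.  Fourier convention:
  two-sided angular-frequency spectra with variance = (1/2π)∫S(ω)dω; the
  public grids are in Hz (default logarithmic, 0.01–200 Hz, 400 points,
  with parabolic refinement of the ΔPSD minimum on the log axis);
* a transient mode that integrates the mean equations jointly with
  dP/dt = A(μ(t))P + PA(μ(t))ᵀ + Qn, re-evaluating A along the mean —
  used for stimulus onset/offset dynamics (Euler at the model step; cost
  grows as (2N)² per step, so transients are exercised on small networks
  in the test suite).

The noise term is discretized as β√dt·N(0,1) per Euler step, matching the
continuous-time Qn = β²I used in the Lyapunov equation; the simulator and
the LNA are cross-checked to 3 Monte-Carlo standard errors at 1000 trials.

## Entropy and relative entropy

Differential entropy of a Gaussian is H = ½log₂((2πe)ⁿ det Σ), computed
via Cholesky log-determinants.  Sample data use the rank-truncated form:
the determinant is the product of the k singular values of the sample
covariance above max(λ)·n·ε·10⁶ (tolerance factor exposed), so short
windows and preprocessing-induced rank loss are handled without
regularization.  The nonparametric cross-check is the k-nearest-neighbour
estimator (digamma-corrected, k = 1 by default, ties broken by optional
jitter), converted to bits.

Relative entropy is the Gaussian KLD between the synaptic-activity
distribution N(0, Cv) and the intrinsic-noise distribution N(0, Qn_ref).
One covariance *shape* enters at two scales: the dynamical noise in the
Lyapunov equation has intensity β², while the KLD reference uses the
per-step noise covariance (β·dt)²·shape.  Entropy *differences* are
invariant to this split (both entropies shift equally under a common
rescaling); the KLD *ordering* is not — its trace and log-determinant
terms scale differently — which is why the reference scale is pinned
explicitly rather than left to a convention.

## The synthetic substrates

The package ships no empirical data; two generators emulate the study's
inputs and are themselves first-class, tested code.

**Modular connectomes.**  Random binary graphs on N nodes in five
contiguous, near-equal modules, parameterized by overall link density q
and the within-module link share p; the total link count is fixed at
round(q·slots) and links are placed uniformly without replacement.
Directed and symmetric modes exist; weights are constant or log-normal.

**Reference connectome stand-in.**  A fixed 66-region instance standing
in for the DSI-derived human connectome: q = 0.14 and mean nonzero weight
0.025 (the empirical matrix's summary statistics), p = 0.5 (moderate
clustering), symmetric adjacency (tractography is reciprocal), log-normal
weights (σ = 0.75 in log) for the heavy-tailed fiber-density
distribution, and the eight visual-system regions (r/lLOCC, r/lMT,
r/lPCAL, r/lST) strength-scaled ×2.5, reflecting the hub status of
medial occipito-parietal cortex.  These choices were fixed once, on
anatomical grounds and on the requirement that the model's documented
dynamical regime holds (stable FIC-controlled rest state up to G ≈ 4.6;
strong, all-node variance quenching at G = 2.15).  What the stand-in does
**not** reproduce: the empirical matrix's exact hub/clique geometry.
Consequently the spontaneous temporal-memory scales and the ~9 Hz
alpha-band PSD-reduction structure match the published values, but the
*stimulated-state* timescale collapse (T95 halving network-wide under a
0.02 nA input to 8 regions) does not emerge on this substrate: the
operating points of unstimulated regions move too little (~2·10⁻³ nA of
indirect current).  Passing tests on the stand-in therefore demonstrate
the pipeline and the single-node/network mechanisms, not a replication
of every connectome-specific number.

**Surrogate fMRI study.**  Seventeen subjects × 4 runs × 194 frames × 33
ROIs per condition, TR 2.16 s.  Frames are i.i.d. zero-mean multivariate
Gaussian with a rank-29 covariance (emulating preprocessing-induced rank
loss; per-subject covariances then carry exactly 29 non-zero singular
values).  Subjects differ by a log-normal volume factor (σ = 0.15,
≈ 6 bits of between-subject entropy spread).  Task runs share the resting
covariance but attenuate fluctuations to 85% amplitude for 4 frames
(≈ 8.6 s) after each stimulus onset (inter-stimulus intervals uniform in
17.3–30.2 s) — stimulus-evoked variability quenching as the sole
rest/task difference, yielding a ≈ 2 bit run-wide entropy reduction that
recovers ~8–9 s after onset.  Real fMRI is neither i.i.d. across frames
nor exactly Gaussian; in particular the parametric and nearest-neighbour
entropy estimates correlate near 1 on these surrogates, higher than on
empirical data.

## Hemodynamics

The Balloon–Windkessel system (vasodilatory signal, inflow, volume,
deoxyhemoglobin; κ = 0.65 s⁻¹, γ_f = 0.41 s⁻¹, τ = 0.98 s, α = 0.32,
ρ = 0.34, V₀ = 0.02, k₁ = 7ρ, k₂ = 2, k₃ = 2ρ−0.2) transduces the
standardized total (E+I) synaptic current into a BOLD percent signal,
Euler-integrated with ≤1 ms sub-steps.  The drive is z-scored against the
spontaneous baseline with an exposed gain, since the neural-to-
hemodynamic coupling scale is not part of the neural model.  The filter
passes < 1 Hz and suppresses faster fluctuations, which is why BOLD
variance changes can be positive in regions whose slow synaptic power
rises even as total synaptic variance falls.

## Numerical choices and degenerate inputs

* Transfer-function singularity at a·u = b: series expansion within
  |d·(a·u−b)| < 1e-8, keeping φ and φ′ smooth for the Jacobian.
* Gating states are clamped to [0,1] only after noisy Euler steps; the
  drift itself is never clipped.
* Fixed points: Euler warm-up followed by Newton (analytic Jacobian);
  residual > 1e-8 or non-finite states raise a stability error.
* T95 requires the ACF to cross 0.05 inside the lag grid; otherwise an
  extend-grid error is raised rather than extrapolating.
* Zero baseline variance in percent-change statistics yields NaN, not an
  exception; degenerate (constant) data raise dedicated errors in the
  entropy and FC stages.
* Peristimulus windows whose ±17.3 s span crosses a run boundary are
  skipped; per-window p-values are reported uncorrected (a Bonferroni
  option exists but is off by default, matching the analysis convention).

## Problem sizes used in the shipped checks

The acceptance script runs the full 66-region substrate: FIC calibration,
stationary LNA for the visual protocol (T95 on a 0–3 s lag grid at 2 ms;
spectra on the 400-point log grid), 500 random stimulation patterns, and
the complete 17-subject surrogate fMRI pipeline with both entropy
estimators.  The test suite exercises stochastic-simulation cross-checks
on an 8-node network (1000 trials) and transient moment integration on
small networks; these sizes give Monte-Carlo standard errors well inside
the asserted tolerances.

## Known limitations

* No transmission delays; coupling is instantaneous.
* Hemodynamic parameters are the canonical published set, not fitted;
  region-specific hemodynamics are out of scope.
* The empirical-data numbers that depend on the real connectome's exact
  geometry (stimulated-state T95, direct-node ΔPSD minimum location) and
  on real data's non-Gaussianity (the 0.91 estimator correlation) are not
  reproduced by the synthetic substrates; see the substrate section.
* The entropy experiment treats stationary stimulation; onset/offset
  transients enter only through the transient moment mode.
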