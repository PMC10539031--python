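# Methods

This note records the model, the assimilation scheme, the synthetic-data
design, and the numerical and design choices behind `cardassim`, together
with their rationale and known limitations.

## Tissue model

The electrophysiology is the three-variable Fenton–Karma monodomain model:
a normalized transmembrane potential `u` with fast-inward, slow-outward and
slow-inward phenomenological currents, a fast inactivation gate `v` and a
slow inactivation gate `w`,

    du/dt = div(D(x) grad u) + I_stim − I_fi(u,v) − I_so(u) − I_si(u,w)
    dv/dt = Θ(u_c−u)(1−v)/τ_v−(u) − Θ(u−u_c) v/τ_v+
    dw/dt = Θ(u_c−u)(1−w)/τ_w−   − Θ(u−u_c) w/τ_w+

with

    I_fi = −v Θ(u−u_c)(1−u)(u−u_c)/τ_d
    I_so =  u Θ(u_c−u)/τ_o + Θ(u−u_c)/τ_r
    I_si = −w (1 + tanh(k_si (u−u_csi)))/(2 τ_si)
    τ_v−(u) = τ_v1− Θ(u−u_v) + τ_v2− Θ(u_v−u)

on a rectangular slab with no-flux boundaries.  The conduction tensor
follows a fiber direction in the (x, y)-plane rotating linearly with depth,
θ(z) = θ0 + δθ(−1/2 + z/S), with D∥ = 0.001 cm²/ms along the fiber and
D⊥ = 0.0002 cm²/ms across it (anisotropy ratio 5); the through-wall
coupling is D⊥.  Defaults: θ0 = 0, δθ = 2π/3 (a typical transmural
rotation).

Conventions and tie-breaks:

- Heaviside Θ(0) = 0 everywhere: activation requires strictly u > u_c.
  At exactly u = u_c neither gate branch is active and the gates are
  unchanged over a step.
- At exactly u = u_v both branches of τ_v−(u) vanish under Θ(0) = 0,
  which would give an infinite rate; the implementation uses u > u_v →
  τ_v1−, else τ_v2− (a measure-zero tie-break that avoids division by
  zero).
- The rest state (0, 1, 1) is not an exact fixed point: I_si has no
  threshold gate, and its tanh tail leaves a drift of order 1e−8/ms.
  Tests assert the drift bound rather than exact invariance.

### Numerics

Forward Euler for the voltage (Euler–Maruyama when the stochastic current
is enabled) and Rush–Larsen exponential integration for the gates, with the
relaxation rate frozen at the step start.  Diffusion is the second-order
finite-difference stencil with per-layer in-plane tensor entries (including
the mixed-derivative term) and mirrored ghost nodes (`u[-1] = u[1]`) for
the no-flux condition.  The default step is dt = 0.1 ms — 20 substeps per
2 ms assimilation interval — validated at startup against a conservative
explicit-diffusion stability bound.  Stochastic voltage noise enters as
σ_u √dt N(0,1) per node per substep, independent across nodes and members,
so σ_u keeps its meaning as the standard deviation of a unit-variance-rate
stochastic current.  Time-scale resampling draws every explicit τ from
N(τ̄, (τ̄ σ_p)²), truncated below at 0.05 τ̄; thresholds are never resampled.
Members are resampled at initialization and after every analysis step.

### Parameter sets

The classic published fits (`br`, `mbr`, `set4`) are shipped and loadable.
None of them can follow a 118 ms basic cycle length 1:1 in slab tissue:
their tissue-level action potentials outlast the pacing period and the
paced slab locks into 2:1 block (verified from rest and under ramped
pacing).  The packaged default `set4-short` is a data-matched variant of
set 4 — τ_si raised 26.5 → 40 ms (shorter plateau, tissue APD ≈ 70 ms) and
τ_o raised 9 → 40 ms (diastolic membrane time constant moved toward
physiological resting values) — chosen once so that the paced slab captures
every stimulus at the 118 ms cycle length.  This mirrors the experimental
situation: preparations recorded at short cycle lengths require their own
fitted parameter sets rather than the textbook ones.

## Observations

Observations are point values of `u` with standard deviation η, taken on
the epicardial (z = 0) and endocardial (z = S) planes.  Recordings are
sampled with a cubic spline in space and linear interpolation in time;
values are clipped to [0, 1].  The default uncertainty is the floor
η = 0.05 (5% of the action-potential amplitude range).  Two refinements
follow the study designs:

- Mid-depth synthesis: an m×m grid of interior records at z = S/2 whose
  values are the average of the two surface values at the projected
  (x, y), each with η = 0.5 — a deliberately weak interpolation prior for
  the unobserved interior (default 8×8 = 64 records).
- Wavefront uncertainty: η(y) = η_ + (η̄−η_) exp(−k²(y−(ū+u_)/2)²) for
  y in (u_, ū) = (0.1, 0.9), with η_ = 0.05, η̄ = 0.5, and η = η_ outside
  that band.  A Gaussian cannot satisfy η(0) = η(1) = η_ exactly, so k is
  chosen to make the Gaussian term ≤ 1e−3 (η̄−η_) at the truncation
  boundaries; the truncation then enforces the floor exactly while keeping
  η continuous to that tolerance.  So η(0.5) = 0.5 and η(0) = η(1) = 0.05.

The observation operator samples `u` at the grid node nearest each record
(layouts are node-aligned by construction; a position farther than half a
cell from every node is rejected as a layout/grid mismatch).

## LETKF

Per grid node, the analysis solves in the M-dimensional ensemble space

    P̃a  = [(M−1) I/ρ + Ybᵀ R̃⁻¹ Yb]⁻¹
    w̄a  = P̃a Ybᵀ R̃⁻¹ (yo − ȳb)
    Wa  = [(M−1) P̃a]^(1/2)   (symmetric square root, eigendecomposition
                              with eigenvalues clamped at ≥ 1e−12)

where R̃⁻¹ is diagonal with entries taper(d)/η²: covariance localization is
applied as observation-error weighting with the fifth-order compactly
supported taper of half-width c = √(10/3) σ_o and total cutoff 2c (21.9
grid units for σ_o = 6).  Only observations at the analysis time enter.
With no local observations the solve reduces exactly to w̄a = 0,
Wa = √ρ I.  Multiplicative inflation is ρ = 1.05 throughout.  Strong
coupling (voltage observations updating u, v and w at the node) is the
default; a weak-coupling mode updates only u.

Distances are physical distances divided by hx, so σ_o keeps one meaning
on anisotropic spacings.  Experiment configurations default the
localization scale to its physical value 0.09 cm — which equals the σ_o = 6
convention at a full-scale 0.015 cm node spacing — rather than re-using
"6 grid units" at coarser resolutions, which would triple the physical
localization footprint and over-constrain the interior.

Gross-error screening: an observation whose innovation exceeds σ_g η
(default σ_g = 10) is inert for that cycle — it neither moves the mean nor
contracts the deviations.  (Merely zeroing its innovation while keeping it
in the precision matrix would still contract the ensemble exactly when the
background is most wrong; the inert form makes the update invariant with
respect to the screened record.)  With η = 0.05 and innovations bounded by
1, no observation is ever screened once σ_g ≥ 20.

Analysis members are bounded: u ∈ [−0.1, 1.5], v, w ∈ [0, 1], with the
mean and deviations recomputed after clipping.  Bounding is applied in
every mode, including free-run: unbounded inflation lets gate deviations
leave [0, 1], where a negative v turns the fast-inward current
anti-restoring and the explicit integration diverges.  In free-run mode
(no observations admitted) the analysis reduces to deviation inflation by
√ρ; the mean is preserved exactly whenever the bounds are inactive, and at
ρ = 1 the free-run analysis is the identity.

The initial ensemble is rest plus spatially correlated Gaussian voltage
perturbations (white noise smoothed over σ_o grid units, rescaled to a
0.1 standard deviation per member, clipped to the analysis bounds), with
gates fully recovered.

## Verification metrics

- Spread: SPRD = (M−1)⁻¹ (Σ_m |x_m − x̄|²)^(1/2) per node and variable —
  the normalization sits outside the root, following the convention of the
  verification formulas this package reproduces.  The depth profile
  averages the squared spreads over each layer; both the squared profile
  and its root are stored (the units of the printed reduction are
  ambiguous against plotted color scales, so both are kept and only shapes
  are compared).
- Surface RMSE: RMS of (observation − mean state at the nearest node),
  restricted to surface records.
- Fair kernel CRPS with the 1-norm:
  Σ_m ‖x_m − y‖₁/M − Σ_{m,m'} ‖x_m − x_m'‖₁/(2M(M−1)); the
  observation-space variant scores surface records, the consistency
  variant scores the full background state against the analysis mean.
- APD/APA: threshold crossings at u_thr = 0.1 with linear sub-sample
  interpolation; APs shorter than 3 samples are discarded as noise, and
  incomplete terminal APs are dropped.

## Twin experiments

The generator replaces an optical-mapping preparation: a truth run of the
same model family, rendered as two surface recordings with the measured
data's properties, plus tabular observations.  Study conditions (the
defaults):

- Pacing at a 118 ms basic cycle length with per-beat uniform ±2 ms jitter
  (the recorded protocol's documented timing variability), delivered as a
  monophasic Gaussian-footprint current (I0 = 0.1 /ms for τ_on = 10 ms) at
  one corner of the slab.  As in the experiment — where the electrode sat
  outside the imaged region — the recording covers an inset region
  excluding a 0.6 cm margin around the stimulated corner, so the direct
  stimulus artifact never enters the recorded amplitude range.
- A conditioning pre-roll of 3 whole pacing periods before recording
  starts: recordings emulate steady constant pacing, and the first action
  potential from rest is ~3× longer than the steady one.  The pre-roll is
  a whole number of periods, so the stimulus phase in recorded time is
  unchanged.
- Truth conduction 4× the printed tensors (conduction velocity 2× the
  base model's): a conservative stand-in for the several-fold conductivity
  misfit between this model family and real ventricular recordings, and
  the reason the slab can follow the short cycle length — each wave must
  clear the domain well before the next stimulus.  The assimilation model
  runs at the printed tensors (the literal experimental situation: the
  model's conduction velocity is half the recording's, and it always lags
  the recorded fronts); a `model_diffusion_scale` knob lets studies
  explore partially calibrated models.
- Optical blur with 0.8 cm FWHM: fluorescence integrates several tissue
  layers, turning the model's sharp fronts into transitions close to a
  centimeter wide.  Sensor noise sd 0.05 (= the uncertainty floor), then
  per-surface min–max normalization over all frames and clipping to
  [0, 1].
- Desk-scale geometry: 3×3 cm surface at 0.05 cm in-plane spacing and a
  1.1 cm wall at 0.1 cm layers (ventricular-wall thickness; the mid-wall
  lies beyond the localization reach of the surface observations, which
  is what lets interior uncertainty behave as in the full-scale study).
  Scaled-down runs use a 2×2 cm, 0.7 cm-thick slab (40×40×8).

What the generator does not emulate: photon transport and dye kinetics,
motion artifacts, the biphasic endocardial-base electrode geometry, and
sustained tissue-level APD alternans — at this cycle length the model
family's 1:1 branch sits in a weakly alternating regime, and the strongly
alternating regime destabilizes capture (the recorded preparation showed
both irregularity and capture, which no single parameterization of this
model reproduces in a slab).  Passing twin tests therefore demonstrate the
pipeline's mechanics and orderings, not a quantitative fit to any real
recording.

## Experiment presets and findings the design rests on

Six presets: free-run (paced members, no observations admitted),
autonomous (deterministic members, no stimulus), stimulus (paced members +
assimilation), stochastic (autonomous model + stochastic current and
resampled time scales, σ_u = σ_p = 0.04), synthetic-obs (autonomous +
mid-depth records), wavefront-uncertainty (autonomous + value-dependent
η).  Each cycle advances members by T_a = 2 ms, computes background
metrics, applies the analysis (or free-run inflation), and logs a metric
row; summary statistics exclude the first 250 ms transient by default.

Two findings from the twin studies shaped the defaults and are worth
stating plainly:

1. Member stimulation and stochastic currents are spread engines.  Paced
   members re-ignite each beat from their own slightly different states,
   regenerating ensemble spread at every threshold crossing; the
   stochastic current maintains a spread floor of σ_u √T_a directly.
2. A deterministic, unstimulated (autonomous) ensemble on a regularly
   paced twin synchronizes and collapses after a few beats: between waves
   the quiescent dynamics contract all deviations, no mechanism
   regenerates them, and once the ensemble subspace degenerates the
   analysis gain loses coherence and new beats can no longer be ignited
   from the observations alone.  Multiplicative inflation (ρ = 1.05)
   cannot balance this.  The test suite computes the contrast directly
   (`test_stochastic_current_sustains_spread_where_deterministic_collapses`):
   on the same twin recording the autonomous ensemble's late-time spread
   collapses below 1e−3 while the stochastic run's stays above 1e−2 and
   tracks the surfaces.  Reconstruction of periodically driven
   excitations with this scheme therefore relies on either explicit
   stimulus information or stochastic model-error representation; the
   scaled-down ordering study accordingly compares the stochastic
   (autonomous-model) assimilating run against the free-run baseline.

A related limitation shows up in the depth structure of the ensemble
spread at the scaled-down study conditions (computed by the twin ordering
tests): with the full uncalibrated conduction misfit, the assimilating run's
variance concentrates at the observed surfaces — where the analysis
fights the lagging model fronts every cycle — rather than peaking in the
unobserved mid-wall, and the slow-conducting free-run ensemble develops a
mid-wall spread minimum (its weakly coupled layers decorrelate) instead
of a depth-uniform profile.  Both shapes differ from the full-scale
expectation that surface observations pin the surfaces and leave the
interior as the uncertainty reservoir; at desk scale that expectation is
recovered only with a partially calibrated model, which the default
conditions deliberately do not assume.

## Problem sizes used in the test suite

Unit and property tests run on 3³–8³ grids.  The twin ordering study runs
the free-run and stochastic presets at 40×40×8, M = 16, 500 cycles
(1 s of recording); the perfect-model sanity check runs the stimulus
preset with matched models and clean observations for 10 cycles.  These
sizes are the package's desk-scale study conditions.
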