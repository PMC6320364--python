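# Methods

This note documents the models, numerical schemes, parameter choices and
known limitations of the package. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Physical model and units

All dynamics are overdamped one-dimensional Langevin motion,

    γ ẋ(t) = f_ext(t) − ∂U/∂x(x) + √(2 kBT γ) ξ(t),

with Gaussian white noise ⟨ξ(t)ξ(t′)⟩ = δ(t−t′) and friction tied to the
diffusion coefficient by Einstein–Stokes, γ = kBT/D(x). Inertia is neglected
throughout: at the micron/fN/second scales of the systems emulated here the
momentum relaxation time is many orders of magnitude below every other
timescale.

Internal units are µm, s, fN and kBT (1 fN·µm = 10⁻²¹ J; kBT = 4.11 fN·µm
at ≈ 298 K). Energies are stored in kBT and forces in fN; every conversion
goes through the single `Units.kBT` constant so unit errors cannot pass
silently. In these units all quantities of interest are O(1)–O(100).

### Landscapes

- `Quartic(a, b, c)`: U = a/4·x⁴ + b/2·x² + c·x. `quartic_from_barrier`
  maps the physical parameters (barrier ΔU₁, well asymmetry ΔU₂, well
  separation L) to a = 64ΔU₁/L⁴, b = −aL²/4, c = 2ΔU₂/L.
- `Linear(f)`: constant force f (fN), U = −f·x/kBT.
- `TrapMixture`: sums of Gaussian wells (center, depth, width). Real
  optical-trap profiles are instrument-specific; a Gaussian well is this
  package's generic stand-in for a point/line trap.
- `Tabulated`: cubic-spline interpolation of (x, U) samples; extrapolation
  outside the table raises an error rather than guessing.

### Telegraph force

`TelegraphSpec(f0, alpha)` switches between +f0 and −f0 with exponential
dwell times. `alpha` is defined through the autocovariance
⟨f(t+Δt)f(t)⟩ ∝ e^(−αΔt); for a symmetric two-level process this fixes the
per-direction switching rate at α/2 (mean dwell per level 2/α). A
"decorrelation time of 2 s" therefore means α = 0.5 s⁻¹ and a 4 s mean
dwell. `fit_decorrelation_rate` validates generated processes by a
log-linear fit of the empirical autocovariance over the lags where it
exceeds 20% of the variance; its standard error is α̂/√(#switches), because
neighbouring-lag autocovariances are far too correlated for a residual-based
regression SE to mean anything.

## Simulator (`pathtimes.simulate`)

Euler–Maruyama with step

    x ← x + [−U′(x)·D(x)/kBT + D′(x) + 𝒯(t)·f0·D(x)/kBT]·dt + √(2D(x)dt)·N(0,1).

The `+D′(x)` term is the kinetic-convention spurious drift that makes the
simulator's stationary state agree with the Fokker–Planck current
j = −(DU′/kBT)ρ − D∂ₓρ for spatially varying D; for constant D (all default
analyses) it vanishes. The inner loop is numba-compiled; drift, noise
amplitude and mobility are linearly interpolated from 4097-point tables, so
one code path serves every landscape variant (interpolation error is O(h²)
and negligible at this resolution).

Numerical choices:

- **dt = 10⁻³ s by default** — at the parameter scales used here the fastest
  intra-well relaxation time γ/U″ is ≳ 0.04 s, so the default step resolves
  it by a factor ≥ 40. A weak-convergence test (halving dt leaves the mean
  exit time within combined 3·SEM) is part of the suite.
- **Crossing times by linear interpolation** between the last interior and
  first exterior sample, which removes the O(dt) first-passage
  discretization bias.
- **Reflecting bounds by mirror reflection**; the 4 µm microchannel is
  emulated with reflecting ends at ±2 µm.
- **Censoring**: exit-protocol repeats that reach t_max inside the interval
  are reported as censored and excluded from τ statistics, mirroring the
  discarding of incident-contaminated repeats in automated experiments.
- **Seeding**: a single user seed expands into independent child seeds via
  `numpy.random.SeedSequence` spawn keys, so adding a pipeline stage never
  perturbs the streams of earlier stages. Identical config + seed gives
  bit-identical trajectories.

### Known sampling bias of event detection

Transition-path events are defined on the *recorded* trajectory. Brief
excursions across a boundary between samples are invisible, which shifts the
detected "last crossing" start earlier and inflates transition-path times by
a few percent at dt = 10⁻³ s (measured against the closed-form free-diffusion
mean). Direction-*internal* comparisons (all KS symmetry tests) are
unaffected because the bias is identical for both directions; the one place
an absolute mean is compared with theory (the L²/6D check), the simulation
uses dt = 5×10⁻⁵ s, which brings the bias well inside the 3·SEM band at
n ≈ 1000 events.

## First-passage theory (`pathtimes.theory`)

Both interval boundaries are always absorbing: ρ(x_left,t) = ρ(x_right,t) = 0.

- **MFPT**: D τ″ − (U′/kBT) D τ′ = −1 is solved by double quadrature with
  integrating factor e^(−U/kBT) (cumulative trapezoids on a 4001-point grid),
  which reduces to τ(x) = (x−x_l)(x_r−x)/2D for a flat landscape.
- **Splitting probabilities**: P_right(x₀) ∝ ∫ e^(U/kBT)/D dx with the 1/D
  weight included for spatially varying D (it cancels for constant D, the
  usual regime). Sign convention: positive force points right, so
  P_right = (1+e^(−fL/2kBT))⁻¹ from a centred start and the downhill exit is
  always the majority one. A small birth–death-chain oracle in the tests
  cross-checks the varying-D case.
- **Exit-time densities**: the full Fokker–Planck equation
  ∂ₜρ = −∂ₓ[−(DU′/kBT)ρ − D∂ₓρ] is evolved by Crank–Nicolson on a uniform
  513-node grid (conservative finite-volume tridiagonal operator, LU
  factorized once), with 16 backward-Euler startup steps to damp the stiff
  modes of the grid-delta initial condition (Rannacher smoothing). Boundary
  fluxes are extracted with second-order one-sided differences and
  normalized by the splitting probability, ρ_τ(t) = j(boundary,t|x₀)/P.
  The time step defaults to (interval length)²/D / 2×10⁴, and the evolution
  continues until the surviving mass falls below 10⁻⁴ × min(P_left,P_right)
  — scaling the cut by the *minority* probability matters, since the late
  survivors split between both exits and an absolute cut truncates a
  disproportionate share of the rarer exit's tail (a 0.6% mean bias when
  conditioning near a boundary).
- **Transition-path-time density**: the ε→0 limit of the exit density
  started at x₀ = boundary + ε. ε is evaluated at 32h and 16h (h = grid
  spacing) and Richardson-extrapolated; smaller ε values are *worse*, since
  a grid delta two nodes from an absorbing wall is discretization-dominated.
  A convergence guard raises an error if the two ε evaluations disagree by
  more than 1% in the mean. Resulting accuracy (verified in the suite):
  density mass within 10⁻³ of 1, first moment within 1% of the quadrature
  value, and sup-norm agreement within 10⁻³ of the peak against the
  method-of-images series for free diffusion.
- **Mean transition-path time** by the standard double-quadrature formula
  with e^(U/kBT)/D weights, evaluated with O(n) prefix sums; equals L²/6D on
  a flat landscape and is exactly direction-symmetric for any static U — the
  central equilibrium symmetry as an identity of the theory stack.

## Inference (`pathtimes.inference`)

Single-step displacements are binned by their *starting* position (left-point
rule, consistent with the Itô drift). Per bin, moment matching — the maximum
likelihood fit of the Gaussian step density — gives D̂ = var/2Δt and, after
eliminating γ via Einstein–Stokes, f̂ = mean·kBT/(D̂Δt). Bins with fewer
than 50 steps are flagged and excluded. Potentials are rebuilt by
trapezoidal integration of −f̂ from the left end with SEs accumulated in
quadrature; because the integral is cumulative, sparse bins at the left end
shift the whole curve, so reconstructions should start where occupancy is
adequate. `force_from_exit_counts` inverts the splitting formula,
f̂ = (2kBT/L)·ln(n_right/n_left), with a Wilson score interval propagated
through the (monotone) logit transform; the default confidence level is 95%.

Sampling arithmetic worth knowing: at the 80 Hz frame rate with f = 3.3 fN
and D = 0.15 µm²/s, a single step has mean 1.5×10⁻³ µm and sd 6.1×10⁻² µm,
so the relative error of f̂ is ≈ 12.9% at 10⁵ steps and ≈ 3.2% at 1.6×10⁶
steps. The acceptance check of the ±10% recovery band uses the latter size
so the band is a 3σ statement rather than a coin flip; D̂'s relative error,
√(2/N), is far smaller at any of these sizes.

## NESS diagnostics (`pathtimes.ness`)

The phase plane is (position, total force f_tot = f_ext − dU/dx).

- **Occupancy**: normalized 2D histogram; in a telegraph-driven bistable
  system it splits into four lobes (two positions × two force levels).
- **Currents and circulation**: net inter-bin crossing rates J are counted
  for x- and f-edges, with each crossing attributed to the lane of the
  *segment midpoint*. Midpoints are invariant under time reversal, so
  reversing the trajectory negates every J exactly, and motion along a
  static curve f(x) (the equilibrium case) generates no spurious lane
  asymmetry — departure-point attribution, by contrast, fabricates
  circulation from the curve's slope. The scalar circulation is the angular
  momentum of the current field about the occupancy centroid (axes scaled by
  their standard deviations so both contribute comparably); it is exactly
  antisymmetric under time reversal and has zero mean under detailed
  balance. Significance comes from a 10-block decomposition of the
  trajectory: mean/SEM of per-block circulations gives a z-score, with
  |z| > 3 flagging broken detailed balance. `circulation_score` (the
  normalized magnitude) is reported alongside for a non-negative summary.
- **Asymmetry sweep**: for each telegraph rate α, simulation chunks
  accumulate until the requested number of direct transitions per direction
  is reached; means, SEMs and the directional KS p-value are reported.

### Hairpin emulation

`hairpin_preset` models a hairpin-like folding coordinate, *not* calibrated
hairpin kinetics: a quartic in the extension coordinate (folded F left,
unfolded U right) with a 4 kBT barrier, a 1 kBT well asymmetry (the folded
state more stable, as for a hairpin held below its coexistence force), and a
telegraph force switching between ∓14 fN at α = 0.2 s⁻¹ over a 1 µm span.
The defaults were chosen once, from timescale arguments: the per-level tilt
(±1.7 kBT well shift) dominates the asymmetry so all four doublet states
F±, U± are visited; the mean dwell per force level (2/α = 10 s) exceeds the
downhill hopping time (a few seconds) so the doublets are metastable; and
the well asymmetry makes the intermediate dwells path-dependent, which is
what renders corner-to-corner times directionally asymmetric — a symmetric
landscape under a symmetric telegraph force gives mirror-symmetric
corner-to-corner paths and only a weak effect. Doublet path times span from
the last exit of one corner region (e.g. U⁺ = unfolded at high force) to the
first entry into the opposite corner (F⁻), *including* intermediate dwells.
With equal force levels the preset degenerates to an equilibrium two-state
system and the inclusive-threshold corner definitions reduce to plain
folded/unfolded transition times, whose symmetry is the control.

## What the synthetic data does and does not show

The simulator emulates the *physics* of the experiments (free diffusion and
drift at fN forces in a channel, bistable hopping, telegraph driving, camera
-rate sampling) but none of their nuisance structure: no localization noise,
no drift of the instrument, no hydrodynamic wall coupling in D(x) (a
measured D(x) table can be supplied, but none is generated), no bead-handle
compliance for the hairpin, and exactly Markovian 1D dynamics. Passing tests
therefore demonstrate correctness of the algorithms and the internal
consistency of theory, simulation and inference under the model assumptions
— not robustness to the artefacts of real trajectories.

## Problem sizes

Default study sizes were chosen so every analysis runs in seconds to a few
minutes on one CPU: 10³–3×10³ protocol repeats, ≥500–1000 transition events
per direction and seed, 1.6×10⁶ inference steps, 1.5–2×10³ s phase-plane
records, and 2.4×10⁴ s hairpin records (~400 events per direction). Event
counts, not wall time, set the statistical resolution; all of them can be
scaled up linearly through the corresponding `SimConfig`/`min_events`
arguments.

## Known limitations

- One-dimensional coordinates only; the "second dimension" is always the
  external force level.
- No time-dependent-potential Fokker–Planck solver: driven cases are handled
  by simulation, equilibrium cases by theory (this mirrors how the driven
  analyses are actually done).
- The asymptotic-Kolmogorov KS p-value is accurate for the 10²–10³ event
  samples produced here but approximate below n ≈ 20 (the tests use scipy's
  exact method as the small-n oracle).
- Entropy production is not estimated; path-time asymmetry witnesses broken
  detailed balance but does not quantify dissipation.
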