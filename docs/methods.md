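# Methods

## Model

A simulated larva is a discrete-time, continuous-space Markov chain on
the plate plane. Step proposals are isotropic bivariate Gaussians with
standard deviation σ per component; σ is the model's length unit and is
identified with ≈ 0.1 mm (a larva advances about one body length in ten
accepted moves). A proposal **r** → **r**′ is accepted with probability
min(1, exp(−W/T)), where

    W(r → r′) = ΔI(r → r′) + β ⟨I⟩ f(α(r → r′))

* **ΔI = I(r′) − I(r)** — the irradiance change over the step. With this
  sign, steps toward darker ground lower W and are always accepted,
  which is what negative phototaxis requires. (The opposite sign
  convention is selectable via `ModelParams.delta_sign = -1` for
  fidelity experiments; it produces positive phototaxis and is not used
  anywhere else.)
* **f(α)** — directional weight of the heading α relative to the source
  bearing, folded to [0°, 180°]. Default `power` family
  f(α) = 1 − (α/180)ⁿ with n = 4; alternative `cosine` family
  ((1 + cos α)/2)ⁿ. Raw cosⁿ would violate f(180°) = 0 for even n, so
  the half-angle form is used — both families then share the boundary
  behaviour f(0) = 1, f(180°) = 0 and monotone decrease.
* **β** — dimensionless directionality weight. When the source sits at
  zenith angle θ above the plate, the projection β = β′ cos θ applies;
  at θ = 90° (overhead source) directionality vanishes and only the
  gradient drives taxis.
* **T** — effective temperature in irradiance units (W/m²). Larger T
  makes weight-increasing moves more likely: the chain explores more and
  navigates less efficiently.

Trajectories start at the origin and stop when an accepted position
reaches the absorbing radius (default 1150 σ ≈ 11.5 cm, the plate
half-width), or at `max_accepted_steps` (default 20 000; this is what
terminates unbiased walks, whose diffusive escape would otherwise take
~10⁶ steps), or at `max_proposals` (default 10⁶, a safety valve for
pathological parameter sets — the trajectory is returned flagged with a
`CapExceededWarning`). Rejected proposals consume neither time nor path
length. The weight is evaluated for every proposal regardless of whether
it would leave the plate; only accepted positions are tested against the
boundary.

### Linear-field batch simulation

All light fields are planes, I(x, y) = a0 + a1x·x + a1y·y. For a plane,
ΔI over a step depends only on the displacement, never on the current
position, and f(α) likewise — so the weight of each proposal is
independent of the chain's state, and acceptance decisions are i.i.d.
across proposals. The simulator therefore draws proposals in batches,
scores and accepts them vectorised, and accumulates accepted
displacements by cumulative sum. This is *exactly* the sequential
Metropolis algorithm (same draws, same order), just evaluated in blocks;
it is what makes study-scale calibration tractable (a 30 × 30 ensemble
runs in ~1–2 s).

## Units and geometry

Internal positions are in σ units; light fields live in cm and W/m².
The single conversion `sigma_cm` (default 0.01 cm = 0.1 mm, so
1 cm = 100 σ) is applied at the simulator boundary, never inside
metrics. Track CSVs serialise positions in cm with 12 significant
digits, which makes write → read → write round-trips byte-identical;
navigation indices survive the round-trip to ~10⁻¹⁰.

⟨I⟩ is the plate-average irradiance, computed over the square plate
(side 2 × `plate_half_width`); for a plane centred at the origin this
equals a0 exactly, so the choice of averaging domain (square vs. the
absorbing disc) is inconsequential.

## Field presets

Presets mirror the experimental pattern geometry: an artificial
projected gradient five times steeper than the natural fall-off toward
the projector, a 40° source zenith angle, source on the +x side.

| preset | a1x (W/m²/cm) | a1y | θ | role |
|---|---|---|---|---|
| `uniform` | 0 | 0 | 40° | unbiased chain (with β = 0) |
| `pos_like` | +84 | 0 | 40° | gradient and directionality reinforcing |
| `neg_like` | −56 | 0 | 40° | gradient opposing directionality |
| `tilted_like` | +14 | +70 | 40° | gradient ⊥ directionality (calibration pattern) |
| `d90_like` | −70 | 0 | 90° | overhead source, gradient only |

All share a0 = 1000 W/m². This is a *simulation* scale, not a
radiometric one: the published effective temperatures (≈ 5–27 W/m²) are
only consistent with per-step weights of comparable order, which for
0.1 mm steps implies field coefficients far steeper than the measured
bench irradiances (tens of W/m² across a 23 cm plate). No positive plane
on the plate can simultaneously make both weight terms match the
published parameter point at bench scale, so the presets adopt the scale
on which the published T and β are identifiable: at (β, T) =
(0.014, 8.75 W/m²) the tilted preset yields ni ≈ (−0.31, −0.05), the
right order for both axes. Since the calibration procedures fit T and β
to target indices anyway, every reported index is reproduced by
construction; only the numerical value of T is scale-dependent.

## Calibration

All fits are stochastic root-finding problems: each objective evaluation
simulates a seeded 30 × 30 ensemble. Three choices keep this tractable
and reproducible:

* **Common random numbers.** Every evaluation inside one fit reuses the
  same evaluation seed, so the objective is a deterministic, smooth
  function of the parameter and Monte-Carlo noise cancels between
  evaluations.
* **Step cap during fitting.** Evaluation ensembles cap trajectories at
  `step_cap` = 4000 accepted steps. The navigation index is a ratio of
  running sums and is stationary long before the boundary is reached at
  weak bias, so this changes estimates negligibly while bounding cost;
  final reported ensembles always use the full boundary rule. The
  evaluation proposal budget is 25 × `step_cap` per larva, which floors
  the acceptance rate probes can drag the simulator into.
* **Parameter resolution.** Bisection on log T (or log β) continues
  until the bracket narrows to 5% in log width (`xtol_rel`), not merely
  until the index residual drops below `tol` — near a flat stretch of
  the response an early stop would leave the parameter quantised on the
  coarse bracketing grid.

`fit_temperature` brackets and bisects on log T; `params.T` is the
initial guess. Reachability: a target index of exactly 0 is rejected (an
unbiased chain looks the same at every T). For β = 0 the greedy (T → 0)
limit of the index is computed exactly — the acceptance indicator
1{W ≤ 0} is position-independent, so the limit is a plain Monte-Carlo
ratio over proposals (for a pure gradient it approaches 2/π ≈ 0.64 along
the gradient axis) — and targets beyond it are rejected. For β > 0 the
T → 0 limit is *not* the supremum (strong directionality suppresses all
but perfectly-away steps, shrinking the gradient-axis index), so
reachability is left to bracket expansion with turnover detection: if
the index magnitude stops growing while the bracket expands toward
stronger bias, the target is declared unreachable.

`fit_beta_tilted` is the two-step decoupled fit on the tilted pattern:
(1) fit T to the y-index with β = 0 (the artificial y-gradient dominates
that axis); (2) holding T, fit β monotonically to the x-index. If the
x-target equals the gradient-only index within tolerance, β = 0 is
returned.

`joint_refine` absorbs the coupling the two-step fit ignores: switching
β on amplifies |ni_y| as well, so the stage-1 T is biased low. Each
sweep runs one ensemble at the current (β, T) and applies damped
multiplicative updates exploiting the local response shape — |ni_y|
approximately ∝ 1/T at fixed β, |ni_x| increasing in β at fixed T:

    T ← T · (|ni_y| / |target_y|)^0.7,     β ← β · (|target_x| / |ni_x|)^0.7

This converges in ~8 one-evaluation sweeps (cap 30) and, in recovery
experiments, returns generating parameters to within a few percent. A
parameter running away by more than ×300 marks the target pair as
contradictory (`UnreachableTargetError`); stopping at the sweep cap
returns the best visited point with a `NonConvergenceWarning`.

`select_angular_model` simulates every candidate (family, n) with the
same seed and ranks by mean RMS deviation of pooled 30°-binned heading
distributions from the reference(s); ties break toward smaller n, then
the power family. With references generated by the model's own quartic
weight, n = 4 wins by an order of magnitude in RMS against n = 3 and
n = 5.

## Metrics

* Navigation index: per-trajectory Δx/s on the accepted-step polyline;
  ensemble index = mean of per-larva indices per replicate, then mean
  over replicates, with the spread reported as the standard deviation
  across replicate means. A pooled variant (summed displacement over
  summed path length) is available as an option.
* Heading distributions pool per-accepted-step headings over larvae,
  folded to [0°, 180°] by symmetry about the source axis, in 30° bins
  (half-open, 180° in the last bin).
* The saturating response NI(u) = A(1 − e^(−u/s)) is fitted by
  Levenberg–Marquardt least squares; it is an interpolation to guide the
  eye, and no inferential claim is attached.
* Welch's t (with Welch–Satterthwaite dof), the one-sample t and
  Benjamini–Hochberg adjustment delegate to scipy/statsmodels.

## What the synthetic data does and does not emulate

Simulated ensembles reproduce the *statistical* structure of tracked
larvae: stochastic paths with the measured drift (navigation indices)
and heading anisotropy, absorbed at the plate edge. They do not model
run/turn segmentation, head sweeps (weathervaning), speed or wall-clock
time (the chain has no clock; the published mean run speed is constant
across light conditions, which is why NI comparisons are meaningful
without one), body dimensions, or larva–larva interactions. Passing
tests therefore validate the decision model and its calibration
machinery, not a kinematic reconstruction of individual tracks.

## Numerical choices and degenerate inputs

* Plane positivity is validated at the four plate corners (exact for a
  plane); negative fields raise `NegativeIntensityError`.
* Spectral band integration uses a monotone PCHIP interpolant (no
  overshoot on noisy spectra, stays non-negative) integrated knotwise by
  adaptive quadrature; agreement with a dense-trapezoid oracle is the
  acceptance check, not any particular quadrature brand.
* Zero-length steps cannot occur under a continuous proposal but are
  guarded with `ZeroStepError`; empty trajectories raise
  `EmptyTrajectoryError`; degenerate statistical samples (n < 2 or zero
  variance) raise `ValueError`.
* Seeding: one master seed; child streams per replicate, then per larva,
  spawned via `numpy.random.SeedSequence`, so ensembles are reproducible
  and order-independent.
* Ensembles in the test suite run at reduced sizes (e.g. 15 × 8
  ensembles with a 2000-step cap for calibration exercises, 20 × 15 for
  the repeated β-recovery experiment) chosen so Monte-Carlo standard
  errors stay well below the asserted tolerances; the end-to-end checks
  and the acceptance script use the study-scale 30 × 30.

## Known limitations

* The published per-pattern field coefficients (supplementary tables)
  are not reproduced; preset fields match the experimental geometry and
  gradient ratio but on the simulation irradiance scale discussed above,
  so fitted T values are comparable in order of magnitude, not unit for
  unit.
* Whether β or β′ is the cross-setup invariant is left to the caller:
  both are accepted and never silently rescaled.
* `joint_refine` assumes the local response elasticities have the usual
  signs; exotic fields (e.g. gradient anti-aligned with a much stronger
  directionality term) may need the damping lowered.
* Heading distributions are per accepted step; tracker-derived
  distributions weight by run, which is a documented difference, not a
  bug.
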