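# Methods

## Model

A scalar phase field φ on a cell-centered uniform grid encodes a K-phase
segmentation: phase k is the band φ ∈ [k − ½, k + ½), and the contours are
the half-integer level sets.  The energy has three terms per cell:

* **Transition potential** `BiC(⟨φ⟩)/ε²`, a multi-well penalty composed with
  the fractional part ⟨φ⟩ = φ − ⌊φ⌋ so that every integer is a well.  Three
  variants are implemented and selectable independently of the derivative
  used by the solver:
  * `literal_eq2` — the published five-branch piecewise cubic, kept verbatim
    including its 1/150 normalization.  As printed it is discontinuous at
    |u| = ½ (the inner branches reach 2.875/150 while the outer branches
    reach 1.875/150) and its outer branches read like mistyped B-spline
    tails; it is retained exactly for fidelity and the discontinuity is
    asserted, not hidden.  Note that under the ⟨·⟩ composition the argument
    lies in [0, 1), so the negative branches are unreachable in the solver;
    they are exposed for testing only.
  * `rescaled_bspline` — a continuity-repaired compressed cubic B-spline,
    (4 − 24u² + 24|u|³)/150 for |u| ≤ ½ and (2 − 2|u|)³/150 for ½ < |u| ≤ 1;
    continuous on ℝ with the same normalization.
  * `double_well` — ¼⟨u⟩²(1 − ⟨u⟩)², the antiderivative of the cubic
    derivative the published discretization actually evaluates; this is the
    variant for which the flow is an exact gradient flow.
* **Interface regularization** |∇φ|²/2, centered differences.
* **Data fidelity** (λ/2) Σₖ (C_k − I₀)² sinc²(φ − k), with
  C_k = Σ I₀ sinc²(φ−k) / Σ sinc²(φ−k) the sinc²-weighted least-squares fit
  value of phase k.  The sinc² windows make the "region" of phase k a soft
  neighborhood of the level φ = k over the whole domain; at integer plateaus
  they collapse to indicators and C_k becomes the plain region mean.

The flow is φ_t = −BiC′(⟨φ⟩)/ε² + Δφ − λ Σₖ (C_k − I₀)² d/dφ[sinc²(φ−k)].

Two deliberate convention notes:

* The derivative of sinc² is evaluated in the factored form
  2·sinc(u)(cos(πu) − sinc(u))/u, algebraically identical to
  sin(2πu)/(πu²) − 2sin²(πu)/(π²u³) but exactly zero at the integers, where
  the analytic function has roots; a naive evaluation leaves O(10⁻¹⁶) noise
  there and a plateau exactly at a well would feel a spurious force.
* The fidelity force carries λ while the energy carries λ/2, so the evolved
  flow descends the energy with λ replaced by 2λ.  Both coefficients follow
  their respective definitions; since the factor is a uniform positive
  constant, descent directions and fixed points are unchanged, only the
  effective fidelity weight differs by 2.

## Discretization

* Grid: unit-width domain, h = 1/N_x, square pixels enforced; fields live at
  cell centers.
* Laplacian: five-point stencil with mirrored ghost cells (homogeneous
  Neumann).  The boundary condition is a modeling choice — it is the
  standard one for image diffusion and makes the stencil exactly
  conservative (ΣΔφ = 0 to round-off), which the tests exploit.
* Gradient term in the energy: centered differences with the same mirrored
  ghosts.  This is a different (wider) stencil than the Laplacian's, so
  energy descent of the explicit flow is not an algebraic identity; it is
  verified empirically at the step sizes used.
* Time stepping:
  * `forward_euler` (default): φⁿ⁺¹ = φⁿ + Δt·RHS(φⁿ).
  * `leapfrog`: (φⁿ⁺¹ − φⁿ⁻¹)/(2Δt) = −[BiC′(⟨φⁿ⁺¹⟩) + BiC′(⟨φⁿ⁻¹⟩)]/(2ε²)
    + Δφⁿ − F(φⁿ), bootstrapped with one Euler step.  The implicit potential
    coupling is resolved by Picard iteration started at φⁿ; the contraction
    factor is Δt·max|BiC″|/ε², so the scheme is only usable where that is
    below 1 (it diverges at the reference protocol parameters, and the
    solver raises with the residual norm).  The stopping rule bounds the
    per-cell residual of the three-level relation by 10⁻¹⁰ (plus a round-off
    floor of order ε_mach·|φ|/(2Δt)).  The scheme's printed "transformed"
    rearrangement is self-referential and is not used; the three-level
    relation itself is authoritative.  Leapfrog is second-order consistent
    with Euler pairs (difference O(Δt²), verified by octave halving) but has
    the usual weak instability on parabolic terms, so Euler is the default.
  * Quantities at half time levels appear in the published step list without
    a defining equation and are not implemented.
* Region means are recomputed once per step before the φ update (standard
  alternating minimization; a flag freezes them instead).  A phase whose
  total sinc² weight falls below 10⁻¹² is degenerate — its mean is set to
  the global image mean with a warning, which keeps the force well defined
  without inventing a phase-deletion rule.
* Subgrid mode: interface cells (those separated from a 4-neighbor by a
  half-integer level) get the potential derivative evaluated on an m×m
  subcell lattice and averaged back.  The subcell values come from a
  through-point (Catmull–Rom) bicubic through the cell centers with
  mirrored extension — an interpolating kernel is required ("through the
  cell centers"); the specific C¹ through-point cubic is our choice.  With
  an all-false mask the code path is bit-identical to the regular one.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| ε | ε_m = h·m/(4√2·atanh ρ) | interface width tied to m grid cells at concentration rate ρ; m = 2, ρ = 0.9 reproduce the reference "ε₂" value 9.381·10⁻⁴ at h = 1/256 |
| λ | 3·10⁴ | unstated in the source; fixed by an explicit-stability budget at the reference Δt = 5·10⁻⁶ (λ·Δt·max|d²sinc²| ≈ 1) while keeping the fidelity force within an order of the well force over a typical misfit band |
| Δt | 5·10⁻⁶ | reference protocol value; see the stability caveat below |
| steps | 10 | reference protocol ("after ten iterations") |
| potential | literal_eq2 + printed cubic derivative | what the published scheme computes |

## Stability of the reference protocol

At h = 1/256 the explicit bound for the five-point Laplacian is
Δt ≤ h²/4 ≈ 3.8·10⁻⁶; the reference Δt = 5·10⁻⁶ exceeds it (8Δt/h² = 2.62),
and the solver emits a `StabilityWarning`.  The consequences are sharp and
worth recording:

* **Straight-edged content is unaffected.**  A field varying along one axis
  obeys the 1-D bound h²/2; stripe phantoms at the protocol recover their
  ground truth at 99.6% (K = 4).
* **Curved hard edges ring.**  The staircase boundary of a disk excites
  modes oscillatory in both axes, for which the per-step amplification is
  |1 − 8Δt/h² − Δt·BiC″/ε²| ≈ 1.6–3; over ten iterations a ringing band a
  few pixels wide grows around the circle and caps the pixel agreement near
  96–97% rather than ≥ 99%.  No free parameter changes this (λ = 0 gives
  the same result); it is a property of the printed protocol itself.  Ten
  iterations from noiseless data keep the blow-up localized because the
  unstable modes start at the amplitude of the initial jump only near the
  interface.
* **Noise is fatal at the protocol step.**  Additive noise populates the
  unstable part of the spectrum globally; σ = 0.05 phantoms degrade to
  ≈ 59% at Δt = 5·10⁻⁶ but recover ≥ 99% at Δt = 2·10⁻⁶.  Noisy-input runs
  in the tests therefore use Δt = 2·10⁻⁶ (inside the bound); this is a
  stability envelope, not a tuning.

## Synthetic phantoms

The generator produces piecewise-constant K-phase images (concentric disks,
vertical stripes, checkerboards, rectangular-stroke glyphs) with known label
maps and optional seeded Gaussian noise clipped to [0, 1].  Default
intensities are k/K for interior phases and 1 for the top phase: the
pipeline's affine normalization pins min → 0 and max → 1, and under
φ = K·I₀ these values put the plateau of phase k exactly at well k (the top
plateau lands at K and clips into the top band).  A uniform spacing k/(K−1)
would place the middle plateau of K = 3 exactly on the contour level 1.5
and the third plateau of K = 4 at 2.67 — inside the basin of well 3, where
both the well force and the fidelity force drive it, irreversibly merging
two phases; the chosen defaults are the ones under which the initialization
is consistent with its own banding.

What the phantoms do *not* emulate: sensor point-spread (edges are
pixel-hard, the worst case for the explicit scheme — see above), intensity
inhomogeneity or shading, textured regions, and non-Gaussian noise.
Passing recovery tests therefore demonstrate correctness of the energy,
flow and extraction on exactly-piecewise-constant data, not segmentation
quality on real scans.

## Degenerate inputs and tie rules

* Band-edge ties go upward (φ = k + ½ → phase k + 1); bands are half-open.
* Constant images normalize to all zeros with a warning.
* Multi-channel input is rejected unless luma conversion (Rec. 601) is
  requested explicitly.
* ⟨φ⟩ of a tiny negative number would round to 1.0, outside [0, 1); the
  nearest in-range representable is returned, preserving φ = ⌊φ⌋ + ⟨φ⟩ to
  one ulp.
* sinc and d sinc²/du return their removable limits (1 and 0) for
  |u| < 10⁻⁸.

## Problem sizes in the tests

Unit and property tests run on 4×4–64×64 grids; the end-to-end protocol
checks use the full 256×256 reference size (sub-second per run); recovery
sweeps use 128×128 with ten steps.  The whole suite completes in a few
seconds on one CPU.

## Known limitations

* The leapfrog scheme is unusable exactly at the reference protocol
  parameters (Picard divergence), matching its role here as a fidelity
  reconstruction rather than the recommended solver.
* The literal potential's discontinuity at ⟨φ⟩ = ½ means the energy with
  that variant is not a Lyapunov function of the flow (the solver pairs it
  with the continuous cubic derivative, as published); use `double_well`
  for exact gradient-flow semantics.
* No adaptive time stepping, implicit/spectral solvers, 3-D volumes, or
  color segmentation.
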