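# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic experiments demonstrate.

## Lattice Boltzmann core

The solver is a D3Q19 BGK (single relaxation time) scheme in lattice units
(Δx = Δt = 1, reference density 1).  The equilibrium is the standard
second-order Maxwell–Boltzmann expansion with c_s² = 1/3:

    f_i^eq = w_i ρ [1 + (e_i·u)/c_s² + (e_i·u)²/(2c_s⁴) − u²/(2c_s²)],

with weights 1/3 (rest), 1/18 (face), 1/36 (edge).  Collision relaxes
toward f^eq with time constant τ > 0.5; body forces use the Guo
second-order scheme, whose half-step correction enters the macroscopic
velocity as u = (Σ f_i e_i + F/2)/ρ.  Propagation is a two-array pull
scheme over the dense bounding box (solid voxels carry zeros); at desk
scale (≤ a few 10⁵ sites) this vectorizes better in numpy than indexed
sparse storage.  Walls are rigid no-slip via halfway bounce-back.  Blood is
Newtonian; ν defaults to 3.3·10⁻⁶ m²/s (a standard literature value for
whole blood — the kinematic viscosity is configurable).

Voxel convention: 0-based indices, physical position = origin +
(index + ½)Δx.  Cylindrical lumina contain the voxel centres within
r + ½ of the axis, so the bounce-back wall plane sits at R = r + ½ and the
nominal, equal-area and hydrodynamic radii coincide; end-patch areas are
then ≈ π(R Δx)².  The body-force Poiseuille test validates this
convention: with the "magic" relaxation time τ = ½ + √(3/16) (the SRT
value for which the bounce-back wall location is exact in channel flow)
an r = 10 cylinder reproduces u(r) = G(R² − r²)/(4ρν) to ~2% relative L2,
dominated by the azimuthal staircase of the voxelized circle.

## Boundary closures

Velocity inlets and pressure outlets replace all populations at patch
sites with the equilibrium for the target state after streaming: inlets
impose the target mean normal velocity (uniform by default; a parabolic
profile with peak = 1.5 × mean is available) with density extrapolated
from the interior neighbour; pressure patches fix ρ = P/c_s² with the
interior-extrapolated velocity.  This closure is exact in the imposed
moment, robust at low Mach, and deliberately sits behind one narrow
interface so a different scheme (e.g. non-equilibrium bounce-back) can be
swapped in.  A guard rejects any boundary target at or above lattice speed
0.1.  Because the closure resets the ρ–u combination on the patch layer
itself, mass-budget diagnostics evaluate fluxes one layer inside the
fluid, where ρu is the transported flux.

## The coupling model

The unresolved capillary bed between an arterial outlet (subscript 0) and
its N venous inlets is modelled per link as a linear resistance,
ΔP_i = k_i q_i L_i with k_i ∝ 1/A_i, where L_i is the centroid–centroid
distance between the coupled patches.  The pressure-drop fraction
ΔP_i/P_0 is drawn i.i.d. from U(0.3, 0.7) — the physiologically expected
range for the pressure lost crossing the microcirculation — from a seeded
generator.  Combining the resistance law with q_0 = Σ q_i gives the
velocity scale factor v_i/v_0 = (A_0/A_i)·w_i/Σ_j w_j with
w_i = ΔP_i A_i/L_i; the equivalent ratio-of-ratios form (every quantity
referenced to link 1) is verified against this simplified form in the
tests.  The identity Σ (A_i/A_0)(v_i/v_0) = 1 holds to round-off by
construction and is asserted to 10⁻¹² over 10⁴ random groups.

Map construction is a two-pass nearest-neighbour assignment on patch
centroids (Euclidean distance, world frame): pass 1 visits outlets in
ascending patch-id order and each claims its nearest unassigned inlet
(guaranteeing outlet coverage); pass 2 assigns every remaining inlet to
its nearest outlet.  Ties break to the lowest patch id.  Both the
iteration order and the tie-break affect the map, so they are fixed and
documented; distance between centroids is the simplest faithful reading
of "proximity of boundary locations".

Exchanges pass only patch-averaged values and alternate direction.
Forward: each venous inlet's velocity target is its factor times the
arterial outlet's mean velocity (averaged over the steps since the last
swap); the inlet-side pressure bookkeeping value is (1 − ΔP_i/P_0)·P_0.
Reverse: each arterial outlet receives the mean over its links of the
factor-descaled venous inlet velocities — the venous tree's consensus
estimate of v_0 — as the target of a capillary-bed body force.  Descaling
by the forward factor is adopted because it exactly inverts the forward
map (a round-trip with consistent velocities returns v_0).  The exchange
cadence defaults to every 10 steps; a 1:1 robustness test shows steady
ratios shift < 1% between cadences of 1 and 10.

The coupled-outlet force acts along the outflow direction with per-site
magnitude gain·(target − mean_v)/v_ref·(½ρ|u|²), v_ref =
max(|target|, |mean_v|): it vanishes with the dynamic pressure at rest and
at the fixed point mean_v = target, and otherwise steers the patch mean
toward the target.  It is applied through the Guo scheme *on top of* the
outlet's pressure closure (both orderings are conceivable; force-plus-
closure keeps the outlet well-posed when the coupled target is stale).
The proportional gain (default 10) trades tracking speed against
stiffness; because the arterial through-flow is set by its own inlet, the
coupled force is a consistency nudge rather than the primary driver, and
the achieved-ratio verification is insensitive to it.

## Unit system and guardrails

Lattice–physical conversion is fixed by (Δx, Δt, ρ_ref); τ follows from
ν = (1/3)(τ − ½)Δx²/Δt and the Mach check from Ma = 3 v_max Δt/Δx.  A run
configuration is refused when τ ≤ 0.5 or Ma ≥ 0.1 and warned when τ > 1.
The physiological reference scenario (1 m/s peak, 25 µm, 1 µs) evaluates
to τ ≈ 0.5158 and Ma = 0.12 — flagged as infeasible, which is precisely
why production-scale runs need finer steps and large machines.  Matching
Reynolds number with artificially raised viscosity is possible by
overriding ν in the config; it is off by default.

## Synthetic geometries and what the experiments show

All domains are generated programmatically and deterministically:

* **Tube** — straight cylinder, one inlet, one outlet (or periodic for the
  Poiseuille test).
* **1:N pair** — arterial square channel above a venous domain of N equal
  square inlet channels draining through a plenum into one outlet; the
  arterial channel is offset horizontally so all outlet–inlet centroid
  distances are distinct and the nearest-neighbour map is unambiguous.
  The 1:3 instance has ~7300 fluid sites; the verification run uses 4000
  steps with exchanges every 10 steps, passing the steady-state criterion
  (all patch means varying < 0.1% over a 500-step window, the package's
  operational definition of steady state) around step ~1200.
* **Random patch clouds** — seeded centroids standing in for large coupled
  trees (e.g. 38 arterial outlets / 494 venous inlets, 13 inlets per
  outlet on average), used to exercise map construction at realistic
  counts without voxel geometry.
* **Bifurcating tree** — three generations (9² → 2×7² → 4×7² channel
  cross-sections, ~1.1·10⁴ fluid sites) whose total lumen area grows
  distally, as in real arterial trees.  At steady state the mean speed at
  the quarter/half/three-quarter measurement planes falls monotonically
  and the per-vessel area–speed association is positive (Spearman ≈ 0.6)
  — the expected arterial velocity-versus-area trend.

Cross-section analysis slices planes perpendicular to a chosen axis,
splits in-plane fluid into 8-connected components (one per vessel), takes
the mean of per-site speed magnitudes (chosen over the magnitude of the
mean velocity because the observable is speed), and estimates vessel area
by the 2D convex hull of site centres, falling back to face counting for
degenerate slices.  Arterial rows are tabulated with negated area purely
as a plotting convention.

These fixtures emulate topology, patch bookkeeping and coupling behaviour
of vascular trees; they do **not** emulate anatomical curvature, elliptic
lumina, pulsatile drive, wall compliance or non-Newtonian rheology.
Passing tests therefore validate the solver kernel, the closures and the
coupling algebra/protocol — not hemodynamic fidelity against physiological
data.

## Numerical details and degenerate inputs

* Initialization: ρ = 1, u = 0 equilibrium everywhere.
* Patch normals: dominant axis direction voted by (solid-behind,
  fluid-ahead) site pairs; exact for the planar axis-aligned patches all
  fixtures produce.
* Patch means: spatial average of the face-normal velocity in the natural
  flow direction (inward for inlets, outward for outlets); exchanges use
  the time average since the previous swap.
* Degenerate guards: non-positive density or pressure, τ ≤ 0.5, boundary
  targets above the Mach guard, zero-length or zero-area links, fixtures
  with infeasible parameters, and planes without fluid all raise typed
  errors (or warn and fall back where the contract specifies).
* Determinism: all randomness flows from explicit seeds; repeated runs of
  one configuration produce byte-identical CSV outputs.

## Known limitations

Single-relaxation-time collision only; equilibrium-completion closures are
first-order accurate at boundaries; the in-process coupling emulates the
message contents (averaged states) but not the parallel mechanics of a
multi-instance MPI deployment; the capillary-bed resistance is linear and
memoryless (no porous-media or windkessel dynamics); and the voxel
fixtures are axis-aligned idealizations.
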