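# Methods

## Fluid model

Plasma is an incompressible Newtonian fluid solved with a forced
single-relaxation-time (BGK) lattice-Boltzmann method. Populations
`f_i` on a D3Q19 lattice (the velocity set is abstracted; D3Q27 is a
drop-in) evolve by

```
f_i(x + c_i, t+1) − f_i(x, t) = −(f_i − f_i^eq)/τ + F_i
```

with the second-order equilibrium, the Guo forcing term
`F_i = (1 − 1/2τ) w_i [(c_i − u)/c_s² + (c_i·u)c_i/c_s⁴]·f`, and the
matching half-force shift in the velocity moment,
`ρu = Σ f_i c_i + f/2`. With this pairing the macroscopic momentum
gains exactly `f·Δt` per step, which the suite asserts by moment
summation. The relaxation time follows from the physical kinematic
viscosity: `τ = 3 ν_p Δt/Δx² + ½`; `τ ≤ ½` is a hard error and values
outside `(½, 3]` are warned about. A Mach guard logs whenever
`|u|/c_s > 0.1`.

Boundaries: periodic wrap (via the streaming roll), halfway bounce-back
for resting solids, and bounce-back with the momentum correction
`−2 w_i ρ (c_i·u_w)/c_s²` for moving plates. Wall faces add one layer
of solid nodes outside the declared fluid extent, so a declared gap of
`d` is exactly `d` between the two halfway wall planes; node centers
sit at `(i+½)Δx`. Couette flow is then machine-exact and Poiseuille
flow is second-order accurate (≈0.3 % L2 error at 20 nodes across the
gap).

A fused compiled (numba) collision kernel and the vectorized numpy
path compute bit-identical updates; the numpy path is the reference
and the suite cross-checks the two.

## Membrane model

Cells are closed triangulated surfaces: RBCs use the Evans–Fung
biconcave profile (an icosphere with its axial coordinate scaled by
`½(c0 + c1ρ² + c2ρ⁴)`, c0 = 0.207161, c1 = 2.002558, c2 = −1.122762,
then scaled to the 8 µm diameter), CTCs are icospheres. The reference
geometry frozen at build time (edge lengths L0, face areas A0, hinge
angles θ0, volume V0) is the force-free state, so the built shape —
not a flat sheet — is the bending ground state.

Four force families act, each with a pole-regularized strain law
(relative strains dL, dθ, dA, dV; poles at limiting strains τ):

| family  | scalar law | stiffness (units of k_BT) |
|---------|------------|---------------------------|
| link    | −κ_l dL/p · [1 + 1/(τ_l²−dL²)] | κ_l = 15 |
| bending | −κ_b dθ/L0 · [1 + 1/(τ_b²−dθ²)] | κ_b = 80 |
| area    | −κ_a dA/L0 · [1 + 1/(τ_a²−dA²)] | κ_a = 5 |
| volume  | −κ_v dV/L0 · [1/(τ_v²−dV²)]     | κ_v = 20 |

τ_v = 0.01 keeps the cell quasi-incompressible. τ_l = τ_a = 2,
τ_b = π/2 and the persistence length p = 2.5 nm are not fixed by the
constitutive statement; these defaults are literature-typical spectrin
values and are configurable. Temperature is 300 K (configurable), so
k_BT = 4.14×10⁻²¹ J. L0 in the bending/area/volume laws is the local
element's rest length, not a global mean.

The per-vertex vector fields are implemented as exact analytic
gradients of the corresponding potentials
(`G(x) = x²/2 − ½ ln((τ²−x²)/τ²)` for the "1+" laws and its pole part
for the volume law): the dihedral-angle gradient for bending
(off-hinge vertices pushed along the face normals, hinge vertices
carrying the lever-arm compensation so each hinge's net force and
torque vanish), the triangle-area gradient for the area force, and
the divergence-theorem volume gradient. This makes the total force
field conservative, reproduces the stated directions (toward the face
centroid / cell centroid) in the symmetric limit, and lets the suite
verify every family against a central-difference gradient of its
energy to better than 1e−4 relative. Crossing a pole
(|strain| ≥ τ) raises a hard error rather than clamping — it means
the step size is unstable.

Phenotypes: the stiff CTC class multiplies κ_l and κ_b by 5 while κ_a
and κ_v stay fixed. Adhesion to micropost surfaces uses a 12-6
Lennard-Jones law parameterized by well depth, zero-force distance
and cutoff, with capped repulsion below half the zero-force distance.

## Fluid–structure coupling

Standard immersed-boundary method. Per step: membrane forces →
spreading `f(x) = Σ F(X_i) δ(x−X_i)` → LBM collide + stream →
interpolation `U(X_i) = Σ u(x) δ(X_i−x)` → forward-Euler advection.
The discrete delta is the 4-point Peskin cosine kernel by default
(2-point hat available; both are non-negative partitions of unity,
the hat reproduces linear fields exactly). Force spread into solid
nodes is dropped with the deficit accumulated on the simulation
object. Vertices are kept unwrapped in physical space; the periodic
wrap happens inside the kernel stencils, which realizes the pipe's
"reintroduced at the inlet" recirculation with no special casing.
Spreading conserves total force to rounding; a membrane sphere in
uniform flow translates with the flow to < 2 % with volume drift
< 1 %. Because the interpolated velocity field is not exactly
divergence-free, a cell's enclosed volume drifts slowly in long runs;
a volume guard (on by default) rescales the shape about its centroid
back to half the τ_v pole when the drift reaches 0.6 τ_v and logs the
cumulative correction. Pole crossings from genuine elastic
deformation still raise an error.

## Geometries

Scenes are voxelized on node centers: a node is solid iff its center
lies inside an obstacle or outside the pipe bore. Obstacles are
cylindrical posts, boxes and a flat-topped wedge (linear leading
ramp, flat measurement top, vertical trailing face). Generated
micropost layouts are a hyperuniform-like surrogate — random
sequential addition under a surface-gap constraint, Monte-Carlo Lloyd
relaxation toward uniform coarse density, then pairwise separation to
restore the gap — with coarse-bin count variance below the Poisson
reference; the real device layout can be loaded verbatim from a text
file (x y radius in µm per line).

## Scenarios and scaled problem sizes

All presets default to desk scale so every scenario runs on one CPU;
paper-scale extents (e.g. the 300×2200×25 µm³ device subdomain, the
90 µm pipe at Δx = 0.25 µm) remain available through configuration.

* **Pipe**: periodic cylindrical channel, body force set from the
  analytic plasma Poiseuille solution for a target Reynolds number;
  RBC discs start perpendicular to the flow, spaced by the
  hematocrit map (linear in 1/d through Hct 0.1 ↔ 22 µm and
  0.49 ↔ 4.5 µm). The desk benchmark uses a 22.5 µm channel of
  radius 5 µm at Re = 0.5 with five cells (the Hct ≈ 0.49 spacing
  analog): the slightly enlarged bore keeps the near-wall lubrication
  gap resolved at Δx = 0.5 µm. The fluid is initialized at the
  developed Poiseuille profile so the recorded transient is the
  cells' shape adaptation rather than the fluid spin-up. The
  deformation index ε = |h−h₀|/h₀ (h measured across the flow,
  h₀ = 8 µm) rises to a plateau; the plateau time is reported in
  units of T0 = L/u0.
* **Shear box**: 20×20×10 µm³, plates at ±v0 so the shear rate is
  2v0/d. Desk-scale regime runs use viscous scaling: the shear rate
  is multiplied by S = 1000 with the fluid viscosity raised to keep
  the Reynolds number ≪ 1 and all four membrane stiffnesses raised to
  keep the capillary number fixed, which compresses a treading period
  to O(10³) steps while preserving the Stokes-regime dynamics.
  Regime labels use the operational rules in `analysis`
  (inclination band ±15°, ≥ 2 treading turns by default; thresholds
  configurable): treading = body-frame marker circulation with stable
  inclination; tumbling = end-over-end axis advance; rolling =
  rotation about the flow axis.
* **Wedge**: ramp + flat-top obstruction, body-force driven; the
  surface shear stress τ = μ ∂u_x/∂z is a one-sided finite
  difference over the first two fluid layers above the top patch
  (exact for linear profiles). RBC-laden runs seed cells uniformly
  in the free lumen.
* **Micropost channel**: quasi-2D confinement (desk preset
  120×40×12 µm³, 12 posts of radius 3 µm, mean speed 1.5 mm/s),
  used by the dataset generator.

## Trajectory dataset

`generate_trajectory_dataset` releases cells of both phenotypes at
random inlet positions in the same channel realization and records
t, x, y, z, vx, vy, vz every 1 ms. Two modes share the geometry and
membrane model:

* `full`: the complete two-way IBM coupling (used for validation at
  small cell counts).
* `fast` (default): the steady plasma flow is solved once with the
  LBM; each cell then follows overdamped membrane dynamics in the
  frozen field — vertex velocity = interpolated fluid velocity +
  mobility × elastic force, with mobility 1/(6πμa), a = 0.25 µm
  drag radius per vertex. Post and wall contact is a projection
  (displacement-capped so a straddling mesh cannot tear), applied
  along the cell-centroid radial direction so contact acts on the
  cell coherently. The explicit step resolves the fastest membrane
  relaxation rate (λ·dt ≤ 0.7, so the 5×-stiff class integrates at a
  proportionally smaller dt — resolving that rate is what preserves
  the phenotypes' different deformation response). Two reduced-order
  concessions are made for robustness, both documented here and
  absent from the full mode: strains saturate at 0.999 of their pole
  (hard contacts produce very large but finite restoring forces
  instead of aborting), and a volume-projection guard rescales the
  shape about its centroid when a contact event drives |dV| past
  0.6 τ_v. Cells are propagated as a single vectorized batch per
  phenotype (identical mesh topology, no cell–cell interaction in
  the dilute limit).

What the fast mode does not capture: two-way momentum exchange
(cells do not perturb the flow), cell–cell hydrodynamics, inertial
lift, and thermal fluctuations. Class separation therefore rests on
deformation-mediated path differences around posts — the same
mechanism as the full model, at reduced fidelity. Passing
classification tests on this data shows the pipeline can read
elasticity from kinematics under those assumptions, not that the
reduced trajectories match wet-lab tracks quantitatively.

## Classifiers

Sequences are linearly resampled to a common length (T = 128 default;
64 in the desk runs), stratified-split, and standardized per channel
with train-set statistics. The CNN processes position channels
(x, y, z) and velocity channels (vx, vy, vz) in separate
conv(16, k5) → pool → conv(32, k5) → pool branches, concatenated into
dense(64) → dense(2). The RNN stacks two bidirectional Elman (tanh)
layers of hidden size 32, each followed by batch normalization and
dropout 0.3 and halving the sequence length, then dense(32) →
dense(2). Both train with Adam (batch 32) on softmax cross-entropy;
all randomness flows through one seeded generator, so training is
bit-reproducible, and the best-validation-accuracy weights are kept.
These widths/epochs are reconstructions — the original
hyper-parameters are not public. A logistic regression on summary
features (per-channel means, spreads, net changes) runs alongside as
a leakage guard. The layer stack is implemented directly in numpy
with hand-written backpropagation; every layer's gradient is verified
against finite differences in the suite, and the trapezoid AUC is
cross-checked against the rank-statistic (Mann–Whitney) computation
and sklearn's reference on identical scores.

## Numerical choices and limitations

* Lattice units internally; one `UnitConverter` owns dx, dt, ρ.
* Voxelization is staircase (first-order at curved walls).
* The IBM membrane is massless and the coupling explicit; very stiff
  membranes at coarse resolution can cross a strain pole, which the
  full model treats as a hard error (reduce dt or refine).
* The hematocrit ↔ spacing map interpolates linearly in 1/d between
  the two stated endpoints.
* Hyperuniform layouts are a surrogate; the real device's
  construction is configuration, not code.
* The regime thresholds (±15° band, 2 turns) are operational
  definitions; the underlying physics is qualitative.
* No thermal membrane fluctuations, membrane viscosity, white cells
  or platelets; two phenotype classes only.
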