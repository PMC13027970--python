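# Methods

## Physical model

The package simulates steady, incompressible, isothermal flow of a
Newtonian fluid in two parallel rectangular microchannels separated by a
perforated membrane. The lower (feed) channel flows in +x, the upper
channel in −x (counter-current). The membrane is a horizontal band of
solid wall segments interrupted by rectangular pores — short vertical
channels that connect the two flow channels — and the flow **inside the
pores is resolved directly** by the same momentum balance as the channel
flow. No Darcy or lumped-permeability closure is applied anywhere in the
2D solver; the membrane's hydraulic behaviour emerges from the resolved
pore geometry.

At the operating point of interest (water-like fluid, `u_mean` = 1 m/s,
channel height 15 µm, ν = 3×10⁻⁷ m²/s) the Reynolds number based on the
channel height is `u·h/ν` = 0.05, so inertia is negligible and the
convective terms are dropped. Gravity is likewise negligible against
viscous stresses at these scales and is kept only as explicit constants
fixed to zero. The governing equations are the Stokes momentum balance

    (1/ρ) ∂p/∂x = ν (∂²u/∂x² + ∂²u/∂y²)
    (1/ρ) ∂p/∂y = ν (∂²v/∂x² + ∂²v/∂y²)

with the continuity constraint ∂u/∂x + ∂v/∂y = 0.

A 2D (depth-averaged-free) description is appropriate because the device
width is much larger than the 15 µm channel height.

## Geometry and grid

All lengths are multiples of the uniform square grid spacing `dx`
(default 0.25 µm). With pore width 4 µm and wall width 1 µm, a membrane
with `n` pores spans `L = 5n + 1` µm — it begins and ends with a wall
segment — and the default stack (15 µm channel + 15 µm membrane + 15 µm
channel) is 45 µm tall; the 60-pore domain is the reference 1205 × 181
node grid (~218 k nodes). Wall segments are closed intervals: a node that
falls exactly on a pore/wall boundary is solid, so each pore opening is
exactly `pore_width` of wall-to-wall fluid gap. The channel/membrane
interface rows follow the same rule, which makes every pore a true
vertical channel.

Boundary conditions:

* **Inlets** — fully developed parabolic profile
  `u(ŷ) = 6·u_mean·(ŷ/h)(1−ŷ/h)`, v = 0; mirrored and negated at the
  upper-channel inlet. A Simpson-quadrature check (exact for the
  parabola) rejects profiles whose flux deviates from `u_mean·h` by more
  than 0.1 %.
* **Outlets** — p = 0 and zero streamwise gradient of u and v.
* **Walls and membrane solid** — no-slip (u = v = 0). A free-slip
  (mirror) alternative is exposed as a configuration switch but is
  untested against reference data; the no-slip choice is required for
  consistency with the parabolic inlet (`u_max = 1.5·u_mean`).
* **Inlet pressure** — the pressure is not prescribed; its inlet ghost
  value is extrapolated with the slope implied by the momentum balance of
  the prescribed profile, `∂p/∂x = μ·∂²u/∂y²` (= −12 μ u_mean/h² for the
  parabola). A plain zero-gradient ghost instead loses O(dx/L) of the
  reported inlet pressure — about 8 % on the shortest (6 µm) channel —
  because the reported value then corresponds to the first interior
  column. With the momentum-informed ghost the sealed-duct solution is
  exact (see below).

## Discretisation and solvers

Velocity and pressure are collocated on the grid nodes. Momentum uses the
5-point central Laplacian; gradients and divergence use central
differences with mirror ghosts across solid faces. On the square grid the
momentum diagonal is the single scalar `Ap = 4ν/dx²`.

Two solution paths solve the same discrete equations:

* **Coupled (default).** The momentum stencils, the central continuity
  equation and the ghost conventions are assembled into one sparse saddle
  system in (u, v, p) and eliminated with SuperLU. Because the central
  (wide) gradient/divergence pair on a collocated grid has an odd–even
  (checkerboard) pressure null mode, the continuity rows carry a
  Rhie–Chow-magnitude stabilisation
  `D·u − (L_c − L_w)p/(ρ·Ap) = 0`, where `L_c` is the compact 5-point
  Laplacian and `L_w = D·G` the wide one. The term vanishes at O(dx²) on
  smooth pressure fields and suppresses the checkerboard mode. The two
  operators disagree on smooth fields only within two columns of the open
  inlet/outlet boundaries (their ghost conventions differ there), so the
  stabilisation rows are dropped in that strip; the interior rows still
  pin the null mode. Without the stabilisation the computed pressure
  carries node-to-node noise of several per cent of the inlet pressure
  and the channel drag is overestimated by ~11 % relative to an
  independent staggered-grid discretisation; with it the two
  discretisations agree to 1–2 % (see Verification).
* **Projection (`method="projection"`).** The classical iterative loop:
  red–black SOR momentum sweeps (or prefactorised direct momentum
  solves) with the current pressure, a pressure-correction Poisson
  equation `∇²(δP) = Ap·∇·U′` with δP = 0 at outlets and `∂δP/∂n = 0`
  elsewhere, velocity projection `U = U′ − ∇(δP)/Ap`, and pressure
  accumulation. The correction formulas are written in the kinematic
  (p/ρ) convention; the accumulated physical pressure therefore gains a
  factor ρ. The loop's fixed point is exactly the **unstabilised**
  coupled system, which the test suite verifies both ways (the coupled
  solution is a fixed point of one projection cycle; the iterated loop
  approaches it). The loop converges slowly — the checkerboard-adjacent
  modes are nearly ill-posed — so it is kept for methodological
  transparency and small studies, not as the production path.

Convergence is measured by a scale-free combined residual: the maximum of
the L∞ momentum residual normalised by `Ap·u_mean` and the L∞ residual of
the continuity system normalised by `u_mean/dx`; the default tolerance is
10⁻⁵. The coupled path reaches ~10⁻¹³ in one solve. Note that with the
stabilised continuity the *raw* central divergence retains localised
residuals at the re-entrant pore-mouth corners, where the Stokes pressure
is genuinely singular; integral mass balance per channel is conserved to
~0.004 % (bound asserted in tests: 0.5 %).

Deterministic throughout: zero initial fields, no random state; repeated
runs are bit-identical.

### Problem sizes and cost

The reference cases solved by `scripts/acceptance.py` are the 1-, 20- and
60-pore domains at dx = 0.25 µm (4.5 k, 73 k and 218 k nodes). On one CPU
the coupled solves take ≈0.2 s, ≈25 s and ≈100 s and peak at ≈5 GB for
the largest case. The test suite exercises the full physics on coarse
dx = 0.5 µm fixtures (1–20 pores) and repeats the two large reference
solves once.

## Analytical references

* **Plane Poiseuille pressure** `P = 12 μ u_mean L / h²` — the sealed
  (no-membrane) limit used for validation and non-dimensionalisation.
* **2D channel permeability** `K = h²/12` and the membrane open-area
  fraction `n·w_pore/L` (→ 0.8 as n grows; its square, 0.64, is the areal
  reading of the same layout — both are reported, neither asserted as the
  one true porosity).
* **Lumped 1D counter-current model.** Each channel is reduced to its
  mean velocity with the lubrication pressure gradient
  `dp_k/dx = −12 μ q_k / h_k³`, coupled by a Darcy-type wall flux
  `v_w = Lp (p₁ − p₂)`; continuity `dq₁/dx = −v_w`, `dq₂/dx = +v_w`.
  Solved as a linear two-point boundary-value problem
  (`scipy.integrate.solve_bvp`) with inlet fluxes and zero outlet
  pressures. The wall hydraulic permeability `Lp` is a user input (the
  reference tabulation gives 5.16×10⁻⁵ m/(Pa·s) without reproducible
  inputs); a clearly-labelled estimate
  `Lp_est = (w_pore²/12)/(μ h_m) · φ` is provided. The 1D model is used
  for qualitative comparison only — the tests assert the ordering
  `p_CFD < p_1D < p_Poiseuille` for the reference configurations, not
  numerical agreement.

## Verification

* **Sealed-duct exactness.** With the membrane sealed, the parabolic
  velocity and linear pressure lie in the discrete scheme's null space,
  so the solver reproduces the closed-form inlet pressure to machine
  precision at every grid spacing — a stronger statement than the formal
  O(dx²) accuracy.
* **Independent discretisation.** The test suite contains a separate
  staggered-grid (MAC) Stokes solver — cell-centred pressure,
  face-centred velocities, half-cell no-slip ghosts, sharing no code with
  the package — used as a cross-check on coarse fixtures. On the 1-pore
  domain the two discretisations agree on inlet pressure and mid-length
  velocity to better than 3 %; grid-refinement studies during development
  showed 1–2 % agreement on the 20-pore reference case and ~4 % on the
  60-pore case at dx = 0.5 µm.
* **Structural invariants** (all asserted in tests): exact linearity of
  (u, v, p) in `u_mean` and of p in μ; point symmetry of the
  counter-current solution under 180° rotation to machine precision on
  the velocity field; per-channel mass balance; monotone trends of inlet
  pressure (↑), mid-length velocity (↓) and near-inlet vertical velocity
  (↑) with pore count.

## Relation to the published reference values

The published table for the 20- and 60-pore cases (inlet pressure,
mid-length horizontal velocity, near-inlet vertical velocity) differs
from the converged solution of the stated problem by roughly +6 % to
+38 % on pressure/velocity with the vertical velocity 13–19 % low — i.e.
it shows systematically *less* transmembrane leakage than the converged
field. Both of this package's independent discretisations agree with
each other and disagree with those table rows in the same direction, and
a trajectory study of the iterative projection scheme shows the published
pressure value is passed transiently part-way through its slow
convergence. The package therefore reports the converged values and makes
no attempt to emulate a partially converged state. The shortest-channel
transmembrane pressure (97 Pa) and every closed-form and geometric
reference value are reproduced at or beyond their printed precision.

## Known limitations

* 2D only; no third dimension, no pore tortuosity or randomness (pores
  are a regular 1D lattice of rectangular slots).
* Creeping flow only — the convective term is absent by design; results
  apply to Re ≪ 1.
* No solute transport: hydrodynamics only, although the transmembrane
  pressure and wall-velocity fields are the inputs a convection-driven
  transport model would need.
* The corner singularities of Stokes flow at the 270° pore-mouth corners
  are represented only to first order locally; headline metrics are
  sampled away from corners and are grid-converged to ~1 %.
* The free-slip wall option and non-equal channel heights are plumbed
  through the configuration but not validated against any reference.
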