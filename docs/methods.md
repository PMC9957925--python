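# Methods

## The interface model

The package simulates quasi-static debonding of a bone-implant interface
(BII) whose strength derives from two sources: press-fit friction and the
structural bond formed by osseointegration.  The bond at each interface
point is tracked by a state variable `phi in [0, 1]` that starts at the
initial degree of osseointegration `phi0` and degrades irreversibly with the
accumulated interface deformation

    g_d = g_s            (modified Coulomb law, MC)
    g_d = g_s + g_sn     (extended modified Coulomb law, EMC)

where `g_s` is the path length of irreversible tangential slip (distance
between the current positions of the current and previous interacting master
points, summed over load steps) and `g_sn` the accumulated absolute change
of the normal gap.  Both are path integrals of absolute increments: they
never decrease, so a slip excursion of +10 um followed by -10 um contributes
20 um.  The bonding state is

    phi(g_d) = phi0 * w(g_d),   w = 1                     for g_d <  a_s
               0.5 - 0.5 sin( pi/(2 b_s) (g_d/a_s - b_s - 1) )
                                                          for a_s <= g_d <= a_s (1 + 2 b_s)
               0                                          beyond,

a C0, non-increasing window: `a_s` (m) is the deformation the bond tolerates
unharmed, `b_s` (dimensionless) the width of the breakdown zone.

**Friction.**  The Coulomb coefficient interpolates between an unbroken and
a broken value, `mu(phi) = phi mu_ub + (1 - phi) mu_b`.  With `phi0 = 0` the
model reduces exactly to classical Coulomb friction with `mu_b`.

**Normal adhesion (EMC only).**  The tensile branch is an exponential
cohesive zone, `t_n(g_n) = phi0 t0 (g_n/g0) exp(1 - g_n/g0)` for
`0 <= g_n < g_b`, zero beyond the cutoff `g_b` or once `phi = 0`;
compression is penalty contact `t_n = eps_n g_n` for `g_n < 0`.  With
`g_b = g0` (the default) the curve is ascending-only with a sharp drop at
peak, matching the abrupt failure seen in coin-implant pull-off experiments.
The sliding limit is shifted so friction survives moderate tension:

    t_t_slide = mu(phi) * max(0, phi0 t0 - t_n).

We scale the adhesive offset by `phi0` (the cohesive amplitude), so that the
sliding threshold of a weakly integrated interface is proportionally weaker
and all three laws nest exactly: EMC -> MC as `t0 -> 0`, MC -> Coulomb as
`phi0 -> 0`.  For the fully integrated demonstrations (`phi0 = 1`) this
coincides with the unscaled form.

**Calibration.**  `t0` is fixed by inverting the peak force of a uniformly
separating circular interface, `F = phi0 t0 pi R^2`: a 9 N pull-off at 26 %
osseointegration on a 2.5 mm coin gives `t0 = 1.8 MPa` (equivalently ~35 N
at full bonding).  `calibrate_t0` exposes this inversion.

## Finite-element machinery

Both bodies are compressible Neo-Hookean
(`sigma = Lambda/J ln J I + G/J (b - I)`), discretized with 8-node
hexahedra, 2x2x2 Gauss quadrature, total-Lagrangian internal forces with the
analytically consistent material tangent (verified against finite
differences to 1e-6 relative).  Quasi-static equilibrium is solved by Newton
iteration on a reduced system `u = u_p + T q` that carries Dirichlet data
and *force-held groups*: all vertical dofs of a driven surface condensed to
one master unknown carrying a prescribed total force — this is how constant
+/- normal-force holds are imposed exactly while lateral motion or rotation
is prescribed.

**Contact discretization.**  The bone surface is the slave (it owns the
bond state — osseointegration is a property of the peri-implant bone), the
implant surface the master.  Each slave quad facet carries a 5x5 Gauss rule;
every point is projected onto the master facets by Gauss-Newton closest-point
iteration with an axis-aligned broad phase (search radius `3 g_b`).
Projections whose in-plane offset from the clamped parametric point exceeds
0.2 % of the facet size are rejected: points beyond the master boundary drop
out of contact instead of smearing pressure onto an edge ring (with this
choice the active area of the pressed coin matches `pi R^2` to ~2 %).
Master normals are *vertex-averaged and interpolated* across facets; on
curved masters (the cup) this removes the crease discontinuities of raw
bilinear facets that otherwise stall the Newton iteration — it plays the
role that smooth surface enrichment plays in isogeometric contact codes.
The coin cross-section is a mapped-square disk scaled so the coarse polygon
footprint has area exactly `pi R^2`.

**Tangential stick** is penalty-regularized: the trial traction is the
committed traction minus `eps_t` times the incremental tangential relative
motion of the slave point against the tracked material master point, then
radially returned onto the slip circle (tie classified as sliding).  Damage
and stick references are committed once per *converged* load step, never per
Newton iteration, so the damage path is solver-independent.  A point whose
traction drops to zero (open) is frozen — damage needs an interacting point —
and re-contact restarts accumulation from the new projection.

**Solver settings.**  Relative residual tolerance 1e-6 (force scale), 40
iterations, step bisection to depth 5.  The contact tangent keeps the
dominant penalty/cohesive/return-mapping blocks and drops projection-
curvature terms, so terminal convergence is linear rather than quadratic;
1e-6 of a ~100 N load resolves reactions to ~1e-4 N.  Two stabilizations
address the semi-smooth structure: the active/stick/slip set is frozen after
iteration 10 (kills set chattering), and an iteration that stagnates below
1e-3 of the contact-force norm is accepted — the residual floor of a faceted
penalty discretization (points crossing facet or boundary creases) is not
resolvable by smooth iteration and is orders of magnitude below any reported
reaction.

## Scenarios

**Coin-shaped implant (CSI).**  Titanium cylinder R = 2.5 mm, H = 3 mm
(E = 113 GPa) centered on a 12.5 x 12.5 x 5 mm trabecular block
(E = 18 GPa, nu = 0.3 both); bottom fixed; penalties
`eps_n = eps_t = E_b / 0.01 m`.  Interface: `a_s = 22 um`, `b_s = 0.74`,
`mu_ub = 0.44`, `mu_b = 0.3`, `t0 = 1.8 MPa`, `g0 = g_b = 3 a_s` (we follow
the text value `g_b = 3 a_s`; an alternative table entry `g_b = a_s` would
contradict the stated ascending-to-cutoff shape).  Mesh: 3x3x2-element
mapped-disk implant (9 contact facets) over a 15x15x2 block (225 slave
facets) — the reference resolution of the original study.  Stages: press to
-70 N (displacement-driven, stop-on-force with a secant landing to
|dF| < 0.014 N), bond the contacting interface homogeneously at `phi0` with
damage reset (insertion slip must not pre-consume the bond), then the
removal path: tangential slide (mode II), torsion (mode III) at
0.65 um / 0.1 deg per step under a constant -70 N or +20 N hold, or an
oblique displacement ramp at angle alpha (mode I+II).  Tension-held stages
terminate with a zero-force record once the remaining cohesive capacity
falls below the held force — the abrupt pop-off.

**Acetabular cup (ACI).**  Hemispherical shell R_i = 25.5 mm, 3 mm thick
(thickness is not critical and was fixed at 3 mm), titanium; steel ancillary
shaft tied to the cup pole by shared nodes; trabecular cylinder R = 50 mm,
H = 40 mm with hemispherical cavity `R_b = R_i - IF/2` meshed as a spherical
O-grid on a cubed-hemisphere parametrization with radial grading toward the
cavity.  The 2 mm rim fillet is represented at coarse resolution by a small
radial relief of the rim ring.  Reference parameters `E_b = 0.2 GPa`,
`IF = 1 mm`, `mu_b = 0.3`, `mu_ub = 1.5 mu_b`, `a_s = 128 um`, `b_s = 1.84`,
`g0 = g_b = 3 a_s`, penalty `E_b / 0.0255 m`.  Stages: insertion to
F0 = -2500 N (stop-on-force, secant landing; the attained displacement is
`d0`), homogeneous osseointegration, then removal: mode I pulls the
ancillary top up by d0, mode II drives the ancillary-top center node
laterally by d0, mode III rotates 10 degrees about the axis.  The default
resolution (cubed-hemisphere n = 4, ~200 bone elements) is far below the
original 20 000-element study; it reproduces the qualitative removal
behavior and the friction-plateau torque of the reference torsion case, and
a `sweep` utility with config-hash caching covers parameter grids.  Full
Table-resolution runs are possible through the mesh parameters but are not
exercised by the test suite.

## What the tests do and do not show

All verification targets are simulation-vs-closed-form or
simulation-vs-published-curve checks on idealized geometry: flat or
spherical interfaces, homogeneous isotropic bodies, homogeneous `phi0`,
perfectly smooth surfaces, quasi-static loading.  Passing them shows the
contact law, its FE coupling and the staging machinery are implemented
correctly — not that the model predicts any particular *in vivo* outcome:
surface roughness, heterogeneous bone, cortical shells, dynamic stick-slip
oscillations (visible post-peak in tension-held runs as small force
oscillations) and bone remodeling are all outside the model.

## Numerical choices and degenerate inputs

- Problem sizes: acceptance runs use 90 slide steps (mode II), 60-70
  rotation steps (mode III), 160 for the tension slide; peaks occur well
  inside these windows since the sliding limit is non-increasing once the
  interface slips.
- `phi0 = 0` with EMC: the smooth-penalty rule `eps_n = phi0 e t0 / g0`
  degenerates; the scenario-level penalty `E_b / L0` is used as the floor in
  all runs (the rule is available as an optional override through the config).
- Zero-length trial tractions return mapping to zero traction (free sliding
  at zero limit).
- A force-held target beyond the adhesive capacity of the interface is
  detected before the solve and terminates the stage as contact loss.
- `mu_ub >= mu_b` is enforced; `g0 <= g_b`, `0 <= phi0 <= 1` validated on
  construction.
- Outputs are bit-deterministic for identical configs; nothing in the
  simulation path draws random numbers.

## Known limitations

- The contact tangent is inexact (curvature terms dropped): robustly
  convergent with step bisection, but step sizes much larger than the
  defaults can stall on strongly curved masters.
- Coarse cup meshes under-resolve the rim pressure concentration; insertion
  forces and d0 carry O(10 %) mesh sensitivity (the convergence utility
  quantifies this per configuration).
- Mode II (lateral) cup removal with 1000 steps at full resolution is
  expensive; the default test path uses reduced steps.
- The quasi-static assumption breaks down in the post-peak stick-slip
  regime of strongly adhesive cases; oscillations there are reported as
  computed, not smoothed.
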