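# osseodebond

Finite-element simulation of **bone-implant interface debonding** with
coupled adhesion and friction, for researchers in implant biomechanics who
want to predict the long-term (secondary) stability of cementless implants
from interface parameters.

Cementless implants hold initially by press-fit friction (primary
stability) and, after healing, by osseointegration — direct structural
bonding of bone to the implant surface.  This package implements a
state-variable contact law for the debonding of such interfaces inside a
finite-strain, quasi-static FE solver:

- **MC (modified Coulomb)** — the friction coefficient degrades from an
  unbroken value to a broken one, `mu(phi) = phi mu_ub + (1 - phi) mu_b`,
  driven by a bonding state `phi = phi0 * w(g_d)` where `g_d` is the
  accumulated irreversible interface deformation and `w` a smooth window
  with threshold `a_s` and transition width `b_s`;
- **EMC (extended MC)** — adds an exponential cohesive zone in the normal
  direction, `t_n = phi0 t0 (g_n/g0) exp(1 - g_n/g0)` up to a cutoff gap
  `g_b`, and an adhesion-shifted sliding limit
  `t_t_slide = mu(phi) (phi0 t0 - t_n)` so the interface can slide (and
  hold) under tension;
- **Coulomb** — the classical limit, recovered exactly for `phi0 = 0`.

Two ready-made scenarios reproduce standard removal tests: a **coin-shaped
implant** (CSI: cylinder on a bone block; sliding, torsion and oblique
pull-off under constant normal force) and an **acetabular cup implant**
(ACI: hemispherical cup press-fit into a reamed cavity; insertion to a
target force, osseointegration, then pull-out / lateral / torsional
removal).

## Worked example

Peak resistance of a fully osseointegrated coin implant sliding under a
constant 70 N compression, with and without normal adhesion:

```python
from osseodebond import CsiConfig, build_csi, run_csi_test

for law in ("mc", "emc"):
    hist = run_csi_test(build_csi(CsiConfig(law=law)), "IIa")
    removal = hist.to_frame().query("stage == 'removal'")
    print(law, f"peak F_x = {removal.F_x.max():.1f} N,",
          f"sliding tail = {removal.F_x.iloc[-1]:.1f} N")
```

```
mc peak F_x = 30.8 N, sliding tail = 21.0 N
emc peak F_x = 45.8 N, sliding tail = 31.1 N
```

The MC peak is the unbroken-friction limit `mu_ub * 70 N ~ 31 N`, decaying
to the broken Coulomb tail `mu_b * 70 N = 21 N` as the accumulated slip
destroys the bond; the cohesive extension adds `mu * phi0 t0 * A ~ 15 N` of
adhesive friction over the coin face.  The same scenarios expose torsion
(`"IIIa"/"IIIb"`, reporting the torque `M_z`) and tension-held tests
(`"IIb"`), which end in the characteristic abrupt pop-off when the
remaining cohesive capacity falls below the held force.

A command-line interface mirrors the library:

```
osseodebond run --config examples/csi_mode2a.yaml --out results/
osseodebond calibrate-t0 --force "9 N" --phi0 0.26 --radius "2.5 mm"
osseodebond law-curves --out curves.csv
osseodebond plot --history results/csi_IIa_mc.csv
```

Configs are YAML with explicit units (`IF: 1 mm`, `E_b: 0.2 GPa`); see
`examples/`.

## Layout

```
src/osseodebond/
  contact_law.py   # point-wise law: state function, damage, CZM, friction
  materials.py     # Neo-Hookean stress and consistent tangent
  elements.py      # hex8 total-Lagrangian element
  mesh.py          # structured block / disk / spherical O-grid generators
  contact_fe.py    # slave-master projection, contact assembly, history
  solver.py        # reduced-system Newton with force-held groups
  scenarios.py     # CSI and ACI builders, staged protocols, sweeps
  response.py      # per-step reaction history, peaks, CSV/JSON output
  io.py, cli.py    # config schema with units, VTK/CSV writers, CLI
docs/methods.md    # model assumptions, numerics, limitations
```
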