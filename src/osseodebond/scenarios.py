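"""Ready-made boundary-value problems: coin-shaped and acetabular cup implants.

The coin-shaped implant (CSI) is a titanium cylinder (R = 2.5 mm, H = 3 mm)
resting centrally on a trabecular-bone block (12.5 x 12.5 x 5 mm); removal
tests slide (mode II), twist (mode III) or obliquely pull (mode I+II) the
implant top under a constant normal preload (-70 N compression, +20 N
tension, or none).

The acetabular cup implant (ACI) is a hemispherical shell (R = 25.5 mm)
press-fit into a reamed hemispherical cavity of a trabecular bone cylinder
(R = 50 mm, H = 40 mm); a stiff ancillary shaft tied to the cup pole drives
insertion to a target force F0, then removal in normal pull-out (mode I),
lateral pull-out (mode II) or torsion (mode III).

Staging is common to both: a press/insertion stage (displacement-driven with
stop-on-force and a secant landing on the exact target), an osseointegration
stage that bonds the currently contacting interface at a homogeneous phi0
with damage reset, and a removal stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .contact_law import AdhesiveFrictionParams, ContactLaw
from .contact_fe import ContactPair
from .materials import ElasticParams
from .mesh import (HexMesh, block_mesh, cavity_block_mesh, cylinder_mesh,
                   hemisphere_shell_mesh)
from .response import ResponseHistory
from .solver import Coupling, FEModel, NonConvergence, SolverSettings, StepBC

__all__ = [
    "CsiConfig", "AciConfig", "StagedModel",
    "build_csi", "build_aci", "run_csi_test", "run_aci_removal",
    "sweep", "csi_convergence_study",
]


# ----------------------------------------------------------------------
# configurations
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class CsiConfig:
    """Coin-shaped implant scenario (geometry, materials, law, protocol)."""

    R_i: float = 2.5e-3
    H_i: float = 3.0e-3
    bone_side: float = 12.5e-3
    bone_height: float = 5.0e-3
    E_i: float = 113e9
    nu_i: float = 0.3
    E_b: float = 18e9
    nu_b: float = 0.3
    a_s: float = 22e-6
    b_s: float = 0.74
    mu_ub: float = 0.44
    mu_b: float = 0.3
    t0: float = 1.8e6
    g0: float = 66e-6          # 3 a_s
    g_b: float = 66e-6
    L0: float = 0.01           # penalty length scale: eps = E_b / L0
    law: str = "mc"
    phi0: float = 1.0
    preload: float = -70.0     # N (compression negative); +20 for tension tests
    du: float = 0.65e-6        # m per removal step
    dtheta_deg: float = 0.1
    alpha_deg: float = 45.0
    n_implant_plan: int = 3
    n_implant_z: int = 2
    n_bone_plan: int = 15
    n_bone_z: int = 2
    refine: int = 1
    n_removal_steps: int | None = None
    tol_rel: float = 1e-6

    @property
    def eps(self) -> float:
        return self.E_b / self.L0

    def law_params(self) -> AdhesiveFrictionParams:
        return AdhesiveFrictionParams(
            a_s=self.a_s, b_s=self.b_s, mu_ub=self.mu_ub, mu_b=self.mu_b,
            t0=self.t0, g0=self.g0, g_b=self.g_b,
            eps_n=self.eps, eps_t=self.eps, law=ContactLaw(self.law))


@dataclass(frozen=True)
class AciConfig:
    """Acetabular cup implant scenario.

    The reference parameter set is ``E_b = 0.2 GPa, IF = 1 mm, mu_b = 0.3``;
    ``mu_ub`` defaults to ``1.5 * mu_b``.  The cavity radius follows
    ``R_b = R_i - IF/2``.
    """

    R_i: float = 25.5e-3
    IF: float = 1.0e-3
    R_cyl: float = 50e-3
    H: float = 40e-3
    cup_thickness: float = 3.0e-3
    fillet: float = 2.0e-3
    E_i: float = 113e9
    nu_i: float = 0.3
    E_a: float = 211e9
    nu_a: float = 0.3
    E_b: float = 0.2e9
    nu_b: float = 0.3
    a_s: float = 128e-6
    b_s: float = 1.84
    mu_b: float = 0.3
    mu_ub: float | None = None
    t0: float = 1.8e6
    g0: float = 384e-6         # 3 a_s
    g_b: float = 384e-6
    L0: float = 0.0255
    law: str = "mc"
    phi0: float = 1.0
    F0: float = -2500.0
    n: int = 4                 # cubed-hemisphere resolution
    bone_layers: int = 4
    cup_layers: int = 1
    shaft_layers: int = 2
    shaft_top: float = 15e-3
    clearance: float = 5e-5
    n_insert: int = 100
    n_removal: int = 100
    n_removal_mode2: int = 1000
    theta3_deg: float = 10.0
    tol_rel: float = 1e-6

    @property
    def mu_ub_eff(self) -> float:
        return 1.5 * self.mu_b if self.mu_ub is None else self.mu_ub

    @property
    def R_b(self) -> float:
        return self.R_i - self.IF / 2.0

    @property
    def eps(self) -> float:
        return self.E_b / self.L0

    def law_params(self) -> AdhesiveFrictionParams:
        mu_ub = max(self.mu_ub_eff, self.mu_b)
        return AdhesiveFrictionParams(
            a_s=self.a_s, b_s=self.b_s, mu_ub=mu_ub, mu_b=self.mu_b,
            t0=self.t0, g0=self.g0, g_b=self.g_b,
            eps_n=self.eps, eps_t=self.eps, law=ContactLaw(self.law))


# ----------------------------------------------------------------------
# staged model and generic drivers
# ----------------------------------------------------------------------
@dataclass
class StagedModel:
    """An FE model plus the bookkeeping of a staged removal protocol."""

    fem: FEModel
    pair: ContactPair
    driven: np.ndarray
    fixed: np.ndarray
    center: np.ndarray
    config: object = None
    ctrl: dict = field(default_factory=lambda: {"u_x": 0.0, "u_y": 0.0,
                                                "u_z": 0.0, "theta": 0.0})

    def _dofs(self, nodes: np.ndarray, axis: int) -> np.ndarray:
        return 3 * nodes + axis

    def _build_bc(self, axes: str, hold_z: float | None,
                  driven: np.ndarray | None = None) -> StepBC:
        """Dirichlet targets from the accumulated control values."""
        driven = self.driven if driven is None else driven
        ref = self.fem.mesh.nodes[driven]
        th = np.deg2rad(self.ctrl["theta"])
        c, s = np.cos(th), np.sin(th)
        dx = ref[:, 0] - self.center[0]
        dy = ref[:, 1] - self.center[1]
        x_t = self.center[0] + c * dx - s * dy + self.ctrl["u_x"]
        y_t = self.center[1] + s * dx + c * dy + self.ctrl["u_y"]
        z_t = ref[:, 2] + self.ctrl["u_z"]
        dofs, vals = [], []
        fixed_dofs = (3 * self.fixed[:, None] + np.arange(3)[None, :]).ravel()
        dofs.append(fixed_dofs)
        vals.append(np.zeros(fixed_dofs.size))
        if "x" in axes:
            dofs.append(self._dofs(driven, 0)); vals.append(x_t - ref[:, 0])
        if "y" in axes:
            dofs.append(self._dofs(driven, 1)); vals.append(y_t - ref[:, 1])
        couplings = []
        if hold_z is not None:
            couplings.append(Coupling(self._dofs(driven, 2), float(hold_z)))
        elif "z" in axes:
            dofs.append(self._dofs(driven, 2)); vals.append(z_t - ref[:, 2])
        return StepBC(np.concatenate(dofs), np.concatenate(vals), couplings)

    def _record(self, hist: ResponseHistory, stage: str, step: int,
                driven: np.ndarray | None = None, hold_z: float | None = None):
        driven = self.driven if driven is None else driven
        F = self.fem.reaction_force(driven)
        M_z = self.fem.reaction_moment_z(driven, self.center)
        hist.append(step=step, stage=stage,
                    u_x=self.ctrl["u_x"], u_z=self.ctrl["u_z"],
                    theta_deg=self.ctrl["theta"],
                    F_x=F[0], F_y=F[1], F_z=F[2], M_z=M_z,
                    phi_bar=self.pair.mean_bonding())

    # ------------------------------------------------------------------
    def press_to_force(self, target: float, du: float, max_steps: int,
                       hist: ResponseHistory, stage: str = "press",
                       force_tol: float | None = None) -> float:
        """Displacement-driven press with stop-on-threshold and secant landing.

        Ramps the driven set downward in steps of ``du`` while monitoring the
        vertical reaction; once the target is crossed, a secant iteration on
        the prescribed displacement lands on the target force.  Returns the
        attained downward displacement ``d0`` (positive).
        """
        if force_tol is None:
            force_tol = max(2e-4 * abs(target), 1e-3)
        prev_u, prev_F = self.ctrl["u_z"], 0.0
        reached = False
        for i in range(max_steps):
            self.ctrl["u_z"] -= du
            bc = self._build_bc("xyz", None)
            self.fem.solve_step(bc)
            F_z = self.fem.reaction_force(self.driven)[2]
            self._record(hist, stage, i)
            if F_z <= target:
                reached = True
                break
            prev_u, prev_F = self.ctrl["u_z"], F_z
        if not reached:
            raise NonConvergence(
                f"press target {target} N not reached within ramp bound")
        # secant landing on the exact target force
        u1, F1 = self.ctrl["u_z"], F_z
        u0, F0 = prev_u, prev_F
        for _ in range(10):
            if abs(F1 - target) <= force_tol:
                break
            if abs(F1 - F0) < 1e-30:
                break
            u_new = u1 + (target - F1) * (u1 - u0) / (F1 - F0)
            u0, F0 = u1, F1
            self.ctrl["u_z"] = u_new
            self.fem.solve_step(self._build_bc("xyz", None))
            u1, F1 = u_new, self.fem.reaction_force(self.driven)[2]
        self._record(hist, stage, max_steps)
        return -self.ctrl["u_z"]

    def pull_to_force(self, target: float, n_steps: int, hist: ResponseHistory,
                      stage: str = "pull") -> None:
        """Force-controlled vertical ramp (e.g. -70 N -> +20 N tension)."""
        F_now = self.fem.reaction_force(self.driven)[2]
        forces = np.linspace(F_now, target, n_steps + 1)[1:]
        for i, F in enumerate(forces):
            bc = self._build_bc("xy", float(F))
            self.fem.solve_step(bc)
            self.ctrl["u_z"] = float(
                np.mean(self.fem.u[self.driven, 2]))
            self._record(hist, stage, i, hold_z=F)

    def set_osseointegration(self, phi0: float) -> None:
        coords = self.fem.mesh.nodes + self.fem.u
        self.pair.set_osseointegration(phi0, coords)

    def removal(self, hist: ResponseHistory, *, n_steps: int,
                du: tuple[float, float, float] = (0.0, 0.0, 0.0),
                dtheta_deg: float = 0.0, hold_z: float | None = None,
                axes: str | None = None, driven: np.ndarray | None = None,
                stage: str = "removal") -> None:
        """Generic removal ramp: translation and/or rotation of the driven set.

        With ``hold_z`` the vertical resultant on the driven set is kept at a
        constant force while the in-plane motion is prescribed.  A
        tension-held stage terminates cleanly (zero-force tail row) once the
        interface can no longer carry the held force.
        """
        driven_set = self.driven if driven is None else driven
        if axes is None:
            axes = "xy" if hold_z is not None else "xyz"
        for i in range(n_steps):
            self.ctrl["u_x"] += du[0]
            self.ctrl["u_y"] += du[1]
            self.ctrl["u_z"] += du[2]
            self.ctrl["theta"] += dtheta_deg
            if hold_z is not None and hold_z > 0.0:
                cap = self.pair.adhesive_capacity()
                if cap <= 1.05 * hold_z:
                    hist.termination = "contact_lost"
                    hist.append(step=i, stage=stage, u_x=self.ctrl["u_x"],
                                u_z=self.ctrl["u_z"], theta_deg=self.ctrl["theta"],
                                phi_bar=self.pair.mean_bonding())
                    return
            bc = self._build_bc(axes, hold_z, driven=driven_set)
            try:
                self.fem.solve_step(bc)
            except NonConvergence:
                if hold_z is not None and hold_z > 0.0:
                    hist.termination = "contact_lost"
                    hist.append(step=i, stage=stage, u_x=self.ctrl["u_x"],
                                u_z=self.ctrl["u_z"], theta_deg=self.ctrl["theta"],
                                phi_bar=self.pair.mean_bonding())
                    return
                raise
            if hold_z is not None:
                self.ctrl["u_z"] = float(np.mean(self.fem.u[driven_set, 2]))
            self._record(hist, stage, i, driven=driven_set, hold_z=hold_z)


# ----------------------------------------------------------------------
# coin-shaped implant
# ----------------------------------------------------------------------
def build_csi(config: CsiConfig) -> StagedModel:
    """Assemble the CSI model: bone block, implant cylinder, contact pair."""
    r = config.refine
    bone = block_mesh(config.bone_side, config.bone_side, config.bone_height,
                      config.n_bone_plan * r, config.n_bone_plan * r,
                      config.n_bone_z * r,
                      origin=(-config.bone_side / 2, -config.bone_side / 2, 0.0),
                      body="bone")
    implant = cylinder_mesh(config.R_i, config.H_i,
                            config.n_implant_plan * r, config.n_implant_z * r,
                            body="implant")
    bone.surfaces = {"bone_top": bone.surfaces["top"],
                     "bone_bottom": bone.surfaces["bottom"]}
    bone.node_sets = {"bone_bottom": bone.node_sets["bottom"]}
    implant.surfaces = {"implant_bottom": implant.surfaces["bottom"],
                        "implant_top": implant.surfaces["top"]}
    implant.node_sets = {"implant_top": implant.node_sets["top"]}
    mesh = bone.merge(implant)
    pair = ContactPair(mesh, "bone_top", "implant_bottom", config.law_params())
    fem = FEModel(mesh,
                  {"bone": ElasticParams(config.E_b, config.nu_b),
                   "implant": ElasticParams(config.E_i, config.nu_i)},
                  [pair], SolverSettings(tol_rel=config.tol_rel))
    return StagedModel(fem=fem, pair=pair,
                       driven=mesh.node_sets["implant_top"],
                       fixed=mesh.node_sets["bone_bottom"],
                       center=np.zeros(3), config=config)


_CSI_DEFAULT_STEPS = {"IIa": 170, "IIb": 160, "IIIa": 60, "IIIb": 70,
                      "I+IIc": 260, "I+IId": 220}


def run_csi_test(model: StagedModel, test: str) -> ResponseHistory:
    """Execute one CSI debonding protocol and return its response curves.

    Tests: ``IIa``/``IIb`` tangential sliding under constant -70 N
    compression / +20 N tension; ``IIIa``/``IIIb`` torsion under the same
    holds; ``I+IIc``/``I+IId`` oblique pull at ``alpha_deg`` with / without
    the initial -70 N press.
    """
    cfg: CsiConfig = model.config
    if test not in _CSI_DEFAULT_STEPS:
        raise ValueError(f"unknown CSI test {test!r}")
    hist = ResponseHistory()
    n_rem = cfg.n_removal_steps or _CSI_DEFAULT_STEPS[test]
    with_press = test != "I+IId"
    tension = test in ("IIb", "IIIb")
    if with_press:
        model.press_to_force(-70.0, cfg.du * 2, 60, hist)
    model.set_osseointegration(cfg.phi0)
    if tension:
        if ContactLaw(cfg.law) is not ContactLaw.EMC:
            raise ValueError("tension-held tests require the EMC law")
        model.pull_to_force(20.0, 18, hist)
        hold = 20.0
    else:
        hold = -70.0 if with_press else None
    if test in ("IIa", "IIb"):
        model.removal(hist, n_steps=n_rem, du=(cfg.du, 0.0, 0.0), hold_z=hold)
    elif test in ("IIIa", "IIIb"):
        model.removal(hist, n_steps=n_rem, dtheta_deg=cfg.dtheta_deg,
                      hold_z=hold)
    else:  # oblique mode I+II
        a = np.deg2rad(cfg.alpha_deg)
        model.removal(hist, n_steps=n_rem,
                      du=(cfg.du * np.cos(a), 0.0, cfg.du * np.sin(a)),
                      hold_z=None)
    return hist


# ----------------------------------------------------------------------
# acetabular cup implant
# ----------------------------------------------------------------------
def _cup_with_ancillary(config: AciConfig) -> HexMesh:
    """Hemispherical cup shell with an ancillary shaft tied to its pole."""
    shell = hemisphere_shell_mesh(config.R_i, config.cup_thickness, config.n,
                                  config.cup_layers, body="implant")
    pole_quads = shell.node_sets.pop("pole_patch_quads")
    inner_quads = shell.surfaces["inner"][pole_quads]
    cap_nodes = np.unique(inner_quads)
    nn0 = shell.n_nodes
    remap = -np.ones(nn0, dtype=np.int64)
    remap[cap_nodes] = np.arange(cap_nodes.size)
    cap_xy = shell.nodes[cap_nodes, :2]
    cap_z = shell.nodes[cap_nodes, 2]
    L = config.shaft_layers
    new_nodes = []
    for ell in range(1, L + 1):
        z = cap_z + (ell / L) * (config.shaft_top - cap_z)
        new_nodes.append(np.column_stack([cap_xy, z]))
    nodes = np.vstack([shell.nodes] + new_nodes)

    hexes = []
    for ell in range(L):
        for q in inner_quads:
            loc = remap[q]
            base = [cap_nodes[l] for l in loc] if ell == 0 else \
                   [nn0 + (ell - 1) * cap_nodes.size + l for l in loc]
            top = [nn0 + ell * cap_nodes.size + l for l in loc]
            hexes.append(base + top)
    hexes = np.vstack([shell.hexes, np.array(hexes, dtype=np.int64)])
    body = np.concatenate([shell.body,
                           np.array(["ancillary"] * (L * inner_quads.shape[0]))])
    top_nodes = nn0 + (L - 1) * cap_nodes.size + np.arange(cap_nodes.size)
    center_node = top_nodes[np.argmin(np.hypot(cap_xy[:, 0], cap_xy[:, 1]))]
    node_sets = {"ancillary_top": top_nodes,
                 "ancillary_center": np.array([center_node])}
    surfaces = {"cup_outer": shell.surfaces["outer"]}
    return HexMesh(nodes, hexes, body, surfaces, node_sets)


def build_aci(config: AciConfig) -> StagedModel:
    """Assemble the ACI model in its pre-insertion configuration.

    The cup starts lifted so that its widest section just clears the cavity
    rim; the interference ``IF`` is realized geometrically (``R_b = R_i -
    IF/2``) and resolved during the insertion stage.  The rim fillet is
    represented at coarse resolution by a small radial relief of the cavity
    rim ring.
    """
    if config.R_b >= config.R_cyl:
        raise ValueError("cavity radius exceeds the bone cylinder")
    rim_relief = 0.15 * config.fillet
    bone = cavity_block_mesh(config.R_b, config.R_cyl, config.H, config.n,
                             n_layers=config.bone_layers, rim_relief=rim_relief,
                             body="bone")
    bone.surfaces = {"cavity": bone.surfaces["cavity"]}
    bone.node_sets = {"bone_bottom": bone.node_sets["bottom"]}
    cup = _cup_with_ancillary(config)
    lift = np.sqrt(max(config.R_i**2 - config.R_b**2, 0.0)) + config.clearance
    cup = cup.translated((0.0, 0.0, lift))
    mesh = bone.merge(cup)
    pair = ContactPair(mesh, "cavity", "cup_outer", config.law_params())
    fem = FEModel(mesh,
                  {"bone": ElasticParams(config.E_b, config.nu_b),
                   "implant": ElasticParams(config.E_i, config.nu_i),
                   "ancillary": ElasticParams(config.E_a, config.nu_a)},
                  [pair], SolverSettings(tol_rel=config.tol_rel))
    return StagedModel(fem=fem, pair=pair,
                       driven=mesh.node_sets["ancillary_top"],
                       fixed=mesh.node_sets["bone_bottom"],
                       center=np.zeros(3), config=config)


def run_aci_removal(model: StagedModel, mode: str,
                    phi0: float | None = None) -> ResponseHistory:
    """Insertion to F0, homogeneous osseointegration, then one removal test.

    ``mode`` is ``"I"`` (normal pull-out by the insertion displacement d0),
    ``"II"`` (lateral displacement of the ancillary-top center node by d0) or
    ``"III"`` (torsion about the implant axis).
    """
    cfg: AciConfig = model.config
    if mode not in ("I", "II", "III"):
        raise ValueError(f"unknown ACI removal mode {mode!r}")
    phi0 = cfg.phi0 if phi0 is None else phi0
    hist = ResponseHistory()
    seat_travel = np.sqrt(max(cfg.R_i**2 - cfg.R_b**2, 0.0)) - (cfg.R_i - cfg.R_b)
    ramp = cfg.clearance + seat_travel + 1.5e-3
    du_ins = ramp / cfg.n_insert
    d0 = model.press_to_force(cfg.F0, du_ins, int(2.5 * cfg.n_insert), hist,
                              stage="insertion",
                              force_tol=max(2e-4 * abs(cfg.F0), 0.5))
    hist.d0 = d0
    model.set_osseointegration(phi0)
    if mode == "I":
        n = cfg.n_removal
        model.removal(hist, n_steps=n, du=(0.0, 0.0, d0 / n),
                      stage="removal_modeI")
    elif mode == "II":
        n = cfg.n_removal_mode2
        center = model.fem.mesh.node_sets["ancillary_center"]
        model.removal(hist, n_steps=n, du=(d0 / n, 0.0, 0.0), axes="x",
                      driven=center, stage="removal_modeII")
    else:
        n = cfg.n_removal
        model.removal(hist, n_steps=n, dtheta_deg=cfg.theta3_deg / n,
                      axes="xyz", stage="removal_modeIII")
    return hist


# ----------------------------------------------------------------------
# parameter sweeps and convergence
# ----------------------------------------------------------------------
def _config_key(config, phi0, mode) -> str:
    payload = json.dumps({"cfg": asdict(config), "phi0": phi0, "mode": mode},
                         sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def sweep(configs, phi0_grid, mode: str = "I", cache_dir=None) -> pd.DataFrame:
    """Peak-metric table over configurations x initial osseointegration.

    Each row carries the removal peaks for one ``(config, phi0)`` pair plus
    the stability ratio column ``ratio_phi1_phi0`` (peak at phi0 = 1 over
    peak at phi0 = 0) filled per config once both ends of the grid are
    present.  Individual run failures are recorded and the sweep continues.
    Results are cached as JSON per configuration when ``cache_dir`` is set.
    """
    records = []
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    for ci, cfg in enumerate(configs):
        for phi0 in phi0_grid:
            key = _config_key(cfg, phi0, mode)
            rec = None
            if cache and (cache / f"{key}.json").exists():
                rec = json.loads((cache / f"{key}.json").read_text())
            if rec is None:
                rec = {"config": ci, "phi0": phi0, "mode": mode,
                       "mu_b": cfg.mu_b, "IF": getattr(cfg, "IF", np.nan),
                       "E_b": cfg.E_b, "law": str(cfg.law)}
                try:
                    if isinstance(cfg, AciConfig):
                        hist = run_aci_removal(build_aci(cfg), mode, phi0)
                    else:
                        hist = run_csi_test(
                            build_csi(replace(cfg, phi0=phi0)), mode)
                    rec.update(hist.peaks())
                    rec["status"] = "ok"
                except Exception as exc:
                    rec["status"] = f"failed: {exc}"
                if cache:
                    (cache / f"{key}.json").write_text(json.dumps(rec))
            records.append(rec)
    df = pd.DataFrame(records)
    for metric in ("F_x_max", "F_z_max", "M_z_max"):
        if metric not in df:
            continue
        ratios = []
        for _, row in df.iterrows():
            sub = df[df.config == row.config]
            lo = sub[sub.phi0 == 0.0]
            hi = sub[sub.phi0 == 1.0]
            if len(lo) and len(hi) and abs(float(lo[metric].iloc[0])) > 1e-12:
                ratios.append(float(hi[metric].iloc[0]) / float(lo[metric].iloc[0]))
            else:
                ratios.append(np.nan)
        df[f"ratio_{metric}"] = ratios
    return df


def csi_convergence_study(config: CsiConfig, test: str = "IIa",
                          refines=(1, 2)) -> pd.DataFrame:
    """Peak forces of one CSI test across structured mesh refinements."""
    rows = []
    for r in refines:
        cfg = replace(config, refine=r)
        hist = run_csi_test(build_csi(cfg), test)
        pk = hist.peaks()
        pk["refine"] = r
        pk["n_elements"] = build_csi(cfg).fem.mesh.n_elements
        rows.append(pk)
    return pd.DataFrame(rows)
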