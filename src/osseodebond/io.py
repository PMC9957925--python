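"""Configuration loading, unit normalization, and file output.

Configs are YAML mappings; every physical quantity may be given either as a
plain number (SI) or as a string with an explicit unit suffix ("1 mm",
"0.2 GPa", "0.1 deg").  Internally everything is SI (m, Pa, N, rad); angles
in configs and outputs are degrees.  Unknown keys are rejected with a message
naming the key.
"""

from __future__ import annotations

import re
from dataclasses import fields
from pathlib import Path

import numpy as np
import yaml

from .scenarios import AciConfig, CsiConfig

__all__ = ["parse_quantity", "load_config", "write_vtk", "write_point_states"]

_UNITS = {
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "cm": 1e-2,
    "Pa": 1.0, "kPa": 1e3, "MPa": 1e6, "GPa": 1e9,
    "N": 1.0, "kN": 1e3, "Nm": 1.0,
    "deg": 1.0, "rad": np.rad2deg(1.0),  # angles normalized to degrees
}

_QUANT_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([a-zA-Zµ]+)?\s*$")


def parse_quantity(value) -> float:
    """Parse a number or a '<value> <unit>' string into SI (angles: deg)."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _QUANT_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse quantity {value!r}")
    num, unit = m.groups()
    if unit is None:
        return float(num)
    if unit not in _UNITS:
        raise ValueError(f"unknown unit {unit!r} in {value!r}")
    return float(num) * _UNITS[unit]


_SCENARIOS = {"csi": CsiConfig, "aci": AciConfig, "point_lab": None}

# config keys that are not physical quantities
_PASSTHROUGH = {"law", "refine", "n_implant_plan", "n_implant_z", "n_bone_plan",
                "n_bone_z", "n_removal_steps", "n", "bone_layers", "cup_layers",
                "shaft_layers", "n_insert", "n_removal", "n_removal_mode2",
                "mu_ub", "mu_b", "phi0", "nu_i", "nu_b", "nu_a", "b_s",
                "tol_rel"}


def load_config(path):
    """Load and validate a scenario config file.

    Returns ``(kind, config, extras)`` where ``config`` is a
    :class:`CsiConfig`/:class:`AciConfig` (or a plain dict of law parameters
    for the ``point_lab`` kind) and ``extras`` holds run options (``test``,
    ``mode``, ``output``...).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "scenario" not in raw:
        raise ValueError("config must be a mapping with a 'scenario' key")
    kind = raw.pop("scenario")
    if kind not in _SCENARIOS:
        raise ValueError(f"unknown scenario kind {kind!r}")
    extras = {k: raw.pop(k) for k in list(raw)
              if k in ("test", "mode", "output", "output_every", "seed")}
    if kind == "point_lab":
        return kind, {k: parse_quantity(v) for k, v in raw.items()}, extras
    cls = _SCENARIOS[kind]
    valid = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in raw.items():
        if key not in valid:
            raise ValueError(f"unknown config key {key!r} for scenario {kind!r}")
        if key in _PASSTHROUGH or value is None:
            kwargs[key] = value
        else:
            kwargs[key] = parse_quantity(value)
    cfg = cls(**kwargs)
    _validate(cfg)
    return kind, cfg, extras


def _validate(cfg) -> None:
    if cfg.a_s <= 0:
        raise ValueError("config key 'a_s' must be positive")
    cfg.law_params()  # full invariant check of the law parameters
    if isinstance(cfg, CsiConfig):
        if not (0.0 < cfg.alpha_deg < 90.0):
            raise ValueError("config key 'alpha_deg' must lie in (0, 90)")
    if isinstance(cfg, AciConfig) and not (0.0 <= cfg.IF <= 5e-3):
        raise ValueError("config key 'IF' out of range")


# ----------------------------------------------------------------------
def write_vtk(path, mesh, point_data: dict | None = None,
              displacement=None) -> None:
    """Write the mesh (optionally deformed) as legacy ASCII VTK."""
    nodes = mesh.nodes if displacement is None else mesh.nodes + displacement
    lines = ["# vtk DataFile Version 3.0", "osseodebond", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_nodes} double"]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in nodes]
    ne = mesh.n_elements
    lines.append(f"CELLS {ne} {9 * ne}")
    lines += ["8 " + " ".join(str(i) for i in h) for h in mesh.hexes]
    lines.append(f"CELL_TYPES {ne}")
    lines += ["12"] * ne
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.9g}" for v in arr]
            else:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{v:.9g}" for v in p) for p in arr]
    Path(path).write_text("\n".join(lines) + "\n")


def write_point_states(path, pair) -> None:
    """Dump the per-quadrature-point contact state (phi, damage, status)."""
    pair.state_table().to_csv(path, index=False, float_format="%.10g")
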