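"""Load-step response records of a removal simulation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ResponseHistory"]

COLUMNS = ["step", "stage", "u_x", "u_z", "theta_deg",
           "F_x", "F_y", "F_z", "M_z", "phi_bar"]


@dataclass
class ResponseHistory:
    """Per-step control values and reaction outputs of a staged simulation.

    Reactions are those on the driven node set: ``F_x``/``F_z`` in N, the
    torque ``M_z`` about the drive axis in Nm, and the area-averaged bonding
    state ``phi_bar`` of the interface.  ``d0`` records the insertion
    displacement attained when the insertion force target was reached.
    """

    rows: list = field(default_factory=list)
    d0: float = 0.0
    termination: str = "completed"

    def append(self, **kw) -> None:
        self.rows.append({c: kw.get(c, 0.0) for c in COLUMNS})

    def to_frame(self) -> pd.DataFrame:
        if not self.rows:
            raise ValueError("empty response history")
        return pd.DataFrame(self.rows, columns=COLUMNS)

    # ------------------------------------------------------------------
    def peaks(self) -> dict:
        df = self.to_frame()
        rem = df[df.stage.str.startswith("removal")] if (df.stage.str.startswith("removal")).any() else df
        return {
            "F_x_max": float(rem.F_x.max()),
            "F_z_max": float(rem.F_z.max()),
            "M_z_max": float(rem.M_z.max()),
            "d0": float(self.d0),
        }

    # ------------------------------------------------------------------
    def write_csv(self, path) -> None:
        """CSV (SI units) plus a JSON sidecar with the peak metrics."""
        df = self.to_frame()
        path = Path(path)
        df.to_csv(path, index=False, float_format="%.10g")
        sidecar = {"peaks": self.peaks(), "termination": self.termination}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read_csv(cls, path) -> "ResponseHistory":
        df = pd.read_csv(path)
        h = cls(rows=df.to_dict("records"))
        side = Path(path).with_suffix(".json")
        if side.exists():
            meta = json.loads(side.read_text())
            h.d0 = meta.get("peaks", {}).get("d0", 0.0)
            h.termination = meta.get("termination", "completed")
        return h
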