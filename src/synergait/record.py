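"""Simulation output container.

A :class:`GaitRecord` wraps the decimated time series of a forward simulation
(generalized coordinates and rates, muscle commands/activations/forces, ground
reaction forces, stance flags, oscillator phase) as a pandas DataFrame plus a
metadata dict (integration settings, touchdown/liftoff events, step count,
success flag).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motor_control import MUSCLES

COORDS = ("x", "y", "theta", "hip_r", "knee_r", "ankle_r", "hip_l", "knee_l", "ankle_l")
LEGS = ("r", "l")


def _muscle_cols(prefix: str) -> list[str]:
    return [f"{prefix}_{m.lower()}_{leg}" for leg in LEGS for m in MUSCLES]


@dataclass
class GaitRecord:
    """Time series of one simulation run plus run metadata."""

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_arrays(
        cls, t, q, qd, a, phi, u, u_syn, u_reg, forces, grf, stance, meta
    ) -> "GaitRecord":
        cols: dict[str, np.ndarray] = {"t": t}
        for k, name in enumerate(COORDS):
            cols[name] = q[:, k]
        for k, name in enumerate(COORDS):
            cols["d" + name] = qd[:, k]
        for k, name in enumerate(_muscle_cols("a")):
            cols[name] = a[:, k]
        for k, name in enumerate(_muscle_cols("u")):
            cols[name] = u[:, k]
        for k, name in enumerate(_muscle_cols("usyn")):
            cols[name] = u_syn[:, k]
        for k, name in enumerate(_muscle_cols("ureg")):
            cols[name] = u_reg[:, k]
        for k, name in enumerate(_muscle_cols("f")):
            cols[name] = forces[:, k]
        cols["grf_rx"] = grf[:, 0]
        cols["grf_ry"] = grf[:, 1]
        cols["grf_lx"] = grf[:, 2]
        cols["grf_ly"] = grf[:, 3]
        cols["stance_r"] = stance[:, 0]
        cols["stance_l"] = stance[:, 1]
        cols["phi"] = phi
        return cls(data=pd.DataFrame(cols), meta=meta)

    # -- convenience accessors --------------------------------------------
    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy()

    def q(self) -> np.ndarray:
        return self.data[list(COORDS)].to_numpy()

    def qd(self) -> np.ndarray:
        return self.data[["d" + c for c in COORDS]].to_numpy()

    def muscle(self, prefix: str) -> np.ndarray:
        """(n, 18) block for prefix in {'a', 'u', 'usyn', 'ureg', 'f'}."""
        return self.data[_muscle_cols(prefix)].to_numpy()

    def grf(self, leg: str) -> np.ndarray:
        """(n, 2) ground reaction force of one leg ('r' or 'l')."""
        return self.data[[f"grf_{leg}x", f"grf_{leg}y"]].to_numpy()

    @property
    def touchdowns(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.asarray(self.meta.get("td_time", [])),
            np.asarray(self.meta.get("td_leg", []), dtype=int),
        )

    @property
    def success(self) -> bool:
        return bool(self.meta.get("success", False))

    @property
    def step_count(self) -> int:
        return int(self.meta.get("steps", 0))

    # -- persistence -------------------------------------------------------
    def to_csv(self, path, meta_path=None) -> None:
        self.data.to_csv(path, index=False)
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump(_jsonable(self.meta), fh, indent=2)

    @classmethod
    def from_csv(cls, path, meta_path=None) -> "GaitRecord":
        data = pd.read_csv(path)
        meta = {}
        if meta_path is not None:
            with open(meta_path) as fh:
                meta = json.load(fh)
        return cls(data=data, meta=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
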