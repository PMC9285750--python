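"""Measurement sets: the clinical data a calibration assimilates.

A :class:`MeasurementSet` carries a target mean pressure p_d at a tagged
cross-section, the inlet mean flow Q_in, one mean flow Q_i per outlet, and
the dimensionless weights of the calibration functional.  Flows are stored
in cm^3/s and the pressure in dyn/cm^2 (mmHg only at I/O; see
:mod:`vasocal.units`).  The net flow Q_in - sum(Q_i) is allowed to be
nonzero: 4D-Flow MRI measurements routinely violate mass conservation by
up to ~15%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import meshing
from .units import MMHG_TO_DYN_CM2


@dataclass
class MeasurementSet:
    p_d: float                      # target mean pressure, dyn/cm^2
    Q_in: float                     # inlet mean flow, cm^3/s
    Q_out: np.ndarray               # per-outlet mean flows, cm^3/s
    pressure_section: int = meshing.INLET
    alpha_p: float = 1.0
    alpha_out: np.ndarray | float = 1.0
    alpha_in: float = 1.0

    def __post_init__(self):
        self.Q_out = np.atleast_1d(np.asarray(self.Q_out, dtype=float))
        if np.isscalar(self.alpha_out) or np.ndim(self.alpha_out) == 0:
            self.alpha_out = np.full(len(self.Q_out), float(self.alpha_out))
        else:
            self.alpha_out = np.asarray(self.alpha_out, dtype=float)
        if self.p_d <= 0:
            raise ValueError("p_d must be positive")
        if self.Q_in <= 0 or np.any(self.Q_out <= 0):
            raise ValueError("all flows must be positive")
        weights = np.concatenate([[self.alpha_p, self.alpha_in], self.alpha_out])
        if np.any(weights < 0) or not np.any(weights > 0):
            raise ValueError("weights must be nonnegative and not all zero")
        if len(self.alpha_out) != len(self.Q_out):
            raise ValueError("one alpha_i per outlet flow is required")

    @property
    def net_flow(self) -> float:
        """Q_in - sum(Q_i), cm^3/s (mass-conservation violation)."""
        return float(self.Q_in - self.Q_out.sum())

    @property
    def p_d_mmhg(self) -> float:
        return self.p_d / MMHG_TO_DYN_CM2

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["Q_out"] = self.Q_out.tolist()
        d["alpha_out"] = self.alpha_out.tolist()
        d["units"] = {"p_d": "dyn/cm2", "Q_in": "cm3/s", "Q_out": "cm3/s"}
        return d

    def save(self, path) -> None:
        path = Path(path)
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        path.write_text(text + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "MeasurementSet":
        d = dict(d)
        d.pop("units", None)
        return cls(**d)

    @classmethod
    def load(cls, path) -> "MeasurementSet":
        return cls.from_dict(json.loads(Path(path).read_text()))
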