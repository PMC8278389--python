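"""Dihedral-angle trajectory container.

A trajectory is an ``(n_frames, n_torsions)`` matrix of torsional angles in
radians, canonically wrapped to the half-open interval ``[-pi, pi)``, with
optional per-frame metadata: timestamps, the total external bias potential
deposited by an enhanced-sampling run, and potential-energy components split
into solute, solvent and solute-solvent terms (all kJ/mol).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import EmptyInputError

TWO_PI = 2.0 * np.pi


def wrap_angles(x):
    """Wrap angles (radians) onto the canonical interval ``[-pi, pi)``.

    Idempotent: ``wrap_angles(wrap_angles(x)) == wrap_angles(x)``. The value
    ``+pi`` maps to ``-pi`` so the interval stays half-open.
    """
    return np.mod(np.asarray(x, dtype=float) + np.pi, TWO_PI) - np.pi


def _as_optional_1d(values, n, name):
    if values is None:
        return None
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.shape[0] != n:
        raise ValueError(
            f"{name} must be a 1-D array with {n} entries, got shape {arr.shape}"
        )
    return arr


@dataclass
class DihedralTrajectory:
    """Frames x torsions angle matrix plus optional per-frame columns.

    Angles are wrapped to ``[-pi, pi)`` on construction, so the canonical
    interval holds no matter how the instance was produced.
    """

    angles: np.ndarray
    angle_names: Sequence[str]
    time: np.ndarray | None = None
    bias: np.ndarray | None = None
    energy_solute: np.ndarray | None = None
    energy_solvent: np.ndarray | None = None
    energy_solute_solvent: np.ndarray | None = None

    def __post_init__(self):
        ang = np.asarray(self.angles, dtype=float)
        if ang.ndim == 1:
            ang = ang[:, None]
        if ang.ndim != 2:
            raise ValueError(f"angles must be 2-D, got ndim={ang.ndim}")
        if ang.shape[0] == 0:
            raise EmptyInputError("trajectory has no frames")
        if ang.shape[1] < 1:
            raise ValueError("trajectory must carry at least one torsion")
        self.angles = wrap_angles(ang)
        self.angle_names = list(self.angle_names)
        if len(self.angle_names) != ang.shape[1]:
            raise ValueError(
                f"{len(self.angle_names)} angle names for {ang.shape[1]} torsions"
            )
        if len(set(self.angle_names)) != len(self.angle_names):
            raise ValueError("angle names must be unique")
        n = ang.shape[0]
        for attr in (
            "time",
            "bias",
            "energy_solute",
            "energy_solvent",
            "energy_solute_solvent",
        ):
            setattr(self, attr, _as_optional_1d(getattr(self, attr), n, attr))

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def n_cv(self) -> int:
        """Number of collective variables (torsions)."""
        return self.angles.shape[1]

    def angle(self, name: str) -> np.ndarray:
        """Time series of one named torsion."""
        try:
            idx = self.angle_names.index(name)
        except ValueError:
            raise KeyError(f"no torsion named {name!r}; have {self.angle_names}")
        return self.angles[:, idx]

    def with_columns(self, **kwargs) -> "DihedralTrajectory":
        """Return a copy with the given optional columns replaced."""
        return replace(self, **kwargs)

    def take(self, indices) -> "DihedralTrajectory":
        """Sub-trajectory restricted to the given frame indices."""
        idx = np.asarray(indices)
        cols = {}
        for attr in (
            "time",
            "bias",
            "energy_solute",
            "energy_solvent",
            "energy_solute_solvent",
        ):
            val = getattr(self, attr)
            cols[attr] = None if val is None else val[idx]
        return DihedralTrajectory(self.angles[idx], self.angle_names, **cols)
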