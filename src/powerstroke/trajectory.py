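"""Ordered coordinate frames over a fixed atom list."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .structure import Structure, write_trajectory_pdb

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Frames of coordinates for the atoms of ``template``.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom; ``times_ps``
    is strictly increasing.  ``records`` holds optional per-frame bias
    bookkeeping (bias energies, applied SMD forces, ...).
    """

    template: Structure
    coords: np.ndarray
    times_ps: np.ndarray
    records: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords shape {self.coords.shape} is not (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.template):
            raise ValueError("frame atom count does not match template")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.times_ps.shape != (self.coords.shape[0],):
            raise ValueError("times length does not match frame count")
        if np.any(np.diff(self.times_ps) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.records and len(self.records) != len(self):
            raise ValueError("records length does not match frame count")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def frame_structure(self, i: int) -> Structure:
        """Materialize frame ``i`` as a Structure (same atom identities)."""
        return self.template.with_coords(self.coords[i])

    def concat(self, other: "Trajectory") -> "Trajectory":
        """Concatenate two trajectories over the same atom list; the second
        trajectory's clock is shifted to continue after the first."""
        if len(other.template) != len(self.template):
            raise ValueError("cannot concatenate trajectories with different atoms")
        dt = self.times_ps[-1] - (self.times_ps[-2] if len(self) > 1 else -1.0)
        shift = self.times_ps[-1] + dt - other.times_ps[0]
        return Trajectory(
            template=self.template,
            coords=np.concatenate([self.coords, other.coords]),
            times_ps=np.concatenate([self.times_ps, other.times_ps + shift]),
            records=(self.records + other.records)
            if self.records and other.records
            else [],
        )

    def write_pdb(self, path) -> None:
        write_trajectory_pdb(self.template, list(self.coords), path)
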