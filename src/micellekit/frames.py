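"""Trajectory containers: a Frame of wrapped bead coordinates plus a
bead→molecule map, and a time-ordered Trajectory of such frames."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np

from .errors import InvalidInputError

if TYPE_CHECKING:  # avoid an import cycle with builder
    from .builder import BoxSpec, MCFATopology, SystemComposition


@dataclass
class Frame:
    """One snapshot: bead positions (nm) in a periodic orthorhombic box.

    ``molecule_of_bead[i]`` is the molecule index of bead ``i``; beads of a
    molecule are stored contiguously in chain order (head first), which is
    what lets bonds be reconstructed from the map alone.  All coordinates
    are wrapped into ``[0, box edge)``.
    """

    time: float  # ps
    box: "BoxSpec"
    positions: np.ndarray  # (n_beads, 3) nm
    molecule_of_bead: np.ndarray  # (n_beads,) int
    bead_types: np.ndarray  # (n_beads,) str labels

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.molecule_of_bead = np.asarray(self.molecule_of_bead, dtype=np.int64)
        self.bead_types = np.asarray(self.bead_types)
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise InvalidInputError("positions must have shape (n_beads, 3)")
        if len(self.molecule_of_bead) != n or len(self.bead_types) != n:
            raise InvalidInputError(
                "positions, molecule_of_bead and bead_types must have equal length"
            )
        self.positions = self.positions % self.box.lengths

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_of_bead.max()) + 1 if self.n_beads else 0

    def wrapped(self) -> "Frame":
        return Frame(
            time=self.time,
            box=self.box,
            positions=self.positions % self.box.lengths,
            molecule_of_bead=self.molecule_of_bead.copy(),
            bead_types=self.bead_types.copy(),
        )


@dataclass
class Trajectory:
    """Time-ordered frames with constant bead identity."""

    frames: list[Frame]
    topology: Optional["MCFATopology"] = None
    composition: Optional["SystemComposition"] = None
    #: run provenance and per-frame diagnostics (seed, kinetic temperature,
    #: potential energy, ...)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.frames:
            raise InvalidInputError("a trajectory needs at least one frame")
        times = [f.time for f in self.frames]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise InvalidInputError("frame times must be strictly increasing")
        n0 = self.frames[0].n_beads
        if any(f.n_beads != n0 for f in self.frames):
            raise InvalidInputError("bead count must be identical across frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_molecules(self) -> int:
        return self.frames[0].n_molecules

    def __iter__(self):
        return iter(self.frames)

    def __len__(self):
        return len(self.frames)

    def __getitem__(self, i):
        return self.frames[i]
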