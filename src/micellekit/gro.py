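"""Fixed-column GRO coordinate files, single- and multi-frame.

Layout per frame: a title line (carrying ``t= <ps>`` when written by this
package), an atom-count line, one fixed-column atom line per bead
(``%5d%-5s%5s%5d%8.3f%8.3f%8.3f``: residue number, residue name, atom
name, atom number, x y z in nm), and a box line.  Residue numbers encode
the bead→molecule map; residue names encode chain type and protonation
state (e.g. ``C10D`` deprotonated, ``C10N`` neutral); atom names are the
bead-type labels.  Only orthorhombic boxes are supported.  Parse errors
carry 1-based line numbers.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Union

import numpy as np

from .builder import BoxSpec
from .errors import GROParseError
from .frames import Frame, Trajectory

_TIME_RE = re.compile(r"\bt=\s*([-+0-9.eE]+)")


def write_gro(
    frames: Union[Frame, Trajectory, Iterable[Frame]],
    path: Union[str, Path],
    name: str = "micellekit",
    chain_id: str | None = None,
) -> None:
    """Write one frame or a multi-frame trajectory (concatenated frames)."""
    if isinstance(frames, Frame):
        frame_list = [frames]
    elif isinstance(frames, Trajectory):
        if chain_id is None and frames.topology is not None:
            chain_id = frames.topology.chain_id
        frame_list = frames.frames
    else:
        frame_list = list(frames)
    prefix = (chain_id or "FA")[:3]
    with open(path, "w") as fh:
        for frame in frame_list:
            fh.write(f"{name} t= {frame.time:.4f}\n")
            fh.write(f"{frame.n_beads:5d}\n")
            mol = frame.molecule_of_bead
            # protonation state per molecule from its head bead
            head_idx = np.searchsorted(mol, np.arange(frame.n_molecules))
            state = np.where(frame.bead_types[head_idx] == "Qa", "D", "N")
            for i in range(frame.n_beads):
                resid = (int(mol[i]) + 1) % 100000
                resname = f"{prefix}{state[mol[i]]}"
                atomname = str(frame.bead_types[i])
                atomid = (i + 1) % 100000
                x, y, z = frame.positions[i]
                fh.write(
                    f"{resid:5d}{resname:<5s}{atomname:>5s}{atomid:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            fh.write(
                f"{frame.box.lx:10.5f}{frame.box.ly:10.5f}{frame.box.lz:10.5f}\n"
            )


def _parse_box_line(line: str, lineno: int) -> BoxSpec:
    parts = line.split()
    try:
        vals = [float(p) for p in parts]
    except ValueError:
        raise GROParseError(f"unparseable box line {line!r}", lineno) from None
    if len(vals) == 3:
        return BoxSpec(*vals)
    if len(vals) == 9:
        if any(abs(v) > 1e-12 for v in vals[3:]):
            raise GROParseError("non-orthorhombic box is not supported", lineno)
        return BoxSpec(vals[0], vals[1], vals[2])
    raise GROParseError(f"box line must hold 3 or 9 numbers, got {len(vals)}", lineno)


def read_gro(path: Union[str, Path]) -> Trajectory:
    """Parse a (possibly multi-frame) GRO file into a Trajectory.

    The bead→molecule map is rebuilt from residue numbers (a new molecule
    starts whenever the residue number changes, which also survives the
    100000 wraparound); bead types are taken from atom names.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise GROParseError("empty file", 1)

    frames: list[Frame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip() and i == len(lines) - 1:
            break
        title = lines[i]
        m = _TIME_RE.search(title)
        time = float(m.group(1)) if m else float(len(frames))
        if i + 1 >= len(lines):
            raise GROParseError("truncated frame: missing atom count", i + 2)
        try:
            n_atoms = int(lines[i + 1].strip())
        except ValueError:
            raise GROParseError(
                f"malformed atom count line {lines[i + 1]!r}", i + 2
            ) from None
        if n_atoms < 0:
            raise GROParseError("negative atom count", i + 2)
        if i + 2 + n_atoms >= len(lines):
            raise GROParseError(
                f"truncated frame: expected {n_atoms} atom lines plus a box line",
                len(lines) + 1,
            )
        positions = np.empty((n_atoms, 3))
        mol_of_bead = np.empty(n_atoms, dtype=np.int64)
        bead_types = []
        prev_resid = None
        mol_counter = -1
        for a in range(n_atoms):
            lineno = i + 3 + a
            line = lines[i + 2 + a]
            if len(line) < 44:
                raise GROParseError(f"atom line too short ({len(line)} chars)", lineno)
            try:
                resid = int(line[0:5])
                atomname = line[10:15].strip()
                x = float(line[20:28])
                y = float(line[28:36])
                z = float(line[36:44])
            except ValueError:
                raise GROParseError(f"malformed atom line {line!r}", lineno) from None
            if resid != prev_resid:
                mol_counter += 1
                prev_resid = resid
            mol_of_bead[a] = mol_counter
            bead_types.append(atomname)
            positions[a] = (x, y, z)
        box = _parse_box_line(lines[i + 2 + n_atoms], i + 3 + n_atoms)
        frames.append(
            Frame(
                time=time,
                box=box,
                positions=positions,
                molecule_of_bead=mol_of_bead,
                bead_types=np.array(bead_types),
            )
        )
        i += 3 + n_atoms
        while i < len(lines) and not lines[i].strip():
            i += 1
    if not frames:
        raise GROParseError("no frames found", 1)
    return Trajectory(frames=frames)
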