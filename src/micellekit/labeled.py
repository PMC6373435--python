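"""Labeled test configurations with known aggregate structure.

Builds frames in which the ground-truth partition into free monomers and
aggregates is known by construction: within each aggregate every molecule
is placed within the contact cutoff of an already placed molecule (so the
single-linkage contact graph is connected), while distinct groups are kept
farther apart than ``cutoff + margin`` under the minimum-image convention.
Clustering such a frame at the same cutoff must recover the construction
exactly, which is what makes these configurations useful as analysis
oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .builder import BoxSpec, MCFATopology
from .errors import InvalidInputError, PlacementError
from .frames import Frame


@dataclass
class GroundTruthPartition:
    """Known free/aggregated split of a labeled configuration."""

    free_molecule_ids: set[int]
    aggregates: list[set[int]]

    def __post_init__(self):
        everything: set[int] = set(self.free_molecule_ids)
        for agg in self.aggregates:
            if everything & agg:
                raise InvalidInputError("ground-truth sets must be disjoint")
            everything |= agg
        n = len(self.free_molecule_ids) + sum(len(a) for a in self.aggregates)
        if everything != set(range(n)):
            raise InvalidInputError("ground truth must cover molecules 0..n-1")

    @property
    def n_molecules(self) -> int:
        return len(self.free_molecule_ids) + sum(len(a) for a in self.aggregates)

    def as_sets(self) -> set[frozenset[int]]:
        """All groups (aggregates and singleton free molecules) as a set."""
        groups = {frozenset(a) for a in self.aggregates}
        groups |= {frozenset([m]) for m in self.free_molecule_ids}
        return groups


def _straight_chain(
    start: np.ndarray, direction: np.ndarray, n_beads: int, bond: float
) -> np.ndarray:
    steps = np.arange(n_beads)[:, None] * bond
    return start[None, :] + steps * direction[None, :]


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _build_group(
    size: int,
    topology: MCFATopology,
    cutoff: float,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> np.ndarray:
    """Local bead coordinates of one connected group, centred on its centroid.

    The first molecule sits at the origin; each later molecule starts
    within (0.4, 0.85) x cutoff of a random already placed bead, which
    guarantees a connected contact graph under the strict < cutoff rule.
    Molecules straying beyond a size-dependent radius are redrawn to keep
    the group compact.
    """
    chain_len = (topology.n_beads - 1) * topology.bond_length
    r_max = chain_len + cutoff * (1.0 + 0.7 * size ** (1.0 / 3.0))
    beads = _straight_chain(np.zeros(3), _random_unit(rng), topology.n_beads, topology.bond_length)
    beads -= beads.mean(axis=0)
    coords = [beads]
    placed = beads
    for _ in range(size - 1):
        for attempt in range(max_retries + 1):
            anchor = placed[rng.integers(len(placed))]
            start = anchor + rng.uniform(0.4, 0.85) * cutoff * _random_unit(rng)
            mol = _straight_chain(start, _random_unit(rng), topology.n_beads, topology.bond_length)
            if np.max(np.linalg.norm(mol, axis=1)) <= r_max:
                coords.append(mol)
                placed = np.concatenate([placed, mol])
                break
        else:
            raise PlacementError(f"could not keep a {size}-molecule aggregate compact")
    group = np.concatenate(coords)
    group -= group.mean(axis=0)
    return group


def generate_labeled_configuration(
    n_free: int,
    aggregate_sizes: Sequence[int],
    topology: MCFATopology,
    box: BoxSpec,
    cutoff: float = 0.6,
    margin: float = 0.2,
    seed: int = 0,
    max_retries: int = 2000,
) -> tuple[Frame, GroundTruthPartition]:
    """Build a frame whose aggregate partition is known by construction.

    Aggregates come first in molecule numbering, then free monomers.
    Raises :class:`PlacementError` when the box cannot hold the requested
    content at the requested separation.
    """
    if n_free < 0 or any(s < 1 for s in aggregate_sizes):
        raise InvalidInputError("group sizes must be positive, n_free non-negative")
    if n_free == 0 and not aggregate_sizes:
        raise InvalidInputError("nothing to place")
    rng = np.random.default_rng(seed)
    sizes = list(aggregate_sizes) + [1] * n_free
    groups = [_build_group(s, topology, cutoff, rng) for s in sizes]
    extents = [float(np.max(np.linalg.norm(g, axis=1))) for g in groups]

    box_l = box.lengths
    min_edge = float(box_l.min())
    for ext in extents:
        if 2 * ext + cutoff + margin >= min_edge / 2.0:
            raise PlacementError(
                "a group is too large for this box: periodic self-images "
                "could not be kept separated"
            )

    centres: list[np.ndarray] = []
    for gi, ext in enumerate(extents):
        for attempt in range(max_retries + 1):
            c = rng.random(3) * box_l
            ok = True
            for cj, extj in zip(centres, extents):
                d = c - cj
                d -= box_l * np.round(d / box_l)
                if np.linalg.norm(d) <= ext + extj + cutoff + margin:
                    ok = False
                    break
            if ok:
                centres.append(c)
                break
        else:
            raise PlacementError(
                f"could not place group {gi} after {max_retries} retries; "
                "box too small for the requested content at this margin"
            )

    positions = np.concatenate(
        [(g + c[None, :]) % box_l for g, c in zip(groups, centres)]
    )
    mols = []
    mol_id = 0
    for s in sizes:
        for _ in range(s):
            mols.extend([mol_id] * topology.n_beads)
            mol_id += 1
    mol_of_bead = np.array(mols, dtype=np.int64)
    bead_types = np.array(topology.bead_names * mol_id)

    frame = Frame(
        time=0.0,
        box=box,
        positions=positions,
        molecule_of_bead=mol_of_bead,
        bead_types=bead_types,
    )
    mol_id = 0
    aggregates = []
    for s in aggregate_sizes:
        aggregates.append(set(range(mol_id, mol_id + s)))
        mol_id += s
    free_ids = set(range(mol_id, mol_id + n_free))
    return frame, GroundTruthPartition(free_molecule_ids=free_ids, aggregates=aggregates)
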