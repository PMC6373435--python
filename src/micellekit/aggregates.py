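"""Aggregate detection and free-monomer analysis.

Two molecules belong to the same aggregate when any pair of their beads
lies strictly closer than a distance cutoff (0.6 nm for this bead model)
under the minimum-image convention; aggregates are the connected
components of that contact graph (single linkage).  A molecule counts as
*free* when its aggregate is no larger than a size cutoff read off the
valley of the bimodal aggregate size distribution (default 5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import InvalidInputError
from .frames import Frame, Trajectory


@dataclass
class AggregatePartition:
    """Per-frame assignment of every molecule to exactly one aggregate.

    Aggregate ids are contiguous from 0, numbered by first molecule
    occurrence.
    """

    frame_time: float
    aggregate_of_molecule: np.ndarray  # (n_molecules,) int
    sizes: dict[int, int]

    def __post_init__(self):
        self.aggregate_of_molecule = np.asarray(self.aggregate_of_molecule, dtype=np.int64)
        if sum(self.sizes.values()) != len(self.aggregate_of_molecule):
            raise InvalidInputError("aggregate sizes must sum to the molecule count")

    @property
    def n_molecules(self) -> int:
        return len(self.aggregate_of_molecule)

    @property
    def n_aggregates(self) -> int:
        return len(self.sizes)

    def size_of_molecule(self) -> np.ndarray:
        """Size of the aggregate each molecule resides in."""
        size_by_id = np.zeros(self.n_aggregates, dtype=np.int64)
        for agg_id, s in self.sizes.items():
            size_by_id[agg_id] = s
        return size_by_id[self.aggregate_of_molecule]

    def members(self, aggregate_id: int) -> set[int]:
        return set(np.flatnonzero(self.aggregate_of_molecule == aggregate_id))

    def as_sets(self) -> list[frozenset[int]]:
        return [frozenset(self.members(a)) for a in range(self.n_aggregates)]


def _relabel_contiguous(labels: np.ndarray) -> tuple[np.ndarray, dict[int, int]]:
    """Renumber component labels by first occurrence; return sizes."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    sizes = dict(zip(*np.unique(out, return_counts=True)))
    return out, {int(k): int(v) for k, v in sizes.items()}


def _check_cutoff(frame: Frame, cutoff: float) -> None:
    if cutoff <= 0:
        raise InvalidInputError("cutoff must be positive")
    half_min_edge = float(np.min(frame.box.lengths)) / 2.0
    if cutoff >= half_min_edge:
        raise InvalidInputError(
            f"cutoff {cutoff} nm >= half the smallest box edge "
            f"({half_min_edge} nm); minimum image is ill-defined"
        )


def cluster_molecules(frame: Frame, cutoff: float = 0.6) -> AggregatePartition:
    """Single-linkage aggregate partition of one frame.

    Neighbour search uses a periodic kd-tree; candidate bead pairs are
    post-filtered to the *strict* ``< cutoff`` rule so the result equals
    the all-pairs computation exactly (boundary-equal distances are
    non-contacts).
    """
    _check_cutoff(frame, cutoff)
    box = frame.box.lengths
    pos = frame.positions % box
    n_mol = frame.n_molecules
    tree = cKDTree(pos, boxsize=box)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs):
        d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
        d -= box * np.round(d / box)
        strict = np.einsum("ij,ij->i", d, d) < cutoff * cutoff
        pairs = pairs[strict]
    mol = frame.molecule_of_bead
    if len(pairs):
        mi, mj = mol[pairs[:, 0]], mol[pairs[:, 1]]
        keep = mi != mj
        mi, mj = mi[keep], mj[keep]
    else:
        mi = mj = np.empty(0, dtype=np.int64)
    graph = coo_matrix(
        (np.ones(len(mi)), (mi, mj)), shape=(n_mol, n_mol)
    )
    _, labels = connected_components(graph, directed=False)
    labels, sizes = _relabel_contiguous(labels)
    return AggregatePartition(frame_time=frame.time, aggregate_of_molecule=labels, sizes=sizes)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_molecules_bruteforce(frame: Frame, cutoff: float = 0.6) -> AggregatePartition:
    """All-pairs reference clustering (full bead distance matrix + union-find).

    Independent of the kd-tree path; intended as an oracle for tests and
    verification runs, O(n_beads^2) in memory and time.
    """
    _check_cutoff(frame, cutoff)
    box = frame.box.lengths
    pos = frame.positions % box
    d = pos[:, None, :] - pos[None, :, :]
    d -= box * np.round(d / box)
    contact = np.einsum("ijk,ijk->ij", d, d) < cutoff * cutoff
    mol = frame.molecule_of_bead
    uf = _UnionFind(frame.n_molecules)
    ii, jj = np.nonzero(np.triu(contact, k=1))
    for i, j in zip(ii, jj):
        if mol[i] != mol[j]:
            uf.union(int(mol[i]), int(mol[j]))
    labels = np.array([uf.find(m) for m in range(frame.n_molecules)])
    labels, sizes = _relabel_contiguous(labels)
    return AggregatePartition(frame_time=frame.time, aggregate_of_molecule=labels, sizes=sizes)


@dataclass
class SizeDistribution:
    """Fraction of molecules residing in aggregates of each size.

    ``probabilities[s]`` is the probability that a randomly chosen molecule
    (in a randomly chosen frame) sits in an aggregate of exactly ``s``
    molecules; values sum to 1.
    """

    probabilities: dict[int, float]
    n_frames_averaged: int
    n_molecules: int

    def __post_init__(self):
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidInputError(f"probabilities sum to {total}, expected 1")

    def dense(self) -> np.ndarray:
        """Probabilities on sizes 1..max as a dense vector (index 0 = size 1)."""
        smax = max(self.probabilities)
        out = np.zeros(smax)
        for s, p in self.probabilities.items():
            out[s - 1] = p
        return out


def size_distribution(
    partitions: Sequence[AggregatePartition], weighting: str = "molecule"
) -> SizeDistribution:
    """Aggregate size distribution averaged over frames.

    ``weighting="molecule"`` (default) weights each size by the number of
    molecules it holds; ``"aggregate"`` weights each aggregate once.
    """
    partitions = list(partitions)
    if not partitions:
        raise InvalidInputError("need at least one partition")
    n_mol = partitions[0].n_molecules
    if any(p.n_molecules != n_mol for p in partitions):
        raise InvalidInputError("molecule counts differ across frames")
    counts: dict[int, float] = {}
    for p in partitions:
        for s in p.sizes.values():
            weight = s if weighting == "molecule" else 1
            counts[s] = counts.get(s, 0) + weight
    if weighting == "molecule":
        denom = n_mol * len(partitions)
    elif weighting == "aggregate":
        denom = sum(p.n_aggregates for p in partitions)
    else:
        raise InvalidInputError(f"unknown weighting {weighting!r}")
    probs = {s: c / denom for s, c in sorted(counts.items())}
    return SizeDistribution(probs, n_frames_averaged=len(partitions), n_molecules=n_mol)


@dataclass
class FreeSizeCutoff:
    """Free/aggregated size boundary read off a size distribution."""

    value: int
    used_default: bool  # True when no valley could be located


def free_cutoff_from_distribution(dist: SizeDistribution, default: int = 5) -> FreeSizeCutoff:
    """Locate the valley between the first two peaks of the distribution.

    Returns the size at the minimum strictly between the first and second
    local maxima (ties broken toward the smaller size).  When the
    distribution has no second peak (e.g. strictly decreasing), the default
    is returned with ``used_default=True``.
    """
    dense = dist.dense()
    # pad so boundary maxima (size 1 is typically a peak) are detected
    padded = np.concatenate([[-np.inf], dense, [-np.inf]])
    peaks, _ = find_peaks(padded)
    peaks = peaks - 1  # back to dense indexing
    if len(peaks) < 2 or peaks[1] - peaks[0] < 2:
        return FreeSizeCutoff(default, used_default=True)
    lo, hi = peaks[0], peaks[1]
    valley = dense[lo + 1 : hi]
    idx = int(np.argmin(valley))  # first occurrence = smallest size on ties
    return FreeSizeCutoff(lo + 1 + idx + 1, used_default=False)  # +1 index->size


@dataclass
class FreeFractionPoint:
    """Mean free-molecule fraction at one concentration."""

    concentration_mM: float
    mean_free_fraction: float
    sd: float
    n_snapshots: int

    def __post_init__(self):
        if not 0.0 <= self.mean_free_fraction <= 1.0:
            raise InvalidInputError("mean free fraction must lie in [0, 1]")
        if self.sd < 0:
            raise InvalidInputError("sd must be non-negative")


def snapshot_indices(n_frames: int, window_fraction: float, n_snapshots: int) -> np.ndarray:
    """Evenly spaced frame indices within the final window of a run."""
    n_window = max(1, int(round(window_fraction * n_frames)))
    if n_window < n_snapshots:
        raise InvalidInputError(
            f"final window holds {n_window} frames but {n_snapshots} snapshots "
            "were requested"
        )
    start = n_frames - n_window
    return np.round(np.linspace(start, n_frames - 1, n_snapshots)).astype(int)


def free_fraction(
    trajectory: Trajectory,
    cutoff: float = 0.6,
    size_cutoff: int = 5,
    window_fraction: float = 0.1,
    n_snapshots: int = 20,
    boundary: str = "le",
    concentration_mM: Optional[float] = None,
) -> FreeFractionPoint:
    """Free-molecule fraction averaged over late-run snapshots.

    ``n_snapshots`` evenly spaced frames are taken from the final
    ``window_fraction`` of the trajectory; per frame, the free fraction is
    the share of molecules in aggregates of size <= ``size_cutoff``
    (``boundary="lt"`` switches to strict <).  The mean and the sample
    standard deviation across snapshots are returned.
    """
    if boundary not in ("le", "lt"):
        raise InvalidInputError("boundary must be 'le' or 'lt'")
    idx = snapshot_indices(trajectory.n_frames, window_fraction, n_snapshots)
    fractions = []
    for i in idx:
        part = cluster_molecules(trajectory.frames[i], cutoff)
        sizes = part.size_of_molecule()
        free = sizes <= size_cutoff if boundary == "le" else sizes < size_cutoff
        fractions.append(free.mean())
    fractions = np.array(fractions)
    if concentration_mM is None and trajectory.composition is not None:
        concentration_mM = trajectory.composition.concentration_mM
    sd = float(fractions.std(ddof=1)) if len(fractions) > 1 else 0.0
    return FreeFractionPoint(
        concentration_mM=float(concentration_mM) if concentration_mM is not None else float("nan"),
        mean_free_fraction=float(fractions.mean()),
        sd=sd,
        n_snapshots=len(fractions),
    )
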