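"""Coarse-grained system construction for medium-chain fatty acids (MCFAs).

A fatty acid is modelled as a short linear chain of coarse-grained beads:
one head bead (``P4`` when the carboxylic acid is neutral, ``Qa`` carrying
charge −1 when deprotonated) followed by apolar ``C1`` tail beads, each
bead standing for roughly four heavy atoms.  C14 and C10 use the standard
0.47 nm bead spacing; C12 and C8 reuse the same bead counts with the
spacing reduced to 0.37 nm to express the two-carbon difference.

This module converts physical targets (concentration in mM, ionic strength
in mM, protonation fraction, box edge lengths in nm) into integer particle
counts and initial coordinates.  Two counting conventions are supported for
ions because published compositions commonly quote "ions per mM" times the
ionic strength rather than a direct mole count; see
:func:`salt_pairs_for_ionic_strength`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, PlacementError
from .frames import Frame

AVOGADRO = 6.02214076e23  # 1/mol

#: bead-type label -> charge in elementary units
BEAD_CHARGES = {"C1": 0, "P4": 0, "Qa": -1}

#: chain id -> (number of beads including the head, bond length in nm)
CHAIN_GEOMETRY = {
    "C14": (4, 0.47),
    "C12": (4, 0.37),
    "C10": (3, 0.47),
    "C8": (3, 0.37),
}


@dataclass(frozen=True)
class BeadSpec:
    """One coarse-grained bead: type label and charge (e units)."""

    name: str
    charge: int

    def __post_init__(self):
        if self.name not in BEAD_CHARGES:
            raise InvalidInputError(f"unknown bead type {self.name!r}")
        if self.charge != BEAD_CHARGES[self.name]:
            raise InvalidInputError(
                f"bead {self.name} must carry charge {BEAD_CHARGES[self.name]}, got {self.charge}"
            )


@dataclass(frozen=True)
class MCFATopology:
    """Ordered bead specification of one fatty-acid chain, head first."""

    chain_id: str
    beads: tuple[BeadSpec, ...]
    bond_length: float  # nm
    deprotonated: bool

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def bead_names(self) -> list[str]:
        return [b.name for b in self.beads]


@dataclass(frozen=True)
class BoxSpec:
    """Orthorhombic periodic box, edge lengths in nm."""

    lx: float
    ly: float
    lz: float
    periodic: bool = True

    def __post_init__(self):
        if min(self.lx, self.ly, self.lz) <= 0:
            raise InvalidInputError("box edge lengths must be positive")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz], dtype=float)

    @property
    def volume_nm3(self) -> float:
        return self.lx * self.ly * self.lz

    @property
    def volume_litres(self) -> float:
        return self.volume_nm3 * 1e-24


def build_topology(chain_id: str, deprotonated: bool) -> MCFATopology:
    """Return the coarse-grained topology for one chain type.

    The head bead is ``Qa`` (charge −1) when deprotonated, ``P4`` otherwise;
    every tail bead is ``C1``.
    """
    if chain_id not in CHAIN_GEOMETRY:
        raise InvalidInputError(
            f"unknown chain id {chain_id!r}; expected one of {sorted(CHAIN_GEOMETRY)}"
        )
    n_beads, bond = CHAIN_GEOMETRY[chain_id]
    head = BeadSpec("Qa", -1) if deprotonated else BeadSpec("P4", 0)
    tail = tuple(BeadSpec("C1", 0) for _ in range(n_beads - 1))
    return MCFATopology(chain_id, (head,) + tail, bond, deprotonated)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def molecules_for_concentration(concentration_mM: float, box: BoxSpec) -> int:
    """Number of molecules representing ``concentration_mM`` in ``box``.

    Direct mole count: ``round(c[mol/L] * V[L] * N_A)``, rounded half away
    from zero.  For the 22x22x44 nm box, 1 mM maps to 13 molecules.
    """
    if concentration_mM < 0:
        raise InvalidInputError("concentration must be non-negative")
    exact = concentration_mM * 1e-3 * box.volume_litres * AVOGADRO
    return _round_half_away(exact)


def salt_pairs_for_ionic_strength(
    ionic_strength_mM: float, box: BoxSpec, convention: str = "per_mm"
) -> int:
    """Number of Na+/Cl- pairs representing an ionic strength.

    ``convention="per_mm"`` (default) scales the per-mM molecule count
    linearly: ``molecules_for_concentration(1 mM) * I[mM]``, which yields
    the conventional 13 x 140 = 1820 pairs for the 22x22x44 nm box.
    ``convention="direct"`` applies the same direct mole count used for
    the fatty acids (1795 pairs for the same box).
    """
    if ionic_strength_mM < 0:
        raise InvalidInputError("ionic strength must be non-negative")
    if convention == "per_mm":
        per_mm = molecules_for_concentration(1.0, box)
        return _round_half_away(per_mm * ionic_strength_mM)
    if convention == "direct":
        return molecules_for_concentration(ionic_strength_mM, box)
    raise InvalidInputError(f"unknown salt convention {convention!r}")


@dataclass(frozen=True)
class SystemComposition:
    """Box plus derived particle counts for one simulated condition.

    Solvent, counterions and salt appear only as counts here; the reduced
    dynamics engine treats them implicitly (salt through Debye screening).
    Charge neutrality: every deprotonated head (−1) is balanced by one
    counterion, so ``n_counterions == n_deprotonated``.
    """

    box: BoxSpec
    chain_id: str
    concentration_mM: float
    fraction_deprotonated: float
    ionic_strength_mM: float
    temperature_C: float
    n_mcfa: int
    n_deprotonated: int
    n_neutral: int
    n_counterions: int
    n_salt_pairs: int

    def __post_init__(self):
        if self.n_deprotonated + self.n_neutral != self.n_mcfa:
            raise InvalidInputError("protonation split must partition n_mcfa")
        if self.n_counterions != self.n_deprotonated:
            raise InvalidInputError("counterions must balance deprotonated heads")
        if min(self.n_mcfa, self.n_salt_pairs) < 0:
            raise InvalidInputError("counts must be non-negative")

    @property
    def total_charge(self) -> int:
        return -self.n_deprotonated + self.n_counterions

    def to_dict(self) -> dict:
        return {
            "box_nm": [self.box.lx, self.box.ly, self.box.lz],
            "chain_id": self.chain_id,
            "concentration_mM": self.concentration_mM,
            "fraction_deprotonated": self.fraction_deprotonated,
            "ionic_strength_mM": self.ionic_strength_mM,
            "temperature_C": self.temperature_C,
            "n_mcfa": self.n_mcfa,
            "n_deprotonated": self.n_deprotonated,
            "n_neutral": self.n_neutral,
            "n_counterions": self.n_counterions,
            "n_salt_pairs": self.n_salt_pairs,
        }


def build_composition(
    chain_id: str,
    concentration_mM: float,
    fraction_deprotonated: float,
    ionic_strength_mM: float,
    box: BoxSpec,
    temperature_C: float = 37.0,
    salt_convention: str = "per_mm",
) -> SystemComposition:
    """Derive all particle counts for one condition.

    The protonation split uses round-half-to-even on
    ``n_mcfa * fraction_deprotonated`` (a pure tie-break; 13 molecules at
    fraction 0.5 gives 6 deprotonated).
    """
    if not 0.0 <= fraction_deprotonated <= 1.0:
        raise InvalidInputError("fraction_deprotonated must lie in [0, 1]")
    if chain_id not in CHAIN_GEOMETRY:
        raise InvalidInputError(f"unknown chain id {chain_id!r}")
    n_mcfa = molecules_for_concentration(concentration_mM, box)
    n_deprot = round(n_mcfa * fraction_deprotonated)  # banker's rounding
    n_salt = salt_pairs_for_ionic_strength(ionic_strength_mM, box, salt_convention)
    return SystemComposition(
        box=box,
        chain_id=chain_id,
        concentration_mM=concentration_mM,
        fraction_deprotonated=fraction_deprotonated,
        ionic_strength_mM=ionic_strength_mM,
        temperature_C=temperature_C,
        n_mcfa=n_mcfa,
        n_deprotonated=n_deprot,
        n_neutral=n_mcfa - n_deprot,
        n_counterions=n_deprot,
        n_salt_pairs=n_salt,
    )


def molecule_bead_types(composition: SystemComposition, topology: MCFATopology) -> list[list[str]]:
    """Per-molecule bead-type labels honouring the protonation split.

    The first ``n_deprotonated`` molecules get a ``Qa`` head, the rest
    ``P4``; tails are ``C1``.  Order is deterministic so the same
    composition always maps to the same labelled system.
    """
    tail = ["C1"] * (topology.n_beads - 1)
    out = []
    for m in range(composition.n_mcfa):
        head = "Qa" if m < composition.n_deprotonated else "P4"
        out.append([head] + tail)
    return out


def place_initial_dispersion(
    composition: SystemComposition,
    topology: MCFATopology,
    seed: int,
    min_separation: float = 0.30,
    max_retries: int = 500,
) -> Frame:
    """Randomly disperse straight-chain molecules in the box.

    Each molecule is a rigid rod of beads spaced exactly ``bond_length``
    apart, at a uniformly random centre and orientation, wrapped into the
    box.  A candidate molecule is rejected (and redrawn, up to
    ``max_retries`` times) if any of its beads falls within
    ``min_separation`` nm of an already placed bead under the minimum-image
    convention; persistent failure raises :class:`PlacementError`.
    Deterministic for a given seed.
    """
    if composition.n_mcfa <= 0:
        raise InvalidInputError("composition holds no molecules to place")
    rng = np.random.default_rng(seed)
    box = composition.box.lengths
    r0 = topology.bond_length
    nb = topology.n_beads
    offsets = (np.arange(nb) - (nb - 1) / 2.0)[:, None] * r0

    placed: list[np.ndarray] = []
    occupied = np.empty((0, 3))
    min_sep2 = min_separation**2
    for _m in range(composition.n_mcfa):
        for attempt in range(max_retries + 1):
            centre = rng.random(3) * box
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            beads = (centre[None, :] + offsets * direction[None, :]) % box
            if occupied.size:
                d = occupied[None, :, :] - beads[:, None, :]
                d -= box * np.round(d / box)
                if np.min(np.einsum("ijk,ijk->ij", d, d)) < min_sep2:
                    continue
            placed.append(beads)
            occupied = np.concatenate([occupied, beads])
            break
        else:
            raise PlacementError(
                f"could not place molecule {_m} after {max_retries} retries; "
                "box too crowded for the requested composition"
            )

    positions = np.concatenate(placed)
    mol_of_bead = np.repeat(np.arange(composition.n_mcfa), nb)
    types = molecule_bead_types(composition, topology)
    bead_types = np.array([t for mol in types for t in mol])
    return Frame(
        time=0.0,
        box=composition.box,
        positions=positions,
        molecule_of_bead=mol_of_bead,
        bead_types=bead_types,
    )
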