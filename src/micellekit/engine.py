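"""Reduced implicit-solvent Langevin engine for amphiphile self-assembly.

This engine is a desk-scale stand-in for explicit-solvent coarse-grained
MD: solvent and salt are implicit.  Hydrophobic attraction enters through
the tail-tail Lennard-Jones well depth; ionic strength enters only through
the Debye screening length of the head-head Coulomb term.  Units follow
the MD convention: nm, ps, amu, kJ/mol (kB = 0.0083144621 kJ/mol/K).

Because the solvent is implicit, absolute aggregation thresholds produced
here are not comparable with explicit-solvent results; the engine is meant
for qualitative trends (concentration and chain-length dependence of the
free-monomer fraction) and for generating analysable trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .builder import (
    BoxSpec,
    MCFATopology,
    SystemComposition,
    build_composition,
    build_topology,
    place_initial_dispersion,
)
from .errors import IntegrationError, InvalidInputError
from .frames import Frame, Trajectory

KB = 0.0083144621  # kJ/mol/K

#: bead-type label -> row index of the epsilon table
TYPE_INDEX = {"C1": 0, "P4": 1, "Qa": 2}

#: default LJ well depths (kJ/mol) by type pair; tails attract strongly
#: (implicit hydrophobic effect), head-involving pairs are weak.
DEFAULT_EPSILON = {
    ("C1", "C1"): 4.2,
    ("C1", "P4"): 1.8,
    ("C1", "Qa"): 1.6,
    ("P4", "P4"): 2.2,
    ("P4", "Qa"): 2.0,
    ("Qa", "Qa"): 1.5,
}


def debye_length_nm(
    ionic_strength_mM: float, temperature_K: float = 310.15, relative_permittivity: float = 15.0
) -> float:
    """Debye screening length for a 1:1 electrolyte.

    lambda_D = sqrt(eps0 * eps_r * kB * T / (2 * NA * e^2 * I)); returns
    inf at zero ionic strength (unscreened).
    """
    if ionic_strength_mM < 0:
        raise InvalidInputError("ionic strength must be non-negative")
    if ionic_strength_mM == 0:
        return float("inf")
    eps0 = 8.8541878128e-12  # F/m
    kb = 1.380649e-23  # J/K
    e = 1.602176634e-19  # C
    na = 6.02214076e23
    ionic_si = ionic_strength_mM  # mM == mol/m^3
    lam_m = math.sqrt(
        eps0 * relative_permittivity * kb * temperature_K / (2.0 * na * e * e * ionic_si)
    )
    return lam_m * 1e9


@dataclass
class EngineParams:
    """Tunable engine parameters (MD units: nm, ps, amu, kJ/mol).

    ``debye_length`` of ``None`` means "derive from the composition's
    ionic strength"; ``bond_length`` of ``None`` means "take it from the
    topology".  ``repulsive_only`` truncates the LJ term at its minimum
    (WCA form), removing every attractive well — the non-aggregating
    control.
    """

    timestep: float = 0.02  # ps
    n_steps: int = 50000
    friction: float = 1.0  # 1/ps
    temperature: float = 310.15  # K
    lj_epsilon: dict = field(default_factory=lambda: dict(DEFAULT_EPSILON))
    lj_sigma: float = 0.47  # nm
    coulomb_relative_permittivity: float = 15.0
    debye_length: Optional[float] = None  # nm
    nonbonded_cutoff: float = 1.2  # nm
    bond_force_constant: float = 1250.0  # kJ/mol/nm^2
    bead_mass: float = 72.0  # amu
    frame_stride: int = 250  # steps between saved frames
    seed: int = 0
    repulsive_only: bool = False
    bond_length: Optional[float] = None  # nm
    minimize_steps: int = 500
    equilibration: Optional[Sequence[tuple[float, int]]] = None  # (dt, steps) ramp

    def __post_init__(self):
        if self.timestep <= 0:
            raise InvalidInputError("timestep must be positive")
        if self.nonbonded_cutoff <= self.lj_sigma:
            raise InvalidInputError("cutoff must exceed sigma")
        for (a, b), v in list(self.lj_epsilon.items()):
            if (b, a) in self.lj_epsilon and self.lj_epsilon[(b, a)] != v:
                raise InvalidInputError(f"epsilon table asymmetric for pair {a},{b}")

    def epsilon_matrix(self) -> np.ndarray:
        mat = np.zeros((3, 3))
        for (a, b), v in self.lj_epsilon.items():
            mat[TYPE_INDEX[a], TYPE_INDEX[b]] = v
            mat[TYPE_INDEX[b], TYPE_INDEX[a]] = v
        return mat


@dataclass
class ParticleSystem:
    """Flat arrays the kernels consume, derived from a Frame."""

    positions: np.ndarray
    box: np.ndarray
    mol_of_bead: np.ndarray
    type_idx: np.ndarray
    charge: np.ndarray
    bonds: np.ndarray  # (n_bonds, 2) int

    @classmethod
    def from_frame(cls, frame: Frame) -> "ParticleSystem":
        types = frame.bead_types
        type_idx = np.array([TYPE_INDEX[t] for t in types], dtype=np.int64)
        charge = np.where(types == "Qa", -1.0, 0.0)
        mol = frame.molecule_of_bead
        # consecutive beads of the same molecule are bonded (chain order)
        same = mol[:-1] == mol[1:]
        i = np.flatnonzero(same)
        bonds = np.stack([i, i + 1], axis=1).astype(np.int64)
        return cls(
            positions=frame.positions.copy(),
            box=frame.box.lengths,
            mol_of_bead=mol.astype(np.int64),
            type_idx=type_idx,
            charge=charge,
            bonds=bonds,
        )


def _kernel_constants(system: ParticleSystem, params: EngineParams, composition=None):
    """Precompute the scalar constants the kernels take."""
    sigma = params.lj_sigma
    if params.repulsive_only:
        lj_cut = 2.0 ** (1.0 / 6.0) * sigma
    else:
        lj_cut = params.nonbonded_cutoff
    sr6 = (sigma / lj_cut) ** 6
    shift_factor = 4.0 * (sr6 * sr6 - sr6)
    lam = params.debye_length
    if lam is None:
        ionic = composition.ionic_strength_mM if composition is not None else 0.0
        lam = debye_length_nm(ionic, params.temperature, params.coulomb_relative_permittivity)
    inv_debye = 0.0 if math.isinf(lam) else 1.0 / lam
    coul_cut = params.nonbonded_cutoff
    coul_shift = math.exp(-coul_cut * inv_debye) / coul_cut
    ke = _kernels.F_ELEC / params.coulomb_relative_permittivity
    r0 = params.bond_length if params.bond_length is not None else 0.47
    cut = max(lj_cut, coul_cut)
    use_cell = bool(np.all(system.box / cut >= 3.0)) and len(system.positions) > 64
    return dict(
        eps_mat=params.epsilon_matrix(),
        sigma2=sigma * sigma,
        shift_factor=shift_factor,
        lj_cut2=lj_cut * lj_cut,
        ke=ke,
        inv_debye=inv_debye,
        coul_cut=coul_cut,
        coul_shift_per_qq=coul_shift,
        r0=r0,
        k_bond=params.bond_force_constant,
        use_cell=use_cell,
    )


def potential_energy_and_forces(
    system: ParticleSystem, params: EngineParams, composition=None, use_cell=None
) -> tuple[float, np.ndarray]:
    k = _kernel_constants(system, params, composition)
    if use_cell is not None:
        k["use_cell"] = use_cell
    e, f = _kernels.compute_forces(
        system.positions, system.box, system.mol_of_bead, system.type_idx,
        system.charge, k["eps_mat"], k["sigma2"], k["shift_factor"],
        k["lj_cut2"], k["ke"], k["inv_debye"], k["coul_cut"],
        k["coul_shift_per_qq"], system.bonds, k["r0"], k["k_bond"], k["use_cell"],
    )
    return float(e), f


def minimize_energy(frame: Frame, params: EngineParams, max_steps: int = 10000) -> Frame:
    """Steepest-descent energy minimisation with adaptive step length.

    Moves along the normalised force direction; a trial step is accepted
    only if it lowers the energy (so energy(out) <= energy(in) always
    holds), the step length growing on success and shrinking on rejection
    until it underflows or ``max_steps`` is reached.
    """
    system = ParticleSystem.from_frame(frame)
    e, f = potential_energy_and_forces(system, params)
    if not math.isfinite(e):
        raise InvalidInputError("initial configuration has non-finite energy")
    h = 0.02  # nm, initial displacement of the largest-force bead
    for _ in range(max_steps):
        fmax = float(np.abs(f).max())
        if fmax < 1e-10 or h < 1e-12:
            break
        trial = (system.positions + h * f / fmax) % system.box
        trial_system = replace(system, positions=trial)
        e_trial, f_trial = potential_energy_and_forces(trial_system, params)
        if e_trial < e:
            system = trial_system
            e, f = e_trial, f_trial
            h *= 1.2
        else:
            h *= 0.2
    return Frame(
        time=frame.time,
        box=frame.box,
        positions=system.positions,
        molecule_of_bead=frame.molecule_of_bead.copy(),
        bead_types=frame.bead_types.copy(),
    )


def _run_dynamics(
    system: ParticleSystem,
    params: EngineParams,
    composition,
    frame_template: Frame,
    rng: np.random.Generator,
) -> tuple[list[Frame], dict]:
    """Integrate ``params.n_steps`` BAOAB steps, emitting strided frames.

    Also returns per-frame diagnostics: potential energy and kinetic
    temperature at each saved frame.
    """
    n = len(system.positions)
    kT = KB * params.temperature
    m = params.bead_mass
    vel = rng.normal(0.0, math.sqrt(kT / m), size=(n, 3))
    k = _kernel_constants(system, params, composition)

    def chunk(pos, vel, forces, dt, n_sub):
        c1 = math.exp(-params.friction * dt)
        c2 = math.sqrt(kT / m * (1.0 - c1 * c1)) if params.friction > 0 else 0.0
        noise = rng.standard_normal((n_sub, n, 3)) if c2 > 0 else np.zeros((n_sub, n, 3))
        return _kernels.baoab_chunk(
            pos, vel, system.box, system.mol_of_bead, system.type_idx,
            system.charge, k["eps_mat"], k["sigma2"], k["shift_factor"],
            k["lj_cut2"], k["ke"], k["inv_debye"], k["coul_cut"],
            k["coul_shift_per_qq"], system.bonds, k["r0"], k["k_bond"],
            k["use_cell"], forces, noise, dt, c1, c2, 1.0 / m,
        )

    e0, forces = potential_energy_and_forces(system, params, composition)
    pos = system.positions

    if params.equilibration:
        for dt_eq, steps_eq in params.equilibration:
            e0 = chunk(pos, vel, forces, dt_eq, steps_eq)
            if not np.all(np.isfinite(pos)):
                raise IntegrationError(0)

    def make_frame(time):
        return Frame(
            time=time,
            box=frame_template.box,
            positions=pos.copy(),
            molecule_of_bead=frame_template.molecule_of_bead.copy(),
            bead_types=frame_template.bead_types.copy(),
        )

    frames = [make_frame(0.0)]
    potential = [float(e0)]
    kin_temp = [kinetic_temperature(vel, m)]
    step = 0
    while step < params.n_steps:
        n_sub = min(params.frame_stride, params.n_steps - step)
        e = chunk(pos, vel, forces, params.timestep, n_sub)
        step += n_sub
        if not np.all(np.isfinite(pos)):
            raise IntegrationError(step)
        frames.append(make_frame(step * params.timestep))
        potential.append(float(e))
        kin_temp.append(kinetic_temperature(vel, m))
    diagnostics = {
        "potential_energy_kJ_per_mol": potential,
        "kinetic_temperature_K": kin_temp,
    }
    return frames, diagnostics


def run_selfassembly(
    composition: SystemComposition,
    topology: MCFATopology,
    params: EngineParams,
) -> Trajectory:
    """Self-assembly run from a random dispersion.

    Places molecules at random, optionally minimises, then integrates
    Langevin dynamics; frames are saved every ``frame_stride`` steps (the
    t=0 configuration included).  A single seed drives placement, initial
    velocities and thermal noise, so identical inputs give identical
    trajectories.
    """
    if params.bond_length is None:
        params = replace(params, bond_length=topology.bond_length)
    ss = np.random.SeedSequence(params.seed)
    place_seed, dyn_seed = ss.spawn(2)
    frame0 = place_initial_dispersion(
        composition, topology, seed=int(place_seed.generate_state(1)[0] % (2**31))
    )
    if params.minimize_steps:
        frame0 = minimize_energy(frame0, params, max_steps=params.minimize_steps)
    system = ParticleSystem.from_frame(frame0)
    rng = np.random.default_rng(dyn_seed)
    frames, diagnostics = _run_dynamics(system, params, composition, frame0, rng)
    diagnostics["seed"] = params.seed
    return Trajectory(
        frames=frames, topology=topology, composition=composition, metadata=diagnostics
    )


def simulate_concentration_series(
    chain_id: str,
    concentrations_mM: Sequence[float],
    params: EngineParams,
    seeds: Sequence[int],
    box: BoxSpec,
    fraction_deprotonated: float = 1.0,
    ionic_strength_mM: float = 140.0,
    temperature_C: float = 37.0,
) -> list[tuple[float, Trajectory]]:
    """One self-assembly run per concentration under shared engine params.

    ``seeds`` must provide one seed per concentration.  Engine errors are
    re-raised tagged with the offending concentration.
    """
    if len(concentrations_mM) < 2:
        raise InvalidInputError("a concentration series needs at least 2 points")
    if len(seeds) != len(concentrations_mM):
        raise InvalidInputError("need one seed per concentration")
    topology = build_topology(chain_id, deprotonated=fraction_deprotonated >= 0.5)
    out = []
    for conc, seed in zip(concentrations_mM, seeds):
        comp = build_composition(
            chain_id, conc, fraction_deprotonated, ionic_strength_mM, box, temperature_C
        )
        run_params = replace(params, seed=int(seed))
        try:
            traj = run_selfassembly(comp, topology, run_params)
        except IntegrationError as err:  # pragma: no cover - needs a blow-up
            err.args = (f"at concentration {conc} mM: {err.args[0]}",)
            raise
        out.append((conc, traj))
    return out


def kinetic_temperature(velocities: np.ndarray, mass: float) -> float:
    """Instantaneous kinetic temperature (K) of a velocity set."""
    n = len(velocities)
    ke = 0.5 * mass * float(np.sum(velocities**2))
    return 2.0 * ke / (3.0 * n * KB)
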