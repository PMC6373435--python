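"""Reduced Langevin engine: determinism, thermodynamic sanity, minimisation."""

import numpy as np
import pytest

import micellekit as mk
from micellekit.builder import BoxSpec
from micellekit.engine import (
    KB,
    EngineParams,
    ParticleSystem,
    potential_energy_and_forces,
)
from micellekit.frames import Frame


@pytest.fixture
def small_system(topo3):
    comp = mk.build_composition("C10", 60.0, 1.0, 140.0, BoxSpec(12, 12, 12))
    return comp, topo3


def dimer_frame(separation, box_edge=10.0):
    """Two bonded beads of one molecule at a given separation."""
    box = BoxSpec(box_edge, box_edge, box_edge)
    pos = np.array([[5.0, 5.0, 5.0], [5.0 + separation, 5.0, 5.0]])
    return Frame(0.0, box, pos, np.array([0, 0]), np.array(["Qa", "C1"]))


class TestDeterminism:
    def test_same_seed_identical_trajectories(self, small_system):
        comp, topo = small_system
        p = EngineParams(seed=7, n_steps=1500, frame_stride=100)
        t1 = mk.run_selfassembly(comp, topo, p)
        t2 = mk.run_selfassembly(comp, topo, p)
        assert len(t1) == len(t2)
        for a, b in zip(t1.frames, t2.frames):
            assert np.array_equal(a.positions, b.positions)

    def test_different_seeds_differ(self, small_system):
        comp, topo = small_system
        t1 = mk.run_selfassembly(comp, topo, EngineParams(seed=7, n_steps=500, frame_stride=100))
        t2 = mk.run_selfassembly(comp, topo, EngineParams(seed=8, n_steps=500, frame_stride=100))
        assert not np.array_equal(t1.frames[-1].positions, t2.frames[-1].positions)


class TestForces:
    def test_cell_list_matches_all_pairs(self, small_system):
        comp, topo = small_system
        frame = mk.place_initial_dispersion(comp, topo, seed=1)
        params = EngineParams(bond_length=topo.bond_length)
        system = ParticleSystem.from_frame(frame)
        e_cell, f_cell = potential_energy_and_forces(system, params, comp, use_cell=True)
        e_all, f_all = potential_energy_and_forces(system, params, comp, use_cell=False)
        assert e_cell == pytest.approx(e_all, rel=1e-12, abs=1e-9)
        assert np.allclose(f_cell, f_all, atol=1e-9)

    def test_forces_are_negative_energy_gradient(self, topo3):
        """Central-difference check of the analytic forces."""
        comp = mk.build_composition("C10", 40.0, 1.0, 140.0, BoxSpec(8, 8, 8))
        frame = mk.place_initial_dispersion(comp, topo3, seed=2)
        params = EngineParams(bond_length=topo3.bond_length)
        system = ParticleSystem.from_frame(frame)
        _, forces = potential_energy_and_forces(system, params, comp)
        h = 1e-6
        rng = np.random.default_rng(0)
        for _ in range(12):
            i = int(rng.integers(system.positions.shape[0]))
            d = int(rng.integers(3))
            pp = system.positions.copy(); pp[i, d] += h
            pm = system.positions.copy(); pm[i, d] -= h
            ep, _ = potential_energy_and_forces(
                ParticleSystem(pp, system.box, system.mol_of_bead, system.type_idx,
                               system.charge, system.bonds), params, comp)
            em, _ = potential_energy_and_forces(
                ParticleSystem(pm, system.box, system.mol_of_bead, system.type_idx,
                               system.charge, system.bonds), params, comp)
            numeric = -(ep - em) / (2 * h)
            assert forces[i, d] == pytest.approx(numeric, rel=1e-4, abs=1e-4)


class TestThermodynamics:
    def test_energy_conservation_without_thermostat(self, small_system):
        """Friction 0 reduces BAOAB to velocity Verlet; drift < 1% of KE."""
        comp, topo = small_system
        p = EngineParams(
            seed=7, n_steps=10000, frame_stride=500, friction=0.0,
            timestep=0.005, minimize_steps=2000,
        )
        traj = mk.run_selfassembly(comp, topo, p)
        pe = np.array(traj.metadata["potential_energy_kJ_per_mol"])
        kt = np.array(traj.metadata["kinetic_temperature_K"])
        ke = 1.5 * traj.frames[0].n_beads * KB * kt
        total = pe + ke
        assert abs(total[-1] - total[0]) < 0.01 * ke[0]

    def test_kinetic_temperature_near_target(self, small_system):
        comp, topo = small_system
        p = EngineParams(seed=3, n_steps=6000, frame_stride=200)
        traj = mk.run_selfassembly(comp, topo, p)
        temps = np.array(traj.metadata["kinetic_temperature_K"])
        late = temps[len(temps) // 2 :].mean()
        assert abs(late - p.temperature) / p.temperature < 0.10

    def test_bond_lengths_fluctuate_around_r0(self, small_system):
        comp, topo = small_system
        p = EngineParams(seed=5, n_steps=4000, frame_stride=200)
        traj = mk.run_selfassembly(comp, topo, p)
        box = traj.frames[0].box.lengths
        means = []
        for frame in traj.frames[len(traj.frames) // 2 :]:
            mol = frame.molecule_of_bead
            same = mol[:-1] == mol[1:]
            i = np.flatnonzero(same)
            d = frame.positions[i + 1] - frame.positions[i]
            d -= box * np.round(d / box)
            means.append(np.linalg.norm(d, axis=1).mean())
        assert abs(np.mean(means) - topo.bond_length) / topo.bond_length < 0.05


class TestMinimise:
    def test_dimer_at_minimum_unchanged(self, topo3):
        frame = dimer_frame(0.47)
        params = EngineParams(bond_length=0.47)
        out = mk.minimize_energy(frame, params, max_steps=100)
        assert np.allclose(out.positions, frame.positions, atol=1e-6)

    def test_stretched_dimer_relaxes_to_bond_length(self):
        frame = dimer_frame(0.94)  # 2 x r0
        params = EngineParams(bond_length=0.47)
        out = mk.minimize_energy(frame, params, max_steps=10000)
        d = out.positions[1] - out.positions[0]
        d -= frame.box.lengths * np.round(d / frame.box.lengths)
        assert np.linalg.norm(d) == pytest.approx(0.47, abs=1e-4)

    def test_energy_never_increases(self, small_system):
        comp, topo = small_system
        params = EngineParams(bond_length=topo.bond_length)
        for seed in (1, 2, 3):
            frame = mk.place_initial_dispersion(comp, topo, seed=seed)
            e_in, _ = potential_energy_and_forces(ParticleSystem.from_frame(frame), params, comp)
            out = mk.minimize_energy(frame, params, max_steps=300)
            e_out, _ = potential_energy_and_forces(ParticleSystem.from_frame(out), params, comp)
            assert e_out <= e_in


class TestSeries:
    def test_series_molecule_counts_match_compositions(self, topo3):
        box = BoxSpec(10, 10, 10)
        p = EngineParams(n_steps=400, frame_stride=100)
        runs = mk.simulate_concentration_series("C10", [30.0, 60.0], p, [1, 2], box)
        assert len(runs) == 2
        for conc, traj in runs:
            expected = mk.molecules_for_concentration(conc, box)
            assert traj.n_molecules == expected

    def test_single_concentration_rejected(self, topo3):
        with pytest.raises(mk.InvalidInputError):
            mk.simulate_concentration_series(
                "C10", [30.0], EngineParams(), [1], BoxSpec(10, 10, 10)
            )

    def test_seed_count_mismatch_rejected(self):
        with pytest.raises(mk.InvalidInputError):
            mk.simulate_concentration_series(
                "C10", [30.0, 60.0], EngineParams(), [1], BoxSpec(10, 10, 10)
            )


class TestDebye:
    def test_length_decreases_with_ionic_strength(self):
        l1 = mk.debye_length_nm(10.0)
        l2 = mk.debye_length_nm(140.0)
        assert l1 > l2 > 0

    def test_zero_ionic_strength_unscreened(self):
        assert mk.debye_length_nm(0.0) == np.inf

    def test_inverse_square_root_scaling(self):
        assert mk.debye_length_nm(40.0) == pytest.approx(
            mk.debye_length_nm(10.0) / 2.0, rel=1e-12
        )
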