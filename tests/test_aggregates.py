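"""Aggregate clustering, size distributions, and free-fraction analysis."""

import numpy as np
import pytest

import micellekit as mk
from micellekit.builder import BoxSpec
from micellekit.frames import Frame, Trajectory

from conftest import random_frame


def two_molecule_frame(gap, box_edge=22.0):
    """Two 3-bead molecules along x; closest beads separated by `gap` nm."""
    box = BoxSpec(box_edge, box_edge, box_edge)
    a = np.array([[1.0, 5.0, 5.0], [1.47, 5.0, 5.0], [1.94, 5.0, 5.0]])
    start = 1.94 + gap
    b = np.array([[start, 5.0, 5.0], [start + 0.47, 5.0, 5.0], [start + 0.94, 5.0, 5.0]])
    return Frame(
        time=0.0,
        box=box,
        positions=np.vstack([a, b]),
        molecule_of_bead=np.array([0, 0, 0, 1, 1, 1]),
        bead_types=np.array(["Qa", "C1", "C1"] * 2),
    )


class TestClusterMolecules:
    def test_contact_below_cutoff_links(self):
        part = mk.cluster_molecules(two_molecule_frame(0.55), cutoff=0.6)
        assert part.n_aggregates == 1
        assert part.sizes[0] == 2

    def test_separation_above_cutoff_does_not_link(self):
        part = mk.cluster_molecules(two_molecule_frame(0.65), cutoff=0.6)
        assert part.n_aggregates == 2

    def test_boundary_equal_distance_is_not_a_contact(self):
        part = mk.cluster_molecules(two_molecule_frame(0.6), cutoff=0.6)
        assert part.n_aggregates == 2

    def test_transitive_closure(self):
        """A-B and B-C in contact link A-C despite their large distance."""
        box = BoxSpec(22, 22, 22)
        pos = np.array([[1.0, 5, 5], [1.5, 5, 5], [2.0, 5, 5]])
        frame = Frame(0.0, box, pos, np.array([0, 1, 2]), np.array(["Qa"] * 3))
        part = mk.cluster_molecules(frame, cutoff=0.6)
        assert part.n_aggregates == 1
        assert part.sizes[0] == 3

    def test_periodic_wrap_links_across_boundary(self):
        box = BoxSpec(22, 22, 22)
        pos = np.array([[0.2, 5, 5], [21.8, 5, 5]])
        frame = Frame(0.0, box, pos, np.array([0, 1]), np.array(["Qa", "Qa"]))
        part = mk.cluster_molecules(frame, cutoff=0.6)
        assert part.n_aggregates == 1

    def test_too_large_cutoff_rejected(self):
        frame = two_molecule_frame(0.5, box_edge=1.0)
        with pytest.raises(mk.InvalidInputError):
            mk.cluster_molecules(frame, cutoff=0.5)

    @pytest.mark.parametrize("n_mol,edge", [(30, 5.0), (80, 7.0), (200, 9.0)])
    def test_matches_bruteforce_oracle(self, n_mol, edge):
        """Cell-based clustering equals the all-pairs union-find oracle."""
        rng = np.random.default_rng(42 + n_mol)
        for _ in range(12):
            frame = random_frame(rng, n_mol, box_edge=edge)
            fast = mk.cluster_molecules(frame, 0.6)
            ref = mk.cluster_molecules_bruteforce(frame, 0.6)
            assert np.array_equal(fast.aggregate_of_molecule, ref.aggregate_of_molecule)
            assert fast.sizes == ref.sizes

    def test_permutation_invariance_of_size_multiset(self):
        rng = np.random.default_rng(0)
        frame = random_frame(rng, 60, box_edge=6.0)
        base = mk.cluster_molecules(frame, 0.6)
        # relabel molecules by a random permutation (reorder bead blocks)
        perm = rng.permutation(60)
        order = np.argsort(perm[frame.molecule_of_bead], kind="stable")
        permuted = Frame(
            0.0, frame.box, frame.positions[order],
            perm[frame.molecule_of_bead][order], frame.bead_types[order],
        )
        other = mk.cluster_molecules(permuted, 0.6)
        assert sorted(base.sizes.values()) == sorted(other.sizes.values())

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        frame = random_frame(rng, 60, box_edge=6.0)
        base = mk.cluster_molecules(frame, 0.6)
        shift = np.array([1.7, -2.3, 4.1])
        moved = Frame(
            0.0, frame.box, (frame.positions + shift) % frame.box.lengths,
            frame.molecule_of_bead, frame.bead_types,
        )
        other = mk.cluster_molecules(moved, 0.6)
        assert np.array_equal(base.aggregate_of_molecule, other.aggregate_of_molecule)

    def test_larger_cutoff_never_increases_aggregate_count(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            frame = random_frame(rng, 50, box_edge=6.0)
            n_prev = None
            for cutoff in (0.3, 0.5, 0.7, 0.9):
                n = mk.cluster_molecules(frame, cutoff).n_aggregates
                if n_prev is not None:
                    assert n <= n_prev
                n_prev = n

    def test_partition_covers_every_molecule_once(self):
        rng = np.random.default_rng(3)
        frame = random_frame(rng, 70, box_edge=6.0)
        part = mk.cluster_molecules(frame, 0.6)
        assert len(part.aggregate_of_molecule) == 70
        assert sum(part.sizes.values()) == 70
        assert set(part.aggregate_of_molecule) == set(range(part.n_aggregates))


class TestSizeDistribution:
    def test_all_monomers(self):
        rng = np.random.default_rng(4)
        frame = random_frame(rng, 20, box_edge=30.0)  # dilute -> all free
        part = mk.cluster_molecules(frame, 0.6)
        dist = mk.size_distribution([part])
        assert dist.probabilities == {1: 1.0}

    def test_single_aggregate_of_all(self, topo3):
        frame, _ = mk.generate_labeled_configuration(
            0, [12], topo3, BoxSpec(16, 16, 16), seed=0
        )
        part = mk.cluster_molecules(frame, 0.6)
        dist = mk.size_distribution([part])
        assert dist.probabilities == {12: 1.0}

    def test_known_mixture_molecule_weighted(self, topo3):
        frame, _ = mk.generate_labeled_configuration(
            10, [10], topo3, BoxSpec(16, 16, 16), seed=1
        )
        part = mk.cluster_molecules(frame, 0.6)
        dist = mk.size_distribution([part])
        assert dist.probabilities[1] == pytest.approx(0.5)
        assert dist.probabilities[10] == pytest.approx(0.5)

    def test_aggregate_weighting_switch(self, topo3):
        frame, _ = mk.generate_labeled_configuration(
            10, [10], topo3, BoxSpec(16, 16, 16), seed=1
        )
        part = mk.cluster_molecules(frame, 0.6)
        dist = mk.size_distribution([part], weighting="aggregate")
        assert dist.probabilities[1] == pytest.approx(10 / 11)
        assert dist.probabilities[10] == pytest.approx(1 / 11)

    def test_inconsistent_molecule_counts_rejected(self):
        rng = np.random.default_rng(5)
        p1 = mk.cluster_molecules(random_frame(rng, 10, box_edge=8.0), 0.6)
        p2 = mk.cluster_molecules(random_frame(rng, 11, box_edge=8.0), 0.6)
        with pytest.raises(mk.InvalidInputError):
            mk.size_distribution([p1, p2])


class TestFreeCutoff:
    def _dist(self, probs):
        total = sum(probs.values())
        return mk.SizeDistribution(
            {s: p / total for s, p in probs.items()}, 1, max(probs)
        )

    def test_bimodal_valley_found(self):
        probs = {1: 30, 2: 10, 3: 4, 4: 2, 5: 1, 6: 2, 10: 3, 30: 40}
        # peaks at 1 and 10(+30 region); unique minimum at size 5
        cut = mk.free_cutoff_from_distribution(self._dist(probs))
        assert cut.value == 5
        assert not cut.used_default

    def test_monotone_decreasing_falls_back_to_default(self):
        probs = {1: 50, 2: 25, 3: 12, 4: 6, 5: 3}
        cut = mk.free_cutoff_from_distribution(self._dist(probs))
        assert cut.value == 5
        assert cut.used_default

    def test_flat_valley_ties_to_smallest_size(self):
        probs = {1: 30, 2: 10, 3: 5, 4: 2, 5: 2, 6: 2, 7: 5, 8: 20}
        cut = mk.free_cutoff_from_distribution(self._dist(probs))
        assert cut.value == 4
        assert not cut.used_default


class TestFreeFraction:
    def _trajectory(self, frames):
        return Trajectory(frames=frames)

    def test_all_monomer_frames_give_one(self):
        rng = np.random.default_rng(6)
        frames = [random_frame(rng, 15, box_edge=30.0) for _ in range(10)]
        for i, f in enumerate(frames):
            f.time = float(i)
        traj = self._trajectory(frames)
        pt = mk.free_fraction(traj, window_fraction=0.5, n_snapshots=5)
        assert pt.mean_free_fraction == 1.0
        assert pt.sd == 0.0

    def test_single_large_aggregate_gives_zero(self, topo3):
        frames = []
        for i in range(10):
            f, _ = mk.generate_labeled_configuration(
                0, [15], topo3, BoxSpec(16, 16, 16), seed=i
            )
            f.time = float(i)
            frames.append(f)
        pt = mk.free_fraction(self._trajectory(frames), window_fraction=0.5, n_snapshots=5)
        assert pt.mean_free_fraction == 0.0

    def test_known_split_recovered(self, topo3):
        """40 singletons and one 60-molecule aggregate -> free fraction 0.40."""
        frames = []
        for i in range(6):
            f, _ = mk.generate_labeled_configuration(
                40, [60], topo3, BoxSpec(26, 26, 26), seed=100 + i
            )
            f.time = float(i)
            frames.append(f)
        pt = mk.free_fraction(self._trajectory(frames), window_fraction=1.0, n_snapshots=6)
        assert pt.mean_free_fraction == pytest.approx(0.4)
        assert pt.sd == pytest.approx(0.0, abs=1e-12)

    def test_size_cutoff_boundary_switch(self, topo3):
        """A size-5 aggregate is free under <=5 but aggregated under <5."""
        f, _ = mk.generate_labeled_configuration(5, [5], topo3, BoxSpec(16, 16, 16), seed=7)
        traj = self._trajectory([f])
        le = mk.free_fraction(traj, window_fraction=1.0, n_snapshots=1, boundary="le")
        lt = mk.free_fraction(traj, window_fraction=1.0, n_snapshots=1, boundary="lt")
        assert le.mean_free_fraction == 1.0
        assert lt.mean_free_fraction == 0.5

    def test_too_few_frames_in_window_rejected(self):
        rng = np.random.default_rng(8)
        frames = [random_frame(rng, 10, box_edge=8.0) for _ in range(5)]
        for i, f in enumerate(frames):
            f.time = float(i)
        with pytest.raises(mk.InvalidInputError):
            mk.free_fraction(self._trajectory(frames), window_fraction=0.2, n_snapshots=20)
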