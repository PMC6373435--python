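import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from micellekit.builder import BoxSpec, build_topology


@pytest.fixture
def paper_box():
    """The 22 x 22 x 44 nm box used for the short-chain systems."""
    return BoxSpec(22.0, 22.0, 44.0)


@pytest.fixture
def topo3():
    """Three-bead deprotonated chain (C10-like)."""
    return build_topology("C10", deprotonated=True)


@pytest.fixture
def topo4():
    """Four-bead deprotonated chain (C14-like)."""
    return build_topology("C14", deprotonated=True)


def random_frame(rng, n_molecules, n_beads_per_mol=3, box_edge=8.0, bond=0.47):
    """A random frame of straight-chain molecules for clustering tests."""
    from micellekit.builder import BoxSpec
    from micellekit.frames import Frame

    box = BoxSpec(box_edge, box_edge, box_edge)
    centres = rng.random((n_molecules, 3)) * box_edge
    dirs = rng.standard_normal((n_molecules, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    offs = (np.arange(n_beads_per_mol) - (n_beads_per_mol - 1) / 2)[None, :, None] * bond
    pos = (centres[:, None, :] + offs * dirs[:, None, :]).reshape(-1, 3) % box_edge
    mol = np.repeat(np.arange(n_molecules), n_beads_per_mol)
    types = np.array((["Qa"] + ["C1"] * (n_beads_per_mol - 1)) * n_molecules)
    return Frame(time=0.0, box=box, positions=pos, molecule_of_bead=mol, bead_types=types)
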