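"""Build a coarse-grained fatty-acid system from physical targets.

Converts concentration, protonation fraction and ionic strength into
particle counts for the reference 22 x 22 x 44 nm box, then places an
initial random dispersion and writes it as a GRO file.
"""

import micellekit as mk
from micellekit.builder import BoxSpec

box = BoxSpec(22.0, 22.0, 44.0)

# 1 mM of decanoate in this box corresponds to 13 molecules; an ionic
# strength of 140 mM NaCl is represented by 13 x 140 = 1820 ion pairs.
print("molecules at 1 mM:", mk.molecules_for_concentration(1.0, box))
print("ion pairs at 140 mM:", mk.salt_pairs_for_ionic_strength(140.0, box))

comp = mk.build_composition(
    chain_id="C10",
    concentration_mM=25.0,
    fraction_deprotonated=1.0,
    ionic_strength_mM=140.0,
    box=box,
    temperature_C=37.0,
)
print("25 mM C10 composition:", comp.to_dict())

topo = mk.build_topology("C10", deprotonated=True)
print("C10 topology:", topo.bead_names, f"bond {topo.bond_length} nm")

frame = mk.place_initial_dispersion(comp, topo, seed=1)
mk.write_gro(frame, "c10_25mM_initial.gro", chain_id="C10")
print(f"wrote {frame.n_beads} beads ({frame.n_molecules} molecules) to c10_25mM_initial.gro")
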