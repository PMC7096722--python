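data_comp_TOY
# Toy ligand for tests and examples: a meta-chloro propylbenzene.
# Restraint dictionary in the CCP4 monomer-library mmCIF dialect.
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
TOY C1 C
TOY C2 C
TOY C3 C
TOY C4 C
TOY C5 C
TOY C6 C
TOY CL1 CL
TOY C7 C
TOY C8 C
TOY C9 C
loop_
_chem_comp_bond.comp_id
_chem_comp_bond.atom_id_1
_chem_comp_bond.atom_id_2
_chem_comp_bond.value_dist
_chem_comp_bond.value_dist_esd
TOY C1 C2 1.390 0.010
TOY C2 C3 1.390 0.010
TOY C3 C4 1.390 0.010
TOY C4 C5 1.390 0.010
TOY C5 C6 1.390 0.010
TOY C6 C1 1.390 0.010
TOY C3 CL1 1.740 0.015
TOY C1 C7 1.510 0.020
TOY C7 C8 1.530 0.020
TOY C8 C9 1.530 0.020
loop_
_chem_comp_angle.comp_id
_chem_comp_angle.atom_id_1
_chem_comp_angle.atom_id_2
_chem_comp_angle.atom_id_3
_chem_comp_angle.value_angle
_chem_comp_angle.value_angle_esd
TOY C6 C1 C2 120.0 1.5
TOY C1 C2 C3 120.0 1.5
TOY C2 C3 C4 120.0 1.5
TOY C3 C4 C5 120.0 1.5
TOY C4 C5 C6 120.0 1.5
TOY C5 C6 C1 120.0 1.5
TOY C2 C3 CL1 120.0 1.8
TOY C4 C3 CL1 120.0 1.8
TOY C2 C1 C7 120.0 1.8
TOY C6 C1 C7 120.0 1.8
TOY C1 C7 C8 112.0 2.0
TOY C7 C8 C9 112.0 2.0
loop_
_chem_comp_tor.comp_id
_chem_comp_tor.id
_chem_comp_tor.atom_id_1
_chem_comp_tor.atom_id_2
_chem_comp_tor.atom_id_3
_chem_comp_tor.atom_id_4
_chem_comp_tor.value_angle
_chem_comp_tor.value_angle_esd
_chem_comp_tor.period
TOY tor_ring C2 C1 C7 C8 90.000 10.00 2
TOY tor_chain C1 C7 C8 C9 180.000 10.00 3
loop_
_chem_comp_plane_atom.comp_id
_chem_comp_plane_atom.plane_id
_chem_comp_plane_atom.atom_id
_chem_comp_plane_atom.dist_esd
TOY ring C1 0.020
TOY ring C2 0.020
TOY ring C3 0.020
TOY ring C4 0.020
TOY ring C5 0.020
TOY ring C6 0.020
TOY ring CL1 0.020
TOY ring C7 0.020
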