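"""Fragment surgery: copy a zone out, edit it, put it back; merge a ligand.

The copy -> operate -> replace cycle is how larger models are edited
piecewise; ligand merging picks the nearest chain and the next free residue
number.
"""

import numpy as np

from rsfit import (
    make_ideal_polypeptide,
    make_toy_ligand,
    merge_ligand,
    replace_fragment,
    select_fragment,
)

master = make_ideal_polypeptide("A" * 100, "helix")

# copy residues 50-60, nudge them, and replace them in the master
frag = select_fragment(master, "//A/50-60")
print(f"selected fragment: {frag.n_residues()} residues "
      f"({frag.n_atoms()} atoms)")
for atom in frag.atoms():
    atom.pos = atom.pos + np.array([0.3, 0.0, 0.0])
edited = replace_fragment(master, frag)
moved = sum(
    1 for r_new, r_old in zip(edited.residues(), master.residues())
    if not np.allclose([a.pos for a in r_new.atoms],
                       [a.pos for a in r_old.atoms]))
print(f"replace_fragment: {moved} residues moved, "
      f"{edited.n_residues() - moved} untouched")

# merge a ligand: nearest chain, next residue number
ligand = make_toy_ligand()
anchor = master.chain("A")[29].pos("CA") + np.array([0.0, 4.0, 0.0])
shift = anchor - ligand.atoms[0].pos
for atom in ligand.atoms:
    atom.pos = atom.pos + shift
with_ligand = merge_ligand(master, ligand)
lig = [r for r in with_ligand.residues() if r.res_type == "TOY"][0]
print(f"ligand merged into chain {lig.chain_id} as residue {lig.seqnum}")
print("The ligand joined chain A (the only chain nearby) and was numbered "
      "one above the chain's previous maximum (100 -> 101).")
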