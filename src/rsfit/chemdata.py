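"""Chemical reference data: elements, protein topology, ideal geometry.

This module is the single source of truth for the geometry used both by the
fixture generators (ideal polypeptides, rotamer placement) and by the
embedded monomer dictionary, so that a model built here scores zero
distortion against restraints derived from the same templates.

Side chains are described as internal-coordinate (NeRF) recipes: each atom
is placed from three previously placed atoms by a bond length, a bond angle
and a dihedral.  Dihedrals are either fixed numbers or ("chi", k, offset),
meaning chi_k + offset degrees.  Aromatic rings use internally consistent
polygon values so that ring-closure bonds are satisfied exactly.
"""

from __future__ import annotations

import numpy as np

import gemmi

from .geometry import place_atom

# ---------------------------------------------------------------------------
# Elements

#: van der Waals contact radii (A) for the elements that occur in standard
#: residues and common ligands; used by clash scoring and nonbonded restraints.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}
DEFAULT_VDW = 1.70

#: Metals recognised by the LINK-record restraint generator.
METAL_ELEMENTS = {
    "ZN", "MG", "FE", "NA", "CA", "MN", "K", "CU", "NI", "CO", "MO", "CD", "HG",
}

#: Built-in metal-to-ligand coordination distances (A), element-pair keyed.
#: Defaults chosen from typical first-shell coordination geometry; users may
#: override any entry through the configuration file.
METAL_BOND_TABLE = {
    ("ZN", "N"): 2.08, ("ZN", "O"): 2.10, ("ZN", "S"): 2.32,
    ("MG", "O"): 2.08, ("MG", "N"): 2.18,
    ("FE", "N"): 2.00, ("FE", "O"): 2.00, ("FE", "S"): 2.30,
    ("NA", "O"): 2.40, ("NA", "N"): 2.45,
    ("CA", "O"): 2.38, ("CA", "N"): 2.50,
    ("MN", "O"): 2.19, ("MN", "N"): 2.21,
    ("K", "O"): 2.80,
    ("CU", "N"): 2.02, ("CU", "O"): 2.00, ("CU", "S"): 2.30,
    ("NI", "N"): 2.05, ("NI", "O"): 2.05,
    ("CO", "N"): 2.00, ("CO", "O"): 2.05,
}
DEFAULT_METAL_BOND = 2.20


def atomic_number(element: str) -> int:
    el = gemmi.Element(element.capitalize() if len(element) > 1 else element)
    return el.atomic_number


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


# ---------------------------------------------------------------------------
# Amino-acid codes

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA = set(THREE_TO_ONE)

# ---------------------------------------------------------------------------
# Backbone ideal geometry (Engh & Huber style values)

BB = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-O": 1.231,
    "C-N": 1.329,       # peptide bond
    "CA-CB": 1.530,
    "N-CA-C": 111.2,    # tau
    "CA-C-O": 120.8,
    "CA-C-N": 116.2,
    "O-C-N": 123.0,
    "C-N-CA": 121.7,
    "N-CA-CB": 110.4,
    "C-N-CA-CB": -122.6,  # improper fixing L chirality
}

#: default backbone torsions for the fixture builders
CONFORMATIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 120.0),
}

# ---------------------------------------------------------------------------
# Side-chain internal-coordinate templates
#
# Entry: (name, element, (a, b, c), bond, angle, dihedral)
# where the new atom is bonded to c and dihedral is a-b-c-new.

CHI = lambda k, off=0.0: ("chi", k, off)  # noqa: E731

_ring6 = dict(bond=1.390, angle=120.0)  # benzene-like hexagon, closes exactly
_ring5 = dict(bond=1.370, angle=108.0)  # regular pentagon, closes exactly

SIDECHAIN_TEMPLATES: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, CHI(1))],
    "CYS": [("SG", "S", ("N", "CA", "CB"), 1.808, 113.8, CHI(1))],
    "THR": [
        ("OG1", "O", ("N", "CA", "CB"), 1.433, 109.6, CHI(1)),
        ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, CHI(1, -120.0)),
    ],
    "VAL": [
        ("CG1", "C", ("N", "CA", "CB"), 1.521, 110.5, CHI(1)),
        ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, CHI(1, 122.0)),
    ],
    "ILE": [
        ("CG1", "C", ("N", "CA", "CB"), 1.530, 110.4, CHI(1)),
        ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, CHI(1, -122.0)),
        ("CD1", "C", ("CA", "CB", "CG1"), 1.513, 113.9, CHI(2)),
    ],
    "LEU": [
        ("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, CHI(1)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.521, 110.7, CHI(2)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.521, 110.7, CHI(2, 122.0)),
    ],
    "ASP": [
        ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, CHI(1)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.4, CHI(2)),
        ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.4, CHI(2, 180.0)),
    ],
    "ASN": [
        ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, CHI(1)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, CHI(2)),
        ("ND2", "N", ("CA", "CB", "CG"), 1.328, 116.4, CHI(2, 180.0)),
    ],
    "GLU": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, CHI(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, CHI(2)),
        ("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.4, CHI(3)),
        ("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.4, CHI(3, 180.0)),
    ],
    "GLN": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, CHI(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, CHI(2)),
        ("OE1", "O", ("CB", "CG", "CD"), 1.231, 120.8, CHI(3)),
        ("NE2", "N", ("CB", "CG", "CD"), 1.328, 116.4, CHI(3, 180.0)),
    ],
    "MET": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, CHI(1)),
        ("SD", "S", ("CA", "CB", "CG"), 1.803, 112.7, CHI(2)),
        ("CE", "C", ("CB", "CG", "SD"), 1.791, 100.9, CHI(3)),
    ],
    "LYS": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, CHI(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, CHI(2)),
        ("CE", "C", ("CB", "CG", "CD"), 1.508, 111.9, CHI(3)),
        ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.7, CHI(4)),
    ],
    "ARG": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, CHI(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, CHI(2)),
        ("NE", "N", ("CB", "CG", "CD"), 1.461, 111.8, CHI(3)),
        ("CZ", "C", ("CG", "CD", "NE"), 1.329, 124.4, CHI(4)),
        ("NH1", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
        ("NH2", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0),
    ],
    "HIS": [
        ("CG", "C", ("N", "CA", "CB"), 1.497, 113.8, CHI(1)),
        ("ND1", "N", ("CA", "CB", "CG"), _ring5["bond"], 126.0, CHI(2)),
        ("CE1", "C", ("CB", "CG", "ND1"), _ring5["bond"], _ring5["angle"], 180.0),
        ("NE2", "N", ("CG", "ND1", "CE1"), _ring5["bond"], _ring5["angle"], 0.0),
        ("CD2", "C", ("ND1", "CE1", "NE2"), _ring5["bond"], _ring5["angle"], 0.0),
    ],
    "PHE": [
        ("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, CHI(1)),
        ("CD1", "C", ("CA", "CB", "CG"), _ring6["bond"], 120.0, CHI(2)),
        ("CE1", "C", ("CB", "CG", "CD1"), _ring6["bond"], _ring6["angle"], 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), _ring6["bond"], _ring6["angle"], 0.0),
        ("CE2", "C", ("CD1", "CE1", "CZ"), _ring6["bond"], _ring6["angle"], 0.0),
        ("CD2", "C", ("CE1", "CZ", "CE2"), _ring6["bond"], _ring6["angle"], 0.0),
    ],
    "TYR": [
        ("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, CHI(1)),
        ("CD1", "C", ("CA", "CB", "CG"), _ring6["bond"], 120.0, CHI(2)),
        ("CE1", "C", ("CB", "CG", "CD1"), _ring6["bond"], _ring6["angle"], 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), _ring6["bond"], _ring6["angle"], 0.0),
        ("CE2", "C", ("CD1", "CE1", "CZ"), _ring6["bond"], _ring6["angle"], 0.0),
        ("CD2", "C", ("CE1", "CZ", "CE2"), _ring6["bond"], _ring6["angle"], 0.0),
        ("OH", "O", ("CD1", "CE1", "CZ"), 1.376, 120.0, 180.0),
    ],
    "TRP": [
        ("CG", "C", ("N", "CA", "CB"), 1.498, 113.6, CHI(1)),
        # fused bicyclic: regular pentagon + regular hexagon sharing one edge
        ("CD1", "C", ("CA", "CB", "CG"), 1.400, 126.0, CHI(2)),
        ("NE1", "N", ("CB", "CG", "CD1"), 1.400, 108.0, 180.0),
        ("CE2", "C", ("CG", "CD1", "NE1"), 1.400, 108.0, 0.0),
        ("CD2", "C", ("CD1", "NE1", "CE2"), 1.400, 108.0, 0.0),
        ("CE3", "C", ("NE1", "CE2", "CD2"), 1.400, 120.0, 180.0),
        ("CZ3", "C", ("CE2", "CD2", "CE3"), 1.400, 120.0, 0.0),
        ("CH2", "C", ("CD2", "CE3", "CZ3"), 1.400, 120.0, 0.0),
        ("CZ2", "C", ("CE3", "CZ3", "CH2"), 1.400, 120.0, 0.0),
    ],
    "PRO": [
        ("CG", "C", ("N", "CA", "CB"), 1.492, 104.5, CHI(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.503, 106.1, CHI(2)),
    ],
}

#: ring-closure (and other non-tree) bonds not implied by the NeRF recipes
EXTRA_BONDS: dict[str, list[tuple[str, str]]] = {
    "PHE": [("CD2", "CG")],
    "TYR": [("CD2", "CG")],
    "HIS": [("CD2", "CG")],
    "TRP": [("CD2", "CG"), ("CZ2", "CE2")],
    "PRO": [("CD", "N")],
}

#: chi dihedral definitions (atom-name quadruples) per residue type
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
}

#: per-chi torsion periodicity (index k-1); sp3-sp3 bonds are threefold,
#: rotations into planar (amide/carboxylate/aromatic) groups twofold
CHI_PERIODS: dict[str, list[int]] = {
    "SER": [3], "CYS": [3], "THR": [3], "VAL": [3],
    "ILE": [3, 3], "LEU": [3, 3],
    "ASP": [3, 2], "ASN": [3, 2],
    "GLU": [3, 3, 2], "GLN": [3, 3, 2],
    "MET": [3, 3, 3],
    "LYS": [3, 3, 3, 3],
    "ARG": [3, 3, 3, 2],
    "HIS": [3, 2], "PHE": [3, 2], "TYR": [3, 2], "TRP": [3, 2],
    "PRO": [3, 3],
}

#: planar atom groups restrained per residue type (side chains)
SIDECHAIN_PLANES: dict[str, list[list[str]]] = {
    "ASP": [["CB", "CG", "OD1", "OD2"]],
    "ASN": [["CB", "CG", "OD1", "ND2"]],
    "GLU": [["CG", "CD", "OE1", "OE2"]],
    "GLN": [["CG", "CD", "OE1", "NE2"]],
    "ARG": [["CD", "NE", "CZ", "NH1", "NH2"]],
    "HIS": [["CB", "CG", "ND1", "CE1", "NE2", "CD2"]],
    "PHE": [["CB", "CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "TYR": [["CB", "CG", "CD1", "CE1", "CZ", "CE2", "CD2", "OH"]],
    "TRP": [["CB", "CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2"]],
}

#: chiral centres: (centre, neighbour1, neighbour2, neighbour3)
CHIRAL_CENTRES: dict[str, list[tuple[str, str, str, str]]] = {
    t: [("CA", "N", "C", "CB")] for t in STANDARD_AA if t != "GLY"
}
CHIRAL_CENTRES["ILE"] = [("CA", "N", "C", "CB"), ("CB", "CA", "CG1", "CG2")]
CHIRAL_CENTRES["THR"] = [("CA", "N", "C", "CB"), ("CB", "CA", "OG1", "CG2")]

#: reference chi angles used when building the canonical copy of each
#: residue type (the top rotamer of the shipped library)
REFERENCE_CHIS: dict[str, tuple[float, ...]] = {
    "SER": (62.0,), "CYS": (-65.0,), "THR": (62.0,), "VAL": (175.0,),
    "ILE": (-65.0, 170.0), "LEU": (-65.0, 175.0),
    "ASP": (-70.0, -15.0), "ASN": (-65.0, -40.0),
    "GLU": (-67.0, 180.0, -10.0), "GLN": (-67.0, 180.0, -25.0),
    "MET": (-65.0, -65.0, -70.0), "LYS": (-67.0, 180.0, 180.0, 180.0),
    "ARG": (-67.0, 180.0, 180.0, 180.0),
    "HIS": (-65.0, -70.0), "PHE": (-65.0, -85.0), "TYR": (-65.0, -85.0),
    "TRP": (-65.0, 95.0), "PRO": (-25.0, 35.0),
    "GLY": (), "ALA": (),
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def n_chis(res_type: str) -> int:
    return len(CHI_ATOMS.get(res_type, []))


def residue_bonds(res_type: str) -> list[tuple[str, str]]:
    """All heavy-atom bonds of a standard residue (intra-residue only)."""
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    if res_type != "GLY":
        bonds.append(("CA", "CB"))
    for entry in SIDECHAIN_TEMPLATES.get(res_type, []):
        name, _el, refs, *_ = entry
        bonds.append((refs[2], name))
    bonds.extend(EXTRA_BONDS.get(res_type, []))
    return bonds


def residue_elements(res_type: str) -> dict[str, str]:
    els = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    if res_type != "GLY":
        els["CB"] = "C"
    for entry in SIDECHAIN_TEMPLATES.get(res_type, []):
        els[entry[0]] = entry[1]
    return els


def build_sidechain(
    backbone: dict[str, np.ndarray],
    res_type: str,
    chis: tuple[float, ...] | None = None,
) -> dict[str, np.ndarray]:
    """Place side-chain atoms (CB onward) from backbone N/CA/C positions.

    ``chis`` defaults to the canonical reference conformation.  Returns a
    name -> position mapping including CB.
    """
    if res_type not in SIDECHAIN_TEMPLATES:
        raise KeyError(f"no side-chain template for residue type {res_type!r}")
    if chis is None:
        chis = REFERENCE_CHIS.get(res_type, ())
    pos: dict[str, np.ndarray] = {
        "N": np.asarray(backbone["N"], float),
        "CA": np.asarray(backbone["CA"], float),
        "C": np.asarray(backbone["C"], float),
    }
    out: dict[str, np.ndarray] = {}
    if res_type != "GLY":
        cb = place_atom(pos["C"], pos["N"], pos["CA"],
                        BB["CA-CB"], BB["N-CA-CB"], BB["C-N-CA-CB"])
        pos["CB"] = cb
        out["CB"] = cb
    for name, _el, refs, bond, ang, tor in SIDECHAIN_TEMPLATES[res_type]:
        if isinstance(tor, tuple):
            _tag, k, off = tor
            if k > len(chis):
                raise ValueError(
                    f"{res_type} needs chi{k} but only {len(chis)} given")
            tor_val = chis[k - 1] + off
        else:
            tor_val = tor
        p = place_atom(pos[refs[0]], pos[refs[1]], pos[refs[2]], bond, ang, tor_val)
        pos[name] = p
        out[name] = p
    return out
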