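"""Monomer dictionaries: ideal-geometry restraint templates per residue type.

The embedded dictionary for the 20 standard amino acids is generated from
the same internal-coordinate templates used to build ideal residues
(:mod:`rsfit.chemdata`), by constructing each residue once at its reference
conformation and measuring every bond, angle, plane and chiral volume.
This guarantees that an ideal-geometry fixture scores zero distortion.

External dictionaries in the mmCIF restraint dialect (_chem_comp_bond,
_chem_comp_angle, _chem_comp_tor, _chem_comp_plane_atom, _chem_comp_chir)
can be loaded for ligands; a small toy ligand dictionary ships with the
package for tests and examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

import gemmi

from . import chemdata
from .geometry import angle_deg, dihedral_deg, place_atom

__all__ = [
    "BondTemplate",
    "AngleTemplate",
    "TorsionTemplate",
    "PlaneTemplate",
    "ChiralTemplate",
    "MonomerEntry",
    "MonomerDictionary",
    "MissingDictionaryError",
    "PEPTIDE_LINK",
    "default_dictionary",
    "toy_ligand_path",
]

# default uncertainties used for the embedded templates
SIGMA_BOND = 0.02    # A
SIGMA_ANGLE = 2.0    # degrees
SIGMA_TORSION = 10.0  # degrees
SIGMA_PLANE = 0.02   # A
SIGMA_CHIRAL = 0.2   # A^3


class MissingDictionaryError(KeyError):
    pass


@dataclass(frozen=True)
class BondTemplate:
    a1: str
    a2: str
    target: float
    sigma: float = SIGMA_BOND


@dataclass(frozen=True)
class AngleTemplate:
    a1: str
    a2: str
    a3: str
    target: float
    sigma: float = SIGMA_ANGLE


@dataclass(frozen=True)
class TorsionTemplate:
    name: str
    a1: str
    a2: str
    a3: str
    a4: str
    target: float
    sigma: float = SIGMA_TORSION
    period: int = 1


@dataclass(frozen=True)
class PlaneTemplate:
    name: str
    atoms: tuple[str, ...]
    sigma: float = SIGMA_PLANE


@dataclass(frozen=True)
class ChiralTemplate:
    centre: str
    n1: str
    n2: str
    n3: str
    volume: float
    sigma: float = SIGMA_CHIRAL


@dataclass
class MonomerEntry:
    name: str
    atoms: dict[str, str]                      # atom name -> element
    bonds: list[BondTemplate] = field(default_factory=list)
    angles: list[AngleTemplate] = field(default_factory=list)
    torsions: list[TorsionTemplate] = field(default_factory=list)
    planes: list[PlaneTemplate] = field(default_factory=list)
    chirals: list[ChiralTemplate] = field(default_factory=list)

    def bond_pairs(self) -> list[tuple[str, str]]:
        return [(b.a1, b.a2) for b in self.bonds]


@dataclass
class MonomerDictionary:
    entries: dict[str, MonomerEntry] = field(default_factory=dict)

    def entry(self, res_type: str) -> MonomerEntry:
        try:
            return self.entries[res_type]
        except KeyError:
            raise MissingDictionaryError(
                f"no dictionary entry for residue type {res_type!r}") from None

    def __contains__(self, res_type: str) -> bool:
        return res_type in self.entries

    def add(self, entry: MonomerEntry) -> None:
        self.entries[entry.name] = entry

    def merge(self, other: "MonomerDictionary") -> "MonomerDictionary":
        merged = MonomerDictionary(dict(self.entries))
        merged.entries.update(other.entries)
        return merged


# ---------------------------------------------------------------------------
# Inter-residue peptide link template

PEPTIDE_LINK = {
    "bond": BondTemplate("C", "N", chemdata.BB["C-N"]),
    "angles": [
        AngleTemplate("CA", "C", "N", chemdata.BB["CA-C-N"]),
        AngleTemplate("O", "C", "N", chemdata.BB["O-C-N"]),
        AngleTemplate("C", "N", "CA", chemdata.BB["C-N-CA"]),
    ],
    # omega: previous CA/C to next N/CA, trans
    "torsion": TorsionTemplate("omega", "CA", "C", "N", "CA", 180.0, 5.0, 1),
    "plane": PlaneTemplate("peptide", ("CA", "C", "O", "N", "CA+"), SIGMA_PLANE),
}


# ---------------------------------------------------------------------------
# Embedded amino-acid dictionary, generated by measurement

def _reference_residue(res_type: str) -> dict[str, np.ndarray]:
    """Build one residue of ``res_type`` at ideal geometry, isolated."""
    bb = chemdata.BB
    n = np.zeros(3)
    ca = np.array([bb["N-CA"], 0.0, 0.0])
    c = place_atom(np.array([0.0, 1.0, 0.0]), n, ca, bb["CA-C"], bb["N-CA-C"], 57.0)
    pos = {"N": n, "CA": ca, "C": c}
    pos["O"] = place_atom(n, ca, c, bb["C-O"], bb["CA-C-O"], 180.0)
    if res_type != "GLY":
        pos.update(chemdata.build_sidechain(pos, res_type))
    return pos


def _entry_from_measurement(res_type: str) -> MonomerEntry:
    pos = _reference_residue(res_type)
    elements = chemdata.residue_elements(res_type)
    entry = MonomerEntry(res_type, elements)
    bonds = chemdata.residue_bonds(res_type)
    for a1, a2 in bonds:
        entry.bonds.append(
            BondTemplate(a1, a2, float(np.linalg.norm(pos[a1] - pos[a2]))))
    # angles: all pairs of bonds sharing an atom
    adj: dict[str, set[str]] = {}
    for a1, a2 in bonds:
        adj.setdefault(a1, set()).add(a2)
        adj.setdefault(a2, set()).add(a1)
    for centre, nbrs in sorted(adj.items()):
        ns = sorted(nbrs)
        for i in range(len(ns)):
            for j in range(i + 1, len(ns)):
                entry.angles.append(
                    AngleTemplate(ns[i], centre, ns[j],
                                  angle_deg(pos[ns[i]], pos[centre], pos[ns[j]])))
    for k, quad in enumerate(chemdata.CHI_ATOMS.get(res_type, [])):
        period = chemdata.CHI_PERIODS[res_type][k]
        entry.torsions.append(
            TorsionTemplate(f"chi{k + 1}", *quad,
                            dihedral_deg(*(pos[a] for a in quad)),
                            SIGMA_TORSION, period))
    for i, plane_atoms in enumerate(chemdata.SIDECHAIN_PLANES.get(res_type, [])):
        entry.planes.append(PlaneTemplate(f"plane{i + 1}", tuple(plane_atoms)))
    for centre, n1, n2, n3 in chemdata.CHIRAL_CENTRES.get(res_type, []):
        u1, u2, u3 = (pos[x] - pos[centre] for x in (n1, n2, n3))
        vol = float(np.dot(u1, np.cross(u2, u3)))
        entry.chirals.append(ChiralTemplate(centre, n1, n2, n3, vol))
    return entry


_DEFAULT: MonomerDictionary | None = None


def default_dictionary() -> MonomerDictionary:
    """The embedded dictionary: 20 amino acids plus the shipped toy ligand."""
    global _DEFAULT
    if _DEFAULT is None:
        d = MonomerDictionary()
        for res_type in sorted(chemdata.STANDARD_AA):
            d.add(_entry_from_measurement(res_type))
        d = d.merge(read_mmcif_dictionary(toy_ligand_path()))
        _DEFAULT = d
    return _DEFAULT


def toy_ligand_path() -> Path:
    return Path(resources.files("rsfit") / "data" / "toy_ligand.cif")


# ---------------------------------------------------------------------------
# mmCIF restraint-dictionary I/O

def read_mmcif_dictionary(path) -> MonomerDictionary:
    """Read an mmCIF restraint dictionary (CCP4 monomer-library dialect)."""
    doc = gemmi.cif.read(str(path))
    out = MonomerDictionary()
    for block in doc:
        comp_ids = set(block.find_values("_chem_comp_atom.comp_id"))
        if not comp_ids:
            continue
        for comp in sorted(comp_ids):
            entry = _read_block_component(block, comp)
            if entry.atoms:
                out.add(entry)
    return out


def _rows(block, prefix, tags):
    table = block.find(prefix, tags)
    return [list(row) for row in table] if table else []


def _read_block_component(block, comp: str) -> MonomerEntry:
    entry = MonomerEntry(comp, {})
    for row in _rows(block, "_chem_comp_atom.",
                     ["comp_id", "atom_id", "type_symbol"]):
        if row[0] == comp:
            entry.atoms[row[1]] = row[2].upper()
    for row in _rows(block, "_chem_comp_bond.",
                     ["comp_id", "atom_id_1", "atom_id_2",
                      "value_dist", "value_dist_esd"]):
        if row[0] == comp:
            entry.bonds.append(
                BondTemplate(row[1], row[2], float(row[3]), float(row[4])))
    for row in _rows(block, "_chem_comp_angle.",
                     ["comp_id", "atom_id_1", "atom_id_2", "atom_id_3",
                      "value_angle", "value_angle_esd"]):
        if row[0] == comp:
            entry.angles.append(
                AngleTemplate(row[1], row[2], row[3], float(row[4]), float(row[5])))
    for row in _rows(block, "_chem_comp_tor.",
                     ["comp_id", "id", "atom_id_1", "atom_id_2", "atom_id_3",
                      "atom_id_4", "value_angle", "value_angle_esd", "period"]):
        if row[0] == comp:
            entry.torsions.append(
                TorsionTemplate(row[1], row[2], row[3], row[4], row[5],
                                float(row[6]), float(row[7]), int(row[8])))
    plane_rows = _rows(block, "_chem_comp_plane_atom.",
                       ["comp_id", "plane_id", "atom_id", "dist_esd"])
    planes: dict[str, list] = {}
    sigmas: dict[str, float] = {}
    for row in plane_rows:
        if row[0] == comp:
            planes.setdefault(row[1], []).append(row[2])
            sigmas[row[1]] = float(row[3])
    for pid, atoms in sorted(planes.items()):
        entry.planes.append(PlaneTemplate(pid, tuple(atoms), sigmas[pid]))
    for row in _rows(block, "_chem_comp_chir.",
                     ["comp_id", "atom_id_centre", "atom_id_1", "atom_id_2",
                      "atom_id_3", "volume_sign"]):
        if row[0] == comp:
            sign = row[5].lower()
            if sign in ("positiv", "positive"):
                vol = 2.5
            elif sign in ("negativ", "negative"):
                vol = -2.5
            else:
                vol = float(row[5])
            entry.chirals.append(
                ChiralTemplate(row[1], row[2], row[3], row[4], vol))
    return entry


def write_mmcif_dictionary(dictionary: MonomerDictionary, path) -> None:
    """Write entries in the same mmCIF dialect the reader consumes."""
    doc = gemmi.cif.Document()
    for name, entry in sorted(dictionary.entries.items()):
        block = doc.add_new_block(f"comp_{name}")
        loop = block.init_loop("_chem_comp_atom.", ["comp_id", "atom_id", "type_symbol"])
        for atom, el in entry.atoms.items():
            loop.add_row([name, atom, el])
        if entry.bonds:
            loop = block.init_loop("_chem_comp_bond.",
                                   ["comp_id", "atom_id_1", "atom_id_2",
                                    "value_dist", "value_dist_esd"])
            for b in entry.bonds:
                loop.add_row([name, b.a1, b.a2, f"{b.target:.4f}", f"{b.sigma:.3f}"])
        if entry.angles:
            loop = block.init_loop("_chem_comp_angle.",
                                   ["comp_id", "atom_id_1", "atom_id_2",
                                    "atom_id_3", "value_angle", "value_angle_esd"])
            for a in entry.angles:
                loop.add_row([name, a.a1, a.a2, a.a3,
                              f"{a.target:.3f}", f"{a.sigma:.2f}"])
        if entry.torsions:
            loop = block.init_loop("_chem_comp_tor.",
                                   ["comp_id", "id", "atom_id_1", "atom_id_2",
                                    "atom_id_3", "atom_id_4", "value_angle",
                                    "value_angle_esd", "period"])
            for t in entry.torsions:
                loop.add_row([name, t.name, t.a1, t.a2, t.a3, t.a4,
                              f"{t.target:.3f}", f"{t.sigma:.2f}", str(t.period)])
        if entry.planes:
            loop = block.init_loop("_chem_comp_plane_atom.",
                                   ["comp_id", "plane_id", "atom_id", "dist_esd"])
            for p in entry.planes:
                for atom in p.atoms:
                    loop.add_row([name, p.name, atom, f"{p.sigma:.3f}"])
        if entry.chirals:
            loop = block.init_loop("_chem_comp_chir.",
                                   ["comp_id", "atom_id_centre", "atom_id_1",
                                    "atom_id_2", "atom_id_3", "volume_sign"])
            for c in entry.chirals:
                loop.add_row([name, c.centre, c.n1, c.n2, c.n3, f"{c.volume:.4f}"])
    doc.write_file(str(path))
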