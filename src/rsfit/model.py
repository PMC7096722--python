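"""Macromolecular model hierarchy, atom selection and PDB/mmCIF I/O.

The in-memory model is a light three-level hierarchy (Structure -> chains of
Residue -> Atom) holding exactly what the fitting and validation algorithms
need: coordinates, occupancies, isotropic B values, altlocs and LINK
records.  File parsing and writing are delegated to gemmi; this module only
converts between gemmi's hierarchy and ours.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import gemmi

from . import chemdata

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "LinkRecord",
    "AtomSelection",
    "FormatError",
    "read_structure",
    "write_structure",
]


class FormatError(ValueError):
    """Raised when a file cannot be parsed or written in the asked format."""


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray
    occ: float = 1.0
    b: float = 20.0
    altloc: str = ""

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if not np.all(np.isfinite(self.pos)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occ <= 1.0:
            raise ValueError(f"occupancy {self.occ} outside [0, 1]")
        if self.b < 0:
            raise ValueError(f"negative B value {self.b}")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.pos.copy(), self.occ, self.b, self.altloc)


@dataclass
class Residue:
    chain_id: str
    seqnum: int
    res_type: str
    inscode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seqnum, self.inscode)

    def atom(self, name: str, altloc: str | None = None) -> Atom | None:
        for a in self.atoms:
            if a.name == name and (altloc is None or a.altloc == altloc):
                return a
        return None

    def pos(self, name: str) -> np.ndarray:
        a = self.atom(name)
        if a is None:
            raise KeyError(f"atom {name} not in {self.chain_id}/{self.seqnum} {self.res_type}")
        return a.pos

    def has_atoms(self, *names: str) -> bool:
        return all(self.atom(n) is not None for n in names)

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.seqnum, self.res_type, self.inscode,
                       [a.copy() for a in self.atoms])


@dataclass
class LinkRecord:
    atom1: tuple[str, int, str, str]  # chain, seqnum, inscode, atom name
    atom2: tuple[str, int, str, str]
    link_type: str = ""
    distance: float | None = None


@dataclass
class Structure:
    chains: list[tuple[str, list[Residue]]] = field(default_factory=list)
    links: list[LinkRecord] = field(default_factory=list)
    title: str = ""

    # -- hierarchy access ---------------------------------------------------
    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def chain(self, chain_id: str) -> list[Residue]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(f"no chain {chain_id!r}")

    def has_chain(self, chain_id: str) -> bool:
        return chain_id in self.chain_ids()

    def residues(self):
        for _cid, rs in self.chains:
            yield from rs

    def atoms(self):
        for r in self.residues():
            yield from r.atoms

    def residue(self, chain_id: str, seqnum: int, inscode: str = "") -> Residue | None:
        if not self.has_chain(chain_id):
            return None
        for r in self.chain(chain_id):
            if r.seqnum == seqnum and r.inscode == inscode:
                return r
        return None

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def n_residues(self) -> int:
        return sum(1 for _ in self.residues())

    def copy(self) -> "Structure":
        return Structure(
            [(cid, [r.copy() for r in rs]) for cid, rs in self.chains],
            copy.deepcopy(self.links),
            self.title,
        )

    def add_residue(self, res: Residue) -> None:
        for cid, rs in self.chains:
            if cid == res.chain_id:
                rs.append(res)
                rs.sort(key=lambda r: (r.seqnum, r.inscode))
                return
        self.chains.append((res.chain_id, [res]))

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms()], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, float)
        for a, p in zip(self.atoms(), xyz, strict=True):
            a.pos = p.copy()

    def sequence(self, chain_id: str) -> str:
        return "".join(
            chemdata.THREE_TO_ONE.get(r.res_type, "X") for r in self.chain(chain_id)
        )

    def validate(self) -> None:
        seen = set()
        for cid, rs in self.chains:
            nums = [(r.seqnum, r.inscode) for r in rs]
            if nums != sorted(nums):
                raise ValueError(f"chain {cid} residues not ordered by seqnum")
            for r in rs:
                key = (cid, r.seqnum, r.inscode)
                if key in seen:
                    raise ValueError(f"duplicate residue id {key}")
                seen.add(key)
                names = [(a.name, a.altloc) for a in r.atoms]
                if len(names) != len(set(names)):
                    raise ValueError(f"duplicate atom names in {key}")


# ---------------------------------------------------------------------------
# Atom selection ("//A/50-100[/CA]" dialect)

_SEL_RE = re.compile(
    r"^//(?P<chain>[^/]+)"
    r"(?:/(?P<range>\d+(?:-\d+)?)"
    r"(?:/(?P<atoms>[A-Za-z0-9',*+]+))?)?$"
)


@dataclass(frozen=True)
class AtomSelection:
    """Parsed form of the ``//CHAIN/START-END[/ATOMNAME]`` selection dialect."""

    chain: str
    start: int | None = None
    end: int | None = None
    atom_names: tuple[str, ...] | None = None

    @classmethod
    def parse(cls, raw: str) -> "AtomSelection":
        m = _SEL_RE.match(raw.strip())
        if not m:
            raise ValueError(f"unparseable atom selection {raw!r}")
        chain = m.group("chain")
        start = end = None
        if m.group("range"):
            parts = m.group("range").split("-")
            start = int(parts[0])
            end = int(parts[1]) if len(parts) == 2 else start
            if end < start:
                raise ValueError(f"inverted residue range in {raw!r}")
        atoms = None
        if m.group("atoms"):
            atoms = tuple(m.group("atoms").split("+"))
        return cls(chain, start, end, atoms)

    def format(self) -> str:
        s = f"//{self.chain}"
        if self.start is not None:
            s += f"/{self.start}-{self.end}" if self.end != self.start else f"/{self.start}"
            if self.atom_names:
                s += "/" + "+".join(self.atom_names)
        return s

    def matches_residue(self, res: Residue) -> bool:
        if res.chain_id != self.chain:
            return False
        if self.start is not None and not (self.start <= res.seqnum <= self.end):
            return False
        return True

    def matches_atom(self, res: Residue, atom: Atom) -> bool:
        if not self.matches_residue(res):
            return False
        return self.atom_names is None or atom.name in self.atom_names


def ensure_selection(sel) -> AtomSelection:
    return sel if isinstance(sel, AtomSelection) else AtomSelection.parse(str(sel))


# ---------------------------------------------------------------------------
# gemmi conversion

def _from_gemmi(st: gemmi.Structure) -> Structure:
    out = Structure(title=st.name or "")
    model = st[0]
    for ch in model:
        residues = []
        for r in ch:
            res = Residue(
                chain_id=ch.name,
                seqnum=r.seqid.num,
                res_type=r.name,
                inscode=(r.seqid.icode or "").strip(),
            )
            for a in r:
                res.atoms.append(
                    Atom(
                        name=a.name,
                        element=a.element.name.upper(),
                        pos=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        occ=float(a.occ),
                        b=float(a.b_iso),
                        altloc=a.altloc if a.altloc != "\x00" else "",
                    )
                )
            residues.append(res)
        if residues:
            out.chains.append((ch.name, residues))
    for con in st.connections:
        p1, p2 = con.partner1, con.partner2
        out.links.append(
            LinkRecord(
                atom1=(p1.chain_name, p1.res_id.seqid.num,
                       (p1.res_id.seqid.icode or "").strip(), p1.atom_name),
                atom2=(p2.chain_name, p2.res_id.seqid.num,
                       (p2.res_id.seqid.icode or "").strip(), p2.atom_name),
                link_type=str(con.type).split(".")[-1],
                distance=con.reported_distance if con.reported_distance > 0 else None,
            )
        )
    return out


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.title
    model = gemmi.Model("1")
    for cid, residues in s.chains:
        chain = gemmi.Chain(cid)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = r.res_type
            gr.seqid = gemmi.SeqId(r.seqnum, r.inscode or " ")
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element.capitalize())
                ga.pos = gemmi.Position(*a.pos)
                ga.occ = a.occ
                ga.b_iso = a.b
                if a.altloc:
                    ga.altloc = a.altloc
                gr.add_atom(ga)
            chain.add_residue(gr)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()

    def address(endpoint):
        chain_id, seqnum, inscode, atom_name = endpoint
        addr = gemmi.AtomAddress()
        addr.chain_name, addr.atom_name = chain_id, atom_name
        addr.res_id = gemmi.ResidueId()
        addr.res_id.seqid = gemmi.SeqId(seqnum, inscode or " ")
        res = s.residue(chain_id, seqnum, inscode)
        if res is not None:
            addr.res_id.name = res.res_type
        return addr

    for i, link in enumerate(s.links):
        con = gemmi.Connection()
        con.name = f"link{i + 1}"
        con.type = gemmi.ConnectionType.Covale
        con.asu = gemmi.Asu.Same
        con.partner1 = address(link.atom1)
        con.partner2 = address(link.atom2)
        if link.distance:
            con.reported_distance = link.distance
        st.connections.append(con)
    return st


def _infer_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def read_structure(path, fmt: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise FormatError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    out = _from_gemmi(st)
    if out.n_atoms() == 0:
        raise FormatError(f"{path}: no atoms found (empty or not a {fmt} file)")
    return out


def write_structure(s: Structure, path, fmt: str = "auto") -> None:
    """Write a :class:`Structure` as PDB or mmCIF."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "pdb":
        for cid in s.chain_ids():
            if len(cid) > 2:
                raise FormatError(
                    f"chain id {cid!r} does not fit PDB columns; write mmCIF instead")
    st = _to_gemmi(s)
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise FormatError(f"unknown format {fmt!r}")


def resolve_link_atom(s: Structure, endpoint: tuple[str, int, str, str]) -> Atom | None:
    chain, seqnum, inscode, name = endpoint
    res = s.residue(chain, seqnum, inscode)
    if res is None:
        return None
    return res.atom(name)
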