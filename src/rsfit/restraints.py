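"""Restraint generation and torsion-flip editing.

Restraints reference atoms by key ``(chain_id, seqnum, inscode, atom_name)``
so a RestraintSet stays valid while coordinates move.  The refinement
engine compiles a RestraintSet against a Structure into flat index arrays.

Classes generated here:

* dictionary geometry (bonds, angles, torsions, planes, chirals) plus
  peptide links between consecutive residues;
* nonbonded repulsion pairs (1-2/1-3/1-4 and metal-linked pairs excluded);
* self local distance restraints with the bounded Geman-McClure loss
  rho(z) = z^2 / (1 + alpha z^2), which is harmonic for small deviations
  and saturates at 1/alpha, so a few bad pairs cannot dominate;
* metal coordination bonds derived from LINK records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import chemdata
from .dictionary import (
    MonomerDictionary,
    PEPTIDE_LINK,
    TorsionTemplate,
    default_dictionary,
)
from .geometry import rotation_about_axis, wrap_degrees
from .model import Structure, ensure_selection

__all__ = [
    "AtomKey",
    "BondRestraint",
    "AngleRestraint",
    "TorsionRestraint",
    "PlaneRestraint",
    "ChiralRestraint",
    "NonbondedPair",
    "GMDistanceRestraint",
    "RestraintSet",
    "build_standard_restraints",
    "generate_self_gm_restraints",
    "gm_residual",
    "metal_link_restraints",
    "torsion_flip_deltas",
    "apply_jed_flip",
    "covalent_graph",
    "DEFAULT_GM_ALPHA",
    "DEFAULT_GM_SIGMA",
    "DEFAULT_GM_LIMIT",
]

AtomKey = tuple  # (chain_id, seqnum, inscode, atom_name)

# Geman-McClure defaults for self restraints; the limit follows common
# practice for side-chain-complete models (4.2 A), with 6-7 A recommended
# when longer-range coupling is wanted.  sigma reflects the positional
# uncertainty of a start model at the domain-fitting stage (a few tenths of
# an angstrom), not coordinate precision: a much smaller sigma makes the
# self restraints anchor refinement to the start model's errors.
DEFAULT_GM_ALPHA = 0.01
DEFAULT_GM_SIGMA = 0.3
DEFAULT_GM_LIMIT = 4.2

# nonbonded contact model: r_min = scale * (vdw_i + vdw_j), with a deeper
# reduction for potential hydrogen-bond partner pairs (N/O with N/O)
NB_SCALE = 0.85
NB_HBOND_SCALE = 0.80
NB_CUTOFF = 4.0


@dataclass(frozen=True)
class BondRestraint:
    atoms: tuple[AtomKey, AtomKey]
    target: float
    sigma: float


@dataclass(frozen=True)
class AngleRestraint:
    atoms: tuple[AtomKey, AtomKey, AtomKey]
    target: float
    sigma: float


@dataclass(frozen=True)
class TorsionRestraint:
    atoms: tuple[AtomKey, AtomKey, AtomKey, AtomKey]
    target: float
    sigma: float
    period: int = 1


@dataclass(frozen=True)
class PlaneRestraint:
    atoms: tuple[AtomKey, ...]
    sigma: float


@dataclass(frozen=True)
class ChiralRestraint:
    atoms: tuple[AtomKey, AtomKey, AtomKey, AtomKey]  # centre, n1, n2, n3
    volume: float
    sigma: float


@dataclass(frozen=True)
class NonbondedPair:
    atoms: tuple[AtomKey, AtomKey]
    r_min: float


@dataclass(frozen=True)
class GMDistanceRestraint:
    atoms: tuple[AtomKey, AtomKey]
    target: float
    sigma: float = DEFAULT_GM_SIGMA
    alpha: float = DEFAULT_GM_ALPHA


@dataclass
class RestraintSet:
    bonds: list[BondRestraint] = field(default_factory=list)
    angles: list[AngleRestraint] = field(default_factory=list)
    torsions: list[TorsionRestraint] = field(default_factory=list)
    planes: list[PlaneRestraint] = field(default_factory=list)
    chirals: list[ChiralRestraint] = field(default_factory=list)
    nonbonded: list[NonbondedPair] = field(default_factory=list)
    gm: list[GMDistanceRestraint] = field(default_factory=list)

    def extend(self, other: "RestraintSet") -> None:
        for name in ("bonds", "angles", "torsions", "planes", "chirals",
                     "nonbonded", "gm"):
            getattr(self, name).extend(getattr(other, name))

    def counts(self) -> dict[str, int]:
        return {
            name: len(getattr(self, name))
            for name in ("bonds", "angles", "torsions", "planes", "chirals",
                         "nonbonded", "gm")
        }


def _akey(res, name) -> AtomKey:
    return (res.chain_id, res.seqnum, res.inscode, name)


def _consecutive(r1, r2) -> bool:
    """Peptide-bonded: adjacent in the chain list with both C and N present."""
    return (
        r1.chain_id == r2.chain_id
        and r1.atom("C") is not None
        and r2.atom("N") is not None
        and r1.res_type in chemdata.STANDARD_AA
        and r2.res_type in chemdata.STANDARD_AA
    )


def _selected_residues(s: Structure, sel):
    if sel is None:
        return list(s.residues())
    sel = ensure_selection(sel)
    return [r for r in s.residues() if sel.matches_residue(r)]


def build_standard_restraints(
    s: Structure,
    dictionary: MonomerDictionary | None = None,
    sel=None,
    nb_cutoff: float = NB_CUTOFF,
    suppressed_pairs: set[frozenset] | None = None,
) -> RestraintSet:
    """Dictionary geometry + peptide links + nonbonded pairs for a selection.

    ``suppressed_pairs`` (frozensets of AtomKeys) are skipped by the
    nonbonded generator; metal-link pairs are suppressed automatically.
    """
    dictionary = dictionary or default_dictionary()
    out = RestraintSet()
    residues = _selected_residues(s, sel)
    if not residues:
        raise ValueError("selection matches no residues")
    for res in residues:
        entry = dictionary.entry(res.res_type)
        present = {a.name for a in res.atoms}
        for b in entry.bonds:
            if b.a1 in present and b.a2 in present:
                out.bonds.append(
                    BondRestraint((_akey(res, b.a1), _akey(res, b.a2)),
                                  b.target, b.sigma))
        for a in entry.angles:
            if all(x in present for x in (a.a1, a.a2, a.a3)):
                out.angles.append(
                    AngleRestraint((_akey(res, a.a1), _akey(res, a.a2),
                                    _akey(res, a.a3)), a.target, a.sigma))
        for t in entry.torsions:
            if all(x in present for x in (t.a1, t.a2, t.a3, t.a4)):
                out.torsions.append(
                    TorsionRestraint((_akey(res, t.a1), _akey(res, t.a2),
                                      _akey(res, t.a3), _akey(res, t.a4)),
                                     t.target, t.sigma, t.period))
        for p in entry.planes:
            if all(x in present for x in p.atoms):
                out.planes.append(
                    PlaneRestraint(tuple(_akey(res, x) for x in p.atoms), p.sigma))
        for c in entry.chirals:
            if all(x in present for x in (c.centre, c.n1, c.n2, c.n3)):
                out.chirals.append(
                    ChiralRestraint((_akey(res, c.centre), _akey(res, c.n1),
                                     _akey(res, c.n2), _akey(res, c.n3)),
                                    c.volume, c.sigma))
    # peptide links between residues consecutive in each chain
    by_chain: dict[str, list] = {}
    for r in residues:
        by_chain.setdefault(r.chain_id, []).append(r)
    link_bonds: list[tuple[AtomKey, AtomKey]] = []
    for chain_residues in by_chain.values():
        for r1, r2 in zip(chain_residues, chain_residues[1:]):
            if not _consecutive(r1, r2):
                continue
            lb = PEPTIDE_LINK["bond"]
            out.bonds.append(
                BondRestraint((_akey(r1, "C"), _akey(r2, "N")), lb.target, lb.sigma))
            link_bonds.append((_akey(r1, "C"), _akey(r2, "N")))
            for ang in PEPTIDE_LINK["angles"]:
                mapping = {"CA": r1, "C": r1, "O": r1, "N": r2}
                if ang.a3 == "CA":  # C-N-CA angle: CA of the next residue
                    keys = (_akey(r1, "C"), _akey(r2, "N"), _akey(r2, "CA"))
                else:
                    keys = tuple(_akey(mapping[x], x) for x in (ang.a1, ang.a2, ang.a3))
                out.angles.append(AngleRestraint(keys, ang.target, ang.sigma))
            tw = PEPTIDE_LINK["torsion"]
            if r1.has_atoms("CA", "C") and r2.has_atoms("N", "CA"):
                out.torsions.append(
                    TorsionRestraint((_akey(r1, "CA"), _akey(r1, "C"),
                                      _akey(r2, "N"), _akey(r2, "CA")),
                                     tw.target, tw.sigma, tw.period))
            if r1.has_atoms("CA", "C", "O") and r2.has_atoms("N", "CA"):
                out.planes.append(
                    PlaneRestraint((_akey(r1, "CA"), _akey(r1, "C"),
                                    _akey(r1, "O"), _akey(r2, "N"),
                                    _akey(r2, "CA")), PEPTIDE_LINK["plane"].sigma))
    # metal links: bond restraints + pair suppression
    metal_bonds, metal_suppressed = metal_link_restraints(s)
    out.bonds.extend(metal_bonds)
    suppress = set(suppressed_pairs or ())
    suppress.update(metal_suppressed)
    out.nonbonded = _nonbonded_pairs(s, residues, out, link_bonds,
                                     nb_cutoff, suppress)
    return out


def _nonbonded_pairs(s, residues, restraint_set, link_bonds, cutoff, suppress):
    keys, xyz, elements = [], [], []
    for r in residues:
        for a in r.atoms:
            keys.append(_akey(r, a.name))
            xyz.append(a.pos)
            elements.append(a.element)
    xyz = np.asarray(xyz)
    index = {k: i for i, k in enumerate(keys)}
    # covalent adjacency from already-generated bond restraints
    adj: dict[int, set[int]] = {i: set() for i in range(len(keys))}
    for b in restraint_set.bonds:
        k1, k2 = b.atoms
        if k1 in index and k2 in index:
            adj[index[k1]].add(index[k2])
            adj[index[k2]].add(index[k1])
    excluded = set()
    for i, nbrs in adj.items():
        for j in nbrs:
            excluded.add(frozenset((i, j)))          # 1-2
            for k in adj[j]:
                if k != i:
                    excluded.add(frozenset((i, k)))  # 1-3
                    for l in adj[k]:
                        if l not in (i, j):
                            excluded.add(frozenset((i, l)))  # 1-4
    tree = cKDTree(xyz)
    out = []
    for i, j in sorted(tree.query_pairs(cutoff)):
        if frozenset((i, j)) in excluded:
            continue
        if frozenset((keys[i], keys[j])) in suppress:
            continue
        e1, e2 = elements[i].upper(), elements[j].upper()
        scale = NB_HBOND_SCALE if e1 in ("N", "O") and e2 in ("N", "O") else NB_SCALE
        r_min = scale * (chemdata.vdw_radius(e1) + chemdata.vdw_radius(e2))
        out.append(NonbondedPair((keys[i], keys[j]), r_min))
    return out


# ---------------------------------------------------------------------------
# Geman-McClure self restraints

def gm_residual(d: float, r: GMDistanceRestraint) -> tuple[float, float]:
    """Energy and d(energy)/d(distance) of a GM restraint at distance ``d``.

    z = (d - target)/sigma; rho = z^2/(1 + alpha z^2).  alpha = 0 recovers
    the harmonic z^2; for alpha > 0 the loss is bounded by 1/alpha.
    """
    if r.sigma <= 0:
        raise ValueError("sigma must be positive")
    z = (d - r.target) / r.sigma
    denom = 1.0 + r.alpha * z * z
    energy = z * z / denom
    grad = 2.0 * z / (denom * denom * r.sigma)
    return float(energy), float(grad)


def generate_self_gm_restraints(
    s: Structure,
    sel=None,
    limit: float = DEFAULT_GM_LIMIT,
    alpha: float = DEFAULT_GM_ALPHA,
    sigma: float = DEFAULT_GM_SIGMA,
    dictionary: MonomerDictionary | None = None,
) -> list[GMDistanceRestraint]:
    """One GM restraint per atom pair within ``limit`` A, target = current
    distance; 1-2 and 1-3 covalently bonded pairs are skipped."""
    if limit <= 0:
        raise ValueError("limit must be positive")
    residues = _selected_residues(s, sel)
    if not residues:
        raise ValueError("selection matches no residues")
    graph = covalent_graph(s, dictionary, residues=residues)
    keys, xyz = [], []
    for r in residues:
        for a in r.atoms:
            keys.append(_akey(r, a.name))
            xyz.append(a.pos)
    xyz = np.asarray(xyz)
    near = {}
    for k in keys:
        nbrs = graph.get(k, set())
        second = set()
        for n in nbrs:
            second |= graph.get(n, set())
        near[k] = (nbrs | second) - {k}
    tree = cKDTree(xyz)
    out = []
    for i, j in sorted(tree.query_pairs(limit)):
        if keys[j] in near[keys[i]]:
            continue
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        out.append(GMDistanceRestraint((keys[i], keys[j]), d, sigma, alpha))
    return out


# ---------------------------------------------------------------------------
# Metal link restraints

def metal_link_restraints(s: Structure):
    """Bond restraints for metal LINKs to N/O/S ligand atoms.

    Returns (bonds, suppressed) where suppressed holds the atom-key pairs
    that must be dropped from nonbonded generation.
    """
    from .model import resolve_link_atom

    bonds, suppressed = [], set()
    for link in s.links:
        a1 = resolve_link_atom(s, link.atom1)
        a2 = resolve_link_atom(s, link.atom2)
        if a1 is None or a2 is None:
            warnings.warn(
                f"dangling LINK {link.atom1} - {link.atom2}; skipped",
                stacklevel=2)
            continue
        e1, e2 = a1.element.upper(), a2.element.upper()
        if e1 in chemdata.METAL_ELEMENTS and e2 in ("N", "O", "S"):
            metal, ligand = e1, e2
            k_metal, k_lig = tuple(link.atom1), tuple(link.atom2)
        elif e2 in chemdata.METAL_ELEMENTS and e1 in ("N", "O", "S"):
            metal, ligand = e2, e1
            k_metal, k_lig = tuple(link.atom2), tuple(link.atom1)
        else:
            continue
        target = chemdata.METAL_BOND_TABLE.get(
            (metal, ligand), chemdata.DEFAULT_METAL_BOND)
        bonds.append(BondRestraint((k_metal, k_lig), target, 0.05))
        suppressed.add(frozenset((k_metal, k_lig)))
    return bonds, suppressed


# ---------------------------------------------------------------------------
# Torsion flips

def torsion_flip_deltas(t: TorsionRestraint | TorsionTemplate) -> list[float]:
    """Flip deltas implied by a torsion restraint's periodicity.

    All nonzero multiples of 360/period mapped into (-180, 180], without
    duplicates; period 1 falls back to the plain 180 degree flip.
    """
    period = int(t.period)
    if period < 1:
        raise ValueError("period must be >= 1")
    if period == 1:
        return [180.0]
    step = 360.0 / period
    deltas = []
    for k in range(1, period):
        d = round(wrap_degrees(k * step), 9)
        if abs(d) < 1e-9:
            continue
        if not any(abs(d - e) < 1e-9 for e in deltas):
            deltas.append(float(d))
    return sorted(deltas, key=lambda x: (abs(x), -x))


def covalent_graph(
    s: Structure,
    dictionary: MonomerDictionary | None = None,
    residues=None,
) -> dict[AtomKey, set[AtomKey]]:
    """Adjacency over atom keys: dictionary bonds + peptide links + LINKs."""
    dictionary = dictionary or default_dictionary()
    residues = list(residues) if residues is not None else list(s.residues())
    graph: dict[AtomKey, set[AtomKey]] = {}

    def connect(k1, k2):
        graph.setdefault(k1, set()).add(k2)
        graph.setdefault(k2, set()).add(k1)

    for r in residues:
        present = {a.name for a in r.atoms}
        for a in r.atoms:
            graph.setdefault(_akey(r, a.name), set())
        if r.res_type in dictionary:
            for a1, a2 in dictionary.entry(r.res_type).bond_pairs():
                if a1 in present and a2 in present:
                    connect(_akey(r, a1), _akey(r, a2))
    by_chain: dict[str, list] = {}
    for r in residues:
        by_chain.setdefault(r.chain_id, []).append(r)
    for chain_residues in by_chain.values():
        for r1, r2 in zip(chain_residues, chain_residues[1:]):
            if _consecutive(r1, r2):
                connect(_akey(r1, "C"), _akey(r2, "N"))
    resid_set = {r.id for r in residues}
    for link in s.links:
        k1, k2 = tuple(link.atom1), tuple(link.atom2)
        if k1[:3] in resid_set and k2[:3] in resid_set:
            connect(k1, k2)
    return graph


def apply_jed_flip(
    s: Structure,
    bond: tuple[AtomKey, AtomKey],
    delta: float,
    reverse: bool = False,
    dictionary: MonomerDictionary | None = None,
) -> Structure:
    """Rotate one side of a rotatable bond by ``delta`` degrees.

    By default the smaller of the two fragments produced by cutting the
    bond moves; ``reverse`` moves the larger one.  A bond inside a ring
    (the cut does not disconnect the graph) is refused.
    """
    k1, k2 = tuple(bond[0]), tuple(bond[1])
    graph = covalent_graph(s, dictionary)
    if k1 not in graph or k2 not in graph:
        raise KeyError(f"bond atoms {k1} / {k2} not found in the model")
    if k2 not in graph[k1]:
        raise ValueError(f"{k1} and {k2} are not covalently bonded")

    def component(start, banned_edge):
        seen = {start}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nb in graph[cur]:
                if frozenset((cur, nb)) == banned_edge or nb in seen:
                    continue
                seen.add(nb)
                stack.append(nb)
        return seen

    edge = frozenset((k1, k2))
    side2 = component(k2, edge)
    if k1 in side2:
        raise ValueError("bond is part of a ring; flip refused")
    side1 = component(k1, edge)
    moving = side2 if len(side2) <= len(side1) else side1
    if reverse:
        moving = side1 if moving is side2 else side2

    out = s.copy()
    p1 = _atom_by_key(out, k1).pos
    p2 = _atom_by_key(out, k2).pos
    R, t = rotation_about_axis(p1, p2 - p1, delta)
    for key in moving:
        atom = _atom_by_key(out, key)
        atom.pos = R @ atom.pos + t
    return out


def _atom_by_key(s: Structure, key: AtomKey):
    chain, seqnum, inscode, name = key
    res = s.residue(chain, seqnum, inscode)
    if res is None:
        raise KeyError(f"no residue {chain}/{seqnum}{inscode}")
    atom = res.atom(name)
    if atom is None:
        raise KeyError(f"no atom {name} in {chain}/{seqnum}{inscode}")
    return atom
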