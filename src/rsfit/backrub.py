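"""Backrub-based side-chain fitting against density.

The backrub move rotates a small rigid set of atoms — the central residue
plus the C and O of the preceding residue and the N of the following one —
about the axis joining the flanking C-alpha atoms.  Because N, CA and C of
the central residue move rigidly, its tau (N-CA-C) angle is exactly
preserved, and the flanking residues see only small tau changes; this is
what lets side chains be repositioned in low-resolution maps without
wrecking the main chain, where a free rigid-body fit of the residue would
distort it.

For each backrub angle, every rotamer of the residue type is built by
internal coordinates on the moved backbone; hypotheses are scored by
density fit minus a clash penalty, and the best one replaces the model only
if it beats the current atoms' score.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from . import chemdata
from .densmap import CubicMapInterpolator, DensityMap
from .geometry import angle_deg, rotation_about_axis
from .model import Atom, Residue, Structure

__all__ = [
    "Rotamer",
    "RotamerLibrary",
    "BackrubError",
    "backrub_axis",
    "generate_backrub_hypotheses",
    "place_rotamer_side_chain",
    "clash_score",
    "backrub_rotamer_fit",
]


class BackrubError(ValueError):
    pass


@dataclass(frozen=True)
class Rotamer:
    res_type: str
    name: str
    probability: float
    chis: tuple[float, ...]


class RotamerLibrary:
    """Named chi-angle sets with prior probabilities per residue type."""

    def __init__(self, rotamers: dict[str, list[Rotamer]]):
        self._rotamers = rotamers
        for res_type, rots in rotamers.items():
            expected = chemdata.n_chis(res_type)
            for r in rots:
                if len(r.chis) != expected:
                    raise ValueError(
                        f"{res_type} rotamer {r.name}: {len(r.chis)} chis, "
                        f"expected {expected}")
            total = sum(r.probability for r in rots)
            if total > 1.0 + 1e-6:
                raise ValueError(f"{res_type} probabilities sum to {total} > 1")

    _default: "RotamerLibrary | None" = None

    @classmethod
    def load_default(cls) -> "RotamerLibrary":
        if cls._default is None:
            path = resources.files("rsfit") / "data" / "rotamers.tsv"
            cls._default = cls.from_tsv(path)
        return cls._default

    @classmethod
    def from_tsv(cls, path) -> "RotamerLibrary":
        rotamers: dict[str, list[Rotamer]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                res_type, name, prob = parts[0], parts[1], float(parts[2])
                chis = tuple(float(x) for x in parts[3:])
                rotamers.setdefault(res_type, []).append(
                    Rotamer(res_type, name, prob, chis))
        for rots in rotamers.values():
            rots.sort(key=lambda r: -r.probability)
        return cls(rotamers)

    def rotamers(self, res_type: str) -> list[Rotamer]:
        return list(self._rotamers.get(res_type, []))

    def has(self, res_type: str) -> bool:
        return bool(self._rotamers.get(res_type))

    def residue_types(self) -> list[str]:
        return sorted(self._rotamers)


# ---------------------------------------------------------------------------
# Backrub motion

def _chain_neighbours(s: Structure, res: Residue):
    chain = s.chain(res.chain_id)
    i = chain.index(res)
    prev_res = chain[i - 1] if i > 0 else None
    next_res = chain[i + 1] if i + 1 < len(chain) else None
    return prev_res, next_res


def backrub_axis(s: Structure, res: Residue):
    """Axis through CA(i-1) toward CA(i+1); raises at chain termini."""
    prev_res, next_res = _chain_neighbours(s, res)
    if prev_res is None or next_res is None:
        raise BackrubError(
            f"residue {res.chain_id}/{res.seqnum} has no flanking residues; "
            "backrub undefined at chain termini")
    if not (prev_res.has_atoms("CA") and next_res.has_atoms("CA")):
        raise BackrubError("flanking residues lack C-alpha atoms")
    p0 = prev_res.pos("CA")
    p1 = next_res.pos("CA")
    d = p1 - p0
    return p0, d / np.linalg.norm(d)


def _moving_atoms(s: Structure, res: Residue):
    """The backrub moving set: residue i, C+O of i-1, N of i+1."""
    prev_res, next_res = _chain_neighbours(s, res)
    moving = [(res, a) for a in res.atoms]
    for name in ("C", "O"):
        a = prev_res.atom(name)
        if a is not None:
            moving.append((prev_res, a))
    a = next_res.atom("N")
    if a is not None:
        moving.append((next_res, a))
    return moving


def generate_backrub_hypotheses(
    s: Structure,
    res: Residue,
    angle_range: float = 10.0,
    n_steps: int = 21,
    back_rotate_peptides: bool = True,
):
    """Rigid rotations of the moving set over [-angle_range, +angle_range].

    Returns a list of (angle, positions) where positions maps (residue id,
    atom name) -> new position.  With ``back_rotate_peptides``, each
    flanking peptide is counter-rotated about its own CA-CA vector to bring
    the peptide O (and the next N) back toward the unmoved positions,
    reducing the strain the main rotation puts on the neighbours.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    axis_point, axis_dir = backrub_axis(s, res)
    moving = _moving_atoms(s, res)
    prev_res, next_res = _chain_neighbours(s, res)
    angles = np.linspace(-angle_range, angle_range, n_steps)
    out = []
    for ang in angles:
        R, t = rotation_about_axis(axis_point, axis_dir, ang)
        pos = {(r.id, a.name): R @ a.pos + t for r, a in moving}
        if back_rotate_peptides and abs(ang) > 1e-9:
            _back_rotate(pos, s, res, prev_res, next_res)
        out.append((float(ang), pos))
    return out


def _back_rotate(pos, s, res, prev_res, next_res):
    """Counter-rotate each flanking peptide about its CA-CA vector so the
    carbonyl O (previous peptide) / amide N (next peptide) return as close
    as possible to their original positions."""
    # previous peptide: rotate moved C,O of residue i-1 about CA(i-1)->CA(i)
    ca_prev = prev_res.pos("CA")
    ca_i = pos[(res.id, "CA")]
    o_orig = prev_res.atom("O")
    if o_orig is not None and (prev_res.id, "O") in pos:
        ang = _optimal_back_angle(
            ca_prev, ca_i - ca_prev, pos[(prev_res.id, "O")], o_orig.pos)
        R, t = rotation_about_axis(ca_prev, ca_i - ca_prev, ang)
        for name in ("C", "O"):
            key = (prev_res.id, name)
            if key in pos:
                pos[key] = R @ pos[key] + t
    # next peptide: rotate moved N of residue i+1 about CA(i)->CA(i+1)
    n_orig = next_res.atom("N")
    if n_orig is not None and (next_res.id, "N") in pos:
        ca_next = next_res.pos("CA")
        ang = _optimal_back_angle(
            ca_i, ca_next - ca_i, pos[(next_res.id, "N")], n_orig.pos)
        R, t = rotation_about_axis(ca_i, ca_next - ca_i, ang)
        key = (next_res.id, "N")
        pos[key] = R @ pos[key] + t


def _optimal_back_angle(axis_point, axis_dir, p, target):
    """Angle about the axis that brings p closest to target (closed form)."""
    k = axis_dir / np.linalg.norm(axis_dir)
    v = p - axis_point
    w = target - axis_point
    v_perp = v - np.dot(v, k) * k
    w_perp = w - np.dot(w, k) * k
    if np.linalg.norm(v_perp) < 1e-9 or np.linalg.norm(w_perp) < 1e-9:
        return 0.0
    x = np.dot(v_perp, w_perp)
    y = np.dot(np.cross(k, v_perp), w_perp)
    return float(np.degrees(np.arctan2(y, x)))


# ---------------------------------------------------------------------------
# Rotamer placement and clash scoring

def place_rotamer_side_chain(res: Residue, rotamer: Rotamer) -> dict[str, np.ndarray]:
    """Positions for CB + side chain of ``res`` at the rotamer's chi angles.

    The backbone (N, CA, C) anchors an internal-coordinate build; measured
    chi dihedrals of the result equal the rotamer's values.
    """
    if res.res_type != rotamer.res_type:
        raise ValueError(
            f"rotamer is for {rotamer.res_type}, residue is {res.res_type}")
    if res.res_type in ("GLY",):
        raise ValueError("glycine has no side chain to place")
    backbone = {n: res.pos(n) for n in ("N", "CA", "C")}
    return chemdata.build_sidechain(backbone, res.res_type, rotamer.chis)


def clash_score(candidate_atoms, environment_atoms, exclude_pairs=None) -> float:
    """Sum over candidate-environment pairs of max(0, r_min - d)^2.

    r_min is the sum of element contact radii; ``exclude_pairs`` (sets of
    (atom name, atom name)) removes covalently bonded junction pairs.
    """
    cand = list(candidate_atoms)
    env = list(environment_atoms)
    if not cand or not env:
        return 0.0
    exclude = exclude_pairs or set()
    cand_xyz = np.array([a.pos for a in cand])
    env_xyz = np.array([a.pos for a in env])
    r_cand = np.array([chemdata.vdw_radius(a.element) for a in cand])
    r_env = np.array([chemdata.vdw_radius(a.element) for a in env])
    tree = cKDTree(env_xyz)
    total = 0.0
    rmax = r_cand.max() + r_env.max()
    for i, xyz in enumerate(cand_xyz):
        for j in tree.query_ball_point(xyz, rmax):
            if (cand[i].name, env[j].name) in exclude:
                continue
            r_min = r_cand[i] + r_env[j]
            d = np.linalg.norm(xyz - env_xyz[j])
            if d < r_min:
                total += (r_min - d) ** 2
    return float(total)


# ---------------------------------------------------------------------------
# The combined fit

def _hypothesis_score(interp, atoms_xyz, weights, cand_atoms, env_atoms,
                      w_density=1.0, w_clash=1.0, exclude=None):
    # smooth-interpolant density: the piecewise-linear interpolant peaks on
    # grid nodes, which would bias hypothesis ranking toward node-snapped
    # poses rather than the true density maximum
    vals, _g = interp.evaluate(atoms_xyz)
    dens = float(np.dot(weights, vals))
    cl = clash_score(cand_atoms, env_atoms, exclude)
    return w_density * dens - w_clash * cl


def backrub_rotamer_fit(
    s: Structure,
    res: Residue,
    density_map: DensityMap,
    library: RotamerLibrary | None = None,
    angle_range: float = 10.0,
    n_steps: int = 21,
    w_density: float = 1.0,
    w_clash: float = 1.0,
    env_radius: float = 6.0,
):
    """Fit a side chain by enumerating (backrub angle x rotamer) hypotheses.

    The score is w_density * density_fit - w_clash * clash penalty against
    nearby environment atoms (bonded junction atoms excluded; no symmetry
    mates).  The model is replaced only when the best hypothesis strictly
    beats the current conformation's score.  Returns (structure, accepted).

    At chain termini, where the backrub axis is undefined, the fit falls
    back to rotamer enumeration on the fixed backbone.
    """
    library = library or RotamerLibrary.load_default()
    res = s.residue(res.chain_id, res.seqnum, res.inscode)
    rotamers = library.rotamers(res.res_type)
    interp = CubicMapInterpolator(density_map)

    try:
        hypotheses = generate_backrub_hypotheses(s, res, angle_range, n_steps)
    except BackrubError:
        hypotheses = [(0.0, {(res.id, a.name): a.pos.copy() for a in res.atoms
                             if a.name in chemdata.BACKBONE_ATOMS or a.name == "CB"})]

    # environment: atoms near the residue, excluding the moving set
    moving_ids = {key for _ang, pos in hypotheses[:1] for key in pos}
    centre = res.pos("CA")
    env = []
    for r in s.residues():
        for a in r.atoms:
            if (r.id, a.name) in moving_ids or r.id == res.id:
                continue
            if np.linalg.norm(a.pos - centre) < env_radius + 5.0:
                env.append(a)
    exclude = {("N", "C"), ("C", "N")}  # peptide junctions

    elements = chemdata.residue_elements(res.res_type)

    def build_candidate(pos_map, rotamer):
        """Full atom set for one hypothesis: moved backbone + side chain."""
        atoms = []
        for (rid, name), p in pos_map.items():
            if rid == res.id and name in chemdata.BACKBONE_ATOMS:
                atoms.append(Atom(name, elements[name], p))
            elif rid != res.id:
                other = s.residue(*rid)
                a0 = other.atom(name)
                atoms.append(Atom(name, a0.element, p))
        if rotamer is not None:
            bb = {n: pos_map[(res.id, n)] for n in ("N", "CA", "C")}
            side = chemdata.build_sidechain(bb, res.res_type, rotamer.chis)
            for name, p in side.items():
                atoms.append(Atom(name, elements[name], p))
        elif res.res_type != "GLY":
            bb = {n: pos_map[(res.id, n)] for n in ("N", "CA", "C")}
            side = chemdata.build_sidechain(bb, res.res_type, None)
            cb = side["CB"]
            atoms.append(Atom("CB", "C", cb))
        return atoms

    def score_atoms(atoms):
        xyz = np.array([a.pos for a in atoms])
        weights = np.array(
            [a.occ * chemdata.atomic_number(a.element) for a in atoms])
        return _hypothesis_score(interp, xyz, weights, atoms, env,
                                 w_density, w_clash, exclude)

    # score of the current model over the same atom set definition
    current_atoms = []
    prev_res, next_res = _chain_neighbours(s, res)
    current_atoms.extend(a for a in res.atoms)
    if prev_res is not None:
        current_atoms.extend(a for n in ("C", "O")
                             if (a := prev_res.atom(n)) is not None)
    if next_res is not None and next_res.atom("N") is not None:
        current_atoms.append(next_res.atom("N"))
    current_score = score_atoms(current_atoms)

    best = (current_score, None, None, None)
    rot_list = rotamers if rotamers else [None]
    for ang, pos_map in hypotheses:
        for rot in rot_list:
            cand = build_candidate(pos_map, rot)
            sc = score_atoms(cand)
            if sc > best[0]:
                best = (sc, ang, rot, (pos_map, cand))
    if best[3] is None:
        return s.copy(), False

    pos_map, cand = best[3]
    out = s.copy()
    out_res = out.residue(res.chain_id, res.seqnum, res.inscode)
    # flanking peptide atoms
    for (rid, name), p in pos_map.items():
        if rid != res.id:
            out.residue(*rid).atom(name).pos = p.copy()
    # central residue: backbone from the hypothesis, side chain from the build
    b_mean = float(np.mean([a.b for a in out_res.atoms]))
    new_atoms = []
    for a in cand:
        b = out_res.atom(a.name).b if out_res.atom(a.name) else b_mean
        occ = out_res.atom(a.name).occ if out_res.atom(a.name) else 1.0
        if any(a.name == x.name for x in new_atoms):
            continue
        is_res_atom = a.name in elements
        if is_res_atom:
            new_atoms.append(Atom(a.name, a.element, a.pos.copy(), occ, b))
    out_res.atoms = new_atoms
    return out, True
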