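"""Deterministic synthetic fixtures: ideal models and Gaussian-atom maps.

Everything in the package can be exercised without downloads: polypeptides
are built at ideal geometry by internal coordinates, and maps are
synthesised from a model as a sum of single-Gaussian atoms,

    rho(x) = sum_atoms occ * Z * exp(-|x - pos|^2 / (2 sigma^2)),

with sigma^2 = B/(8 pi^2), so map blurring and atom B values live on the
same temperature-factor scale.  The single-Gaussian atom is a deliberate
simplification of real scattering factors; it gives closed-form checks
(integrals, blur identities) and realistic-looking ~3 A density at the
default B = 40 A^2.
"""

from __future__ import annotations

import numpy as np

from . import chemdata
from .densmap import DensityMap
from .geometry import place_atom
from .model import Atom, Residue, Structure

__all__ = [
    "make_ideal_polypeptide",
    "make_toy_ligand",
    "synthesize_map",
    "perturb",
    "random_rigid_transform",
    "DEFAULT_SPACING",
    "DEFAULT_ATOM_B",
]

DEFAULT_SPACING = 0.8   # A per voxel: comfortably finer than 3 A features
DEFAULT_ATOM_B = 40.0   # A^2: a ~3 A-resolution look
DEFAULT_PADDING = 6.0   # A of margin around the model


def make_ideal_polypeptide(
    sequence: str,
    conformation: str = "helix",
    chain_id: str = "A",
    start_seqnum: int = 1,
    phi_psi: tuple[float, float] | None = None,
    b_factor: float = 20.0,
) -> Structure:
    """Build an ideal-geometry polypeptide from a one-letter sequence.

    ``conformation`` selects backbone torsions ("helix": phi,psi = -57,-47;
    "strand": -120,120), overridable with an explicit ``phi_psi``.  Side
    chains are placed at the canonical reference (top-rotamer) chi angles;
    omega is 180 (trans) throughout.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty sequence")
    for ch in sequence:
        if ch not in chemdata.ONE_TO_THREE:
            raise ValueError(f"invalid one-letter residue code {ch!r}")
    if phi_psi is None:
        if conformation not in chemdata.CONFORMATIONS:
            raise ValueError(f"unknown conformation {conformation!r}")
        phi, psi = chemdata.CONFORMATIONS[conformation]
    else:
        phi, psi = phi_psi
    bb = chemdata.BB
    residues: list[Residue] = []
    prev = None  # (N, CA, C) of the previous residue
    for i, one in enumerate(sequence):
        res_type = chemdata.ONE_TO_THREE[one]
        if prev is None:
            n = np.zeros(3)
            ca = np.array([bb["N-CA"], 0.0, 0.0])
            c = place_atom(np.array([0.0, 1.0, 0.0]), n, ca,
                           bb["CA-C"], bb["N-CA-C"], 57.0)
        else:
            pn, pca, pc = prev
            n = place_atom(pn, pca, pc, bb["C-N"], bb["CA-C-N"], psi)
            ca = place_atom(pca, pc, n, bb["N-CA"], bb["C-N-CA"], 180.0)
            c = place_atom(pc, n, ca, bb["CA-C"], bb["N-CA-C"], phi)
        o = place_atom(n, ca, c, bb["C-O"], bb["CA-C-O"], psi + 180.0)
        res = Residue(chain_id, start_seqnum + i, res_type)
        res.atoms.append(Atom("N", "N", n, 1.0, b_factor))
        res.atoms.append(Atom("CA", "C", ca, 1.0, b_factor))
        res.atoms.append(Atom("C", "C", c, 1.0, b_factor))
        res.atoms.append(Atom("O", "O", o, 1.0, b_factor))
        if res_type != "GLY":
            placed = chemdata.build_sidechain({"N": n, "CA": ca, "C": c}, res_type)
            elements = chemdata.residue_elements(res_type)
            for name, p in placed.items():
                res.atoms.append(Atom(name, elements[name], p, 1.0, b_factor))
        residues.append(res)
        prev = (n, ca, c)
    return Structure([(chain_id, residues)], title=f"ideal {conformation}")


def make_toy_ligand(chain_id: str = "L", seqnum: int = 1) -> Residue:
    """3-D coordinates for the shipped TOY ligand (meta-chloro propylbenzene)."""
    pos: dict[str, np.ndarray] = {}
    pos["C9"] = np.zeros(3)
    pos["C8"] = np.array([1.53, 0.0, 0.0])
    pos["C7"] = place_atom(np.array([0.0, 1.0, 0.0]), pos["C9"], pos["C8"],
                           1.53, 112.0, 40.0)
    pos["C1"] = place_atom(pos["C9"], pos["C8"], pos["C7"], 1.51, 112.0, 180.0)
    pos["C2"] = place_atom(pos["C8"], pos["C7"], pos["C1"], 1.39, 120.0, 90.0)
    pos["C3"] = place_atom(pos["C7"], pos["C1"], pos["C2"], 1.39, 120.0, 180.0)
    pos["C4"] = place_atom(pos["C1"], pos["C2"], pos["C3"], 1.39, 120.0, 0.0)
    pos["C5"] = place_atom(pos["C2"], pos["C3"], pos["C4"], 1.39, 120.0, 0.0)
    pos["C6"] = place_atom(pos["C3"], pos["C4"], pos["C5"], 1.39, 120.0, 0.0)
    pos["CL1"] = place_atom(pos["C1"], pos["C2"], pos["C3"], 1.74, 120.0, 180.0)
    res = Residue(chain_id, seqnum, "TOY")
    for name in ("C1", "C2", "C3", "C4", "C5", "C6", "CL1", "C7", "C8", "C9"):
        element = "CL" if name == "CL1" else "C"
        res.atoms.append(Atom(name, element, pos[name], 1.0, 20.0))
    return res


def synthesize_map(
    s: Structure,
    spacing: float = DEFAULT_SPACING,
    padding: float = DEFAULT_PADDING,
    atom_b: float = DEFAULT_ATOM_B,
    like: DensityMap | None = None,
) -> DensityMap:
    """Gaussian-atom density for a model on a padded orthogonal grid.

    ``like`` reuses an existing map's grid geometry (origin, shape, cell),
    which keeps two synthesised maps voxel-aligned for comparisons.
    """
    if s.n_atoms() == 0:
        raise ValueError("empty model")
    if spacing <= 0 or atom_b <= 0:
        raise ValueError("spacing and atom_b must be positive")
    xyz = s.coords()
    w = np.array([a.occ * chemdata.atomic_number(a.element) for a in s.atoms()])
    if like is not None:
        lo = like.origin.copy()
        shape = np.array(like.grid.shape)
        cell = tuple(like.cell)
        spacing = float(like.spacing[0])
    else:
        lo = xyz.min(axis=0) - padding
        hi = xyz.max(axis=0) + padding
        shape = np.maximum(2, np.ceil((hi - lo) / spacing).astype(int))
        cell = tuple(float(n * spacing) for n in shape)
    sigma2 = atom_b / (8.0 * np.pi ** 2)
    cut = 4.5 * np.sqrt(sigma2)  # ~1e-4 relative truncation
    grid = np.zeros(tuple(shape), dtype=float)
    axes = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
    for p, wi in zip(xyz, w):
        i_lo = np.maximum(0, np.floor((p - cut - lo) / spacing).astype(int))
        i_hi = np.minimum(shape, np.ceil((p + cut - lo) / spacing).astype(int) + 1)
        if np.any(i_lo >= i_hi):
            continue
        dx = axes[0][i_lo[0]:i_hi[0]] - p[0]
        dy = axes[1][i_lo[1]:i_hi[1]] - p[1]
        dz = axes[2][i_lo[2]:i_hi[2]] - p[2]
        g = np.exp(
            -(dx[:, None, None] ** 2 + dy[None, :, None] ** 2
              + dz[None, None, :] ** 2) / (2.0 * sigma2))
        grid[i_lo[0]:i_hi[0], i_lo[1]:i_hi[1], i_lo[2]:i_hi[2]] += wi * g
    return DensityMap(grid, cell, origin=lo)


def random_rigid_transform(
    rng: np.random.Generator,
    max_rot_deg: float,
    max_trans: float,
    pivot: np.ndarray,
):
    """Uniform random axis, rotation angle in [0, max_rot] about ``pivot``,
    translation components uniform in [-max_trans, max_trans]."""
    from .geometry import rotation_about_axis

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_rot_deg)
    R, t0 = rotation_about_axis(pivot, axis, angle)
    t = t0 + rng.uniform(-max_trans, max_trans, size=3)
    return R, t


def perturb(
    s: Structure,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    noise_A: float = 0.0,
    seed: int = 0,
) -> Structure:
    """Apply a rigid transform and/or seeded Gaussian coordinate noise."""
    out = s.copy()
    xyz = out.coords()
    if rotation is not None:
        xyz = xyz @ np.asarray(rotation, float).T
    if translation is not None:
        xyz = xyz + np.asarray(translation, float)
    if noise_A > 0:
        rng = np.random.default_rng(seed)
        xyz = xyz + rng.normal(scale=noise_A, size=xyz.shape)
    out.set_coords(xyz)
    return out
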