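"""Model validation: Ramachandran/Kleywegt analysis, rotamer probabilities,
temperature-factor statistics, per-residue density fit, ligand distortion.

The Ramachandran tables are smooth synthetic probability surfaces built
from wrapped Gaussian mixtures centred on the classical favoured regions
(alpha, beta, polyproline-II, left-handed alpha), with per-class variants
for Gly (symmetrised), Pro (phi-confined), pre-Pro and Ile/Val.  They are
peak-normalised; the preferred/allowed cutoffs are relative probabilities
and are configurable.  The surfaces reproduce the qualitative layout of
high-resolution-derived tables but are generated, not fitted to a database.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chemdata
from .densmap import DensityMap, _trilinear
from .dictionary import MonomerDictionary, default_dictionary
from .geometry import dihedral_deg, wrap_degrees
from .model import Residue, Structure, ensure_selection

__all__ = [
    "RamaTables",
    "RamaPoint",
    "KleywegtPair",
    "phi_psi",
    "rama_class",
    "rama_report",
    "kleywegt_compare",
    "rotamer_analysis",
    "b_factor_stats",
    "density_fit_graph",
    "ligand_distortion",
]

PREFERRED_MIN = 0.02
ALLOWED_MIN = 0.002
RAMA_GRID_STEP = 5.0  # degrees

RAMA_CLASSES = ("all", "general", "ile_val", "gly", "pro", "pre_pro")

# wrapped-Gaussian mixture components per class:
# (phi0, psi0, sigma_phi, sigma_psi, weight)
_RAMA_COMPONENTS = {
    "general": [
        (-63.0, -43.0, 14.0, 14.0, 0.45),   # alpha
        (-120.0, 130.0, 25.0, 25.0, 0.30),  # beta
        (-65.0, 145.0, 18.0, 18.0, 0.18),   # polyproline II
        (57.0, 42.0, 12.0, 12.0, 0.07),     # left-handed alpha
    ],
    "ile_val": [
        (-63.0, -45.0, 12.0, 12.0, 0.35),
        (-115.0, 125.0, 22.0, 22.0, 0.45),
        (-65.0, 140.0, 16.0, 16.0, 0.20),
    ],
    "gly": [
        (-63.0, -43.0, 16.0, 16.0, 0.25),
        (63.0, 43.0, 16.0, 16.0, 0.25),
        (-90.0, 170.0, 28.0, 28.0, 0.20),
        (90.0, -170.0, 28.0, 28.0, 0.20),
        (-65.0, 145.0, 20.0, 20.0, 0.10),
    ],
    "pro": [
        (-63.0, -35.0, 10.0, 14.0, 0.45),
        (-63.0, 148.0, 10.0, 16.0, 0.55),
    ],
    "pre_pro": [
        (-63.0, -43.0, 13.0, 13.0, 0.30),
        (-120.0, 130.0, 24.0, 24.0, 0.40),
        (-65.0, 145.0, 18.0, 18.0, 0.20),
        (-130.0, 75.0, 16.0, 16.0, 0.10),
    ],
}


def _wrapped_gaussian_grid(components, step):
    axis = np.arange(-180.0, 180.0, step)
    phi, psi = np.meshgrid(axis, axis, indexing="ij")
    grid = np.zeros_like(phi)
    for p0, s0, sp, ss, w in components:
        for dphi in (-360.0, 0.0, 360.0):
            for dpsi in (-360.0, 0.0, 360.0):
                grid += w * np.exp(
                    -((phi - p0 + dphi) ** 2 / (2 * sp ** 2)
                      + (psi - s0 + dpsi) ** 2 / (2 * ss ** 2)))
    return axis, grid / grid.max()


@dataclass
class RamaTables:
    """Per-class (phi, psi) relative-probability grids with cutoffs."""

    preferred_min: float = PREFERRED_MIN
    allowed_min: float = ALLOWED_MIN
    step: float = RAMA_GRID_STEP
    grids: dict = field(default_factory=dict)
    axis: np.ndarray | None = None

    def __post_init__(self):
        if not 0 < self.allowed_min < self.preferred_min:
            raise ValueError("need preferred_min > allowed_min > 0")
        if not self.grids:
            for cls in RAMA_CLASSES:
                if cls == "all":
                    continue
                self.axis, grid = _wrapped_gaussian_grid(
                    _RAMA_COMPONENTS[cls], self.step)
                self.grids[cls] = grid
            combined = (
                0.80 * self.grids["general"]
                + 0.08 * self.grids["gly"]
                + 0.05 * self.grids["pro"]
                + 0.07 * self.grids["ile_val"]
            )
            self.grids["all"] = combined / combined.max()

    def probability(self, cls: str, phi: float, psi: float) -> float:
        """Bilinear lookup with periodic wrap; peak-normalised scale."""
        grid = self.grids[cls]
        n = len(self.axis)
        fi = (wrap_degrees(phi) + 180.0) / self.step
        fj = (wrap_degrees(psi) + 180.0) / self.step
        i0, j0 = int(np.floor(fi)) % n, int(np.floor(fj)) % n
        ti, tj = fi - np.floor(fi), fj - np.floor(fj)
        i1, j1 = (i0 + 1) % n, (j0 + 1) % n
        return float(
            grid[i0, j0] * (1 - ti) * (1 - tj)
            + grid[i1, j0] * ti * (1 - tj)
            + grid[i0, j1] * (1 - ti) * tj
            + grid[i1, j1] * ti * tj)

    def category(self, prob: float) -> str:
        if prob >= self.preferred_min:
            return "preferred"
        if prob >= self.allowed_min:
            return "allowed"
        return "outlier"


@dataclass
class RamaPoint:
    residue: tuple[str, int, str]
    res_type: str
    phi: float
    psi: float
    rama_class: str
    probability: float
    category: str

    @property
    def marker(self) -> str:
        if self.res_type == "GLY":
            return "triangle"
        if self.res_type == "PRO":
            return "square"
        return "circle"


@dataclass
class KleywegtPair:
    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    phi_a: float
    psi_a: float
    phi_b: float
    psi_b: float
    torus_distance: float


def phi_psi(s: Structure, res: Residue):
    """(phi, psi) of a residue, or None at chain termini / chain breaks."""
    chain = s.chain(res.chain_id)
    i = chain.index(res)
    prev_res = chain[i - 1] if i > 0 else None
    next_res = chain[i + 1] if i + 1 < len(chain) else None
    if prev_res is None or next_res is None:
        return None
    needed = (prev_res.atom("C"), res.atom("N"), res.atom("CA"),
              res.atom("C"), next_res.atom("N"))
    if any(a is None for a in needed):
        return None
    c0, n, ca, c, n1 = (a.pos for a in needed)
    return (dihedral_deg(c0, n, ca, c), dihedral_deg(n, ca, c, n1))


def rama_class(res: Residue, next_res: Residue | None) -> str:
    """Class assignment; pre-Pro takes precedence over the type classes."""
    if next_res is not None and next_res.res_type == "PRO":
        return "pre_pro"
    if res.res_type == "GLY":
        return "gly"
    if res.res_type == "PRO":
        return "pro"
    if res.res_type in ("ILE", "VAL"):
        return "ile_val"
    return "general"


def rama_report(
    s: Structure,
    tables: RamaTables | None = None,
    sel=None,
    outliers_only: bool = False,
):
    """Ramachandran analysis: (points, summary dict with counts/percentages)."""
    tables = tables or RamaTables()
    residues = list(s.residues())
    if sel is not None:
        sel = ensure_selection(sel)
        residues = [r for r in residues if sel.matches_residue(r)]
    points = []
    for res in residues:
        if res.res_type not in chemdata.STANDARD_AA:
            continue
        angles = phi_psi(s, res)
        if angles is None:
            continue
        chain = s.chain(res.chain_id)
        i = chain.index(res)
        next_res = chain[i + 1] if i + 1 < len(chain) else None
        cls = rama_class(res, next_res)
        prob = tables.probability(cls, *angles)
        points.append(RamaPoint(res.id, res.res_type, angles[0], angles[1],
                                cls, prob, tables.category(prob)))
    counts = {"preferred": 0, "allowed": 0, "outlier": 0}
    for p in points:
        counts[p.category] += 1
    total = len(points)
    summary = {
        "n": total,
        "counts": counts,
        "percent": {k: (100.0 * v / total if total else 0.0)
                    for k, v in counts.items()},
    }
    if outliers_only:
        points = [p for p in points if p.category == "outlier"]
    return points, summary


def _paired_residues(s1, chain_a, s2, chain_b):
    ra = s1.chain(chain_a)
    rb = s2.chain(chain_b)
    by_num = {r.seqnum: r for r in rb}
    pairs = [(r, by_num[r.seqnum]) for r in ra if r.seqnum in by_num]
    if pairs and all(a.res_type == b.res_type for a, b in pairs):
        return pairs
    # types disagree somewhere: align the one-letter sequences
    from Bio import Align

    aligner = Align.PairwiseAligner(scoring="blastp")
    aligner.mode = "global"
    seq_a = "".join(chemdata.THREE_TO_ONE.get(r.res_type, "X") for r in ra)
    seq_b = "".join(chemdata.THREE_TO_ONE.get(r.res_type, "X") for r in rb)
    aln = aligner.align(seq_a, seq_b)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for k in range(a1 - a0):
            pairs.append((ra[a0 + k], rb[b0 + k]))
    return pairs


def kleywegt_compare(
    s1: Structure,
    chain_a: str,
    s2: Structure | None = None,
    chain_b: str | None = None,
    top_n: int = 50,
) -> list[KleywegtPair]:
    """Compare two (NCS-related) chains in Ramachandran space.

    Residues are paired by sequence number (falling back to sequence
    alignment when types differ); each pair gets the torus distance
    sqrt(dphi^2 + dpsi^2) with 360-degree wrap on both axes.  Pairs are
    sorted by decreasing distance and truncated to the ``top_n`` most
    distant, mirroring the plot's default of showing the 50 worst.
    """
    s2 = s2 if s2 is not None else s1
    chain_b = chain_b if chain_b is not None else chain_a
    pairs = _paired_residues(s1, chain_a, s2, chain_b)
    out = []
    for ra, rb in pairs:
        ang_a = phi_psi(s1, ra)
        ang_b = phi_psi(s2, rb)
        if ang_a is None or ang_b is None:
            continue
        dphi = wrap_degrees(ang_a[0] - ang_b[0])
        dpsi = wrap_degrees(ang_a[1] - ang_b[1])
        out.append(KleywegtPair(ra.id, rb.id, *ang_a, *ang_b,
                                float(np.hypot(dphi, dpsi))))
    if not out:
        raise ValueError(f"chains {chain_a} and {chain_b} share no residues")
    out.sort(key=lambda p: -p.torus_distance)
    return out[:top_n]


def rotamer_analysis(s: Structure, library=None, sel=None) -> pd.DataFrame:
    """Nearest library rotamer and its prior probability per residue.

    Distance is the Euclidean norm of the wrapped chi differences; exact
    ties go to the lower-index (more probable) rotamer.  Residues without
    rotamers (Gly, Ala) are skipped.
    """
    from .backrub import RotamerLibrary

    library = library or RotamerLibrary.load_default()
    residues = list(s.residues())
    if sel is not None:
        sel = ensure_selection(sel)
        residues = [r for r in residues if sel.matches_residue(r)]
    rows = []
    for res in residues:
        quads = chemdata.CHI_ATOMS.get(res.res_type)
        if not quads or not library.has(res.res_type):
            continue
        try:
            chis = [dihedral_deg(*(res.pos(a) for a in quad)) for quad in quads]
        except KeyError:
            continue  # incomplete side chain
        best = None
        for k, rot in enumerate(library.rotamers(res.res_type)):
            d = np.sqrt(sum(
                wrap_degrees(c - rc) ** 2 for c, rc in zip(chis, rot.chis)))
            if best is None or d < best[0] - 1e-12:
                best = (d, k, rot)
        d, _k, rot = best
        rows.append({
            "chain": res.chain_id, "seqnum": res.seqnum,
            "res_type": res.res_type, "rotamer": rot.name,
            "probability": rot.probability, "chi_distance": float(d),
        })
    return pd.DataFrame(rows)


def b_factor_stats(s: Structure, sel=None):
    """Occupancy-unweighted B statistics: (mean, median, per-residue means).

    The median is the robust companion to the mean: a handful of waters
    with very large B values shift the mean but leave the median alone.
    """
    residues = list(s.residues())
    if sel is not None:
        sel = ensure_selection(sel)
        residues = [r for r in residues if sel.matches_residue(r)]
    bvals = [a.b for r in residues for a in r.atoms]
    if not bvals:
        raise ValueError("selection contains no atoms")
    per_residue = pd.DataFrame(
        [{"chain": r.chain_id, "seqnum": r.seqnum, "res_type": r.res_type,
          "mean_b": float(np.mean([a.b for a in r.atoms])),
          "n_atoms": len(r.atoms)}
         for r in residues if r.atoms])
    return float(np.mean(bvals)), float(np.median(bvals)), per_residue


def density_fit_graph(s: Structure, density_map: DensityMap, sel=None) -> pd.DataFrame:
    """Per-residue density fit: mean occ*Z-weighted density per atom."""
    residues = list(s.residues())
    if sel is not None:
        sel = ensure_selection(sel)
        residues = [r for r in residues if sel.matches_residue(r)]
    rows = []
    for r in residues:
        if not r.atoms:
            continue
        xyz = np.array([a.pos for a in r.atoms])
        w = np.array([a.occ * chemdata.atomic_number(a.element) for a in r.atoms])
        vals, _g, _i = _trilinear(density_map, xyz)
        rows.append({
            "chain": r.chain_id, "seqnum": r.seqnum, "res_type": r.res_type,
            "fit": float(np.dot(w, vals) / len(r.atoms)),
        })
    return pd.DataFrame(rows)


def ligand_distortion(res: Residue, dictionary: MonomerDictionary | None = None):
    """Dictionary-based geometry z-scores for one residue/ligand.

    Each bond/angle/torsion template is compared with the built geometry;
    torsion deviations use the nearest periodic image.  Returns (DataFrame
    of per-restraint records, dict of RMS z per class).
    """
    dictionary = dictionary or default_dictionary()
    entry = dictionary.entry(res.res_type)
    rows = []
    for b in entry.bonds:
        if res.has_atoms(b.a1, b.a2):
            obs = float(np.linalg.norm(res.pos(b.a1) - res.pos(b.a2)))
            rows.append({"class": "bond", "atoms": f"{b.a1}-{b.a2}",
                         "observed": obs, "target": b.target,
                         "sigma": b.sigma, "z": (obs - b.target) / b.sigma})
    for a in entry.angles:
        if res.has_atoms(a.a1, a.a2, a.a3):
            from .geometry import angle_deg

            obs = angle_deg(res.pos(a.a1), res.pos(a.a2), res.pos(a.a3))
            rows.append({"class": "angle", "atoms": f"{a.a1}-{a.a2}-{a.a3}",
                         "observed": obs, "target": a.target,
                         "sigma": a.sigma, "z": (obs - a.target) / a.sigma})
    for t in entry.torsions:
        if res.has_atoms(t.a1, t.a2, t.a3, t.a4):
            obs = dihedral_deg(res.pos(t.a1), res.pos(t.a2),
                               res.pos(t.a3), res.pos(t.a4))
            delta = wrap_degrees(obs - t.target)
            step = 360.0 / max(1, t.period)
            delta = delta - step * np.round(delta / step)
            rows.append({"class": "torsion",
                         "atoms": f"{t.a1}-{t.a2}-{t.a3}-{t.a4}",
                         "observed": obs, "target": t.target,
                         "sigma": t.sigma, "z": float(delta / t.sigma)})
    df = pd.DataFrame(rows)
    summary = {}
    if not df.empty:
        for cls, group in df.groupby("class"):
            summary[cls] = float(np.sqrt((group["z"] ** 2).mean()))
    return df, summary
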