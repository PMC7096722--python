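"""Real-space refinement: scoring, minimisation, rigid and stochastic fits.

The refinement target is

    total = sum of restraint energies  -  map_weight * density_fit_score,

so lower is better.  Restraint energies are squared, sigma-scaled residuals
(with the bounded Geman-McClure loss for self distance restraints).
Gradients are analytic for every term: distances, angles, torsions, chiral
volumes, best-fit-plane deviations (exact via the envelope theorem, since
the fitted plane minimises the deviations) and the trilinear density term.

Minimisation uses L-BFGS-B with the gradient; atoms outside the refined
zone are fixed anchors that still contribute to shared restraints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from . import chemdata
from .densmap import CubicMapInterpolator, DensityMap, _trilinear
from .geometry import rotation_about_axis, wrap_degrees
from .model import Structure, ensure_selection
from .restraints import RestraintSet, generate_self_gm_restraints
from .dictionary import default_dictionary

__all__ = [
    "RefinementConfig",
    "RigidTransform",
    "ScoreBreakdown",
    "CompiledTarget",
    "total_score",
    "refine_zone",
    "rigid_body_refine",
    "jiggle_fit",
    "nudge_register",
]


@dataclass
class RefinementConfig:
    map_weight: float = 10.0
    max_iter: int = 400
    gtol: float = 1e-6
    rng_seed: int = 0
    weights: dict = field(default_factory=lambda: {
        "bonds": 1.0,
        "angles": 1.0,
        "torsions": 0.0,   # torsion restraints are off by default
        "planes": 1.0,
        "chirals": 1.0,
        "nonbonded": 1.0,
        "gm": 1.0,
    })

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if any(w < 0 for w in self.weights.values()) or self.map_weight < 0:
            raise ValueError("weights must be non-negative")


@dataclass
class RigidTransform:
    rotation: np.ndarray
    translation: np.ndarray
    pivot: np.ndarray

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, float)
        return (xyz - self.pivot) @ self.rotation.T + self.pivot + self.translation

    @classmethod
    def identity(cls, pivot=None) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3),
                   np.zeros(3) if pivot is None else np.asarray(pivot, float))


@dataclass
class ScoreBreakdown:
    terms: dict[str, float]
    density: float

    @property
    def geometry(self) -> float:
        return float(sum(self.terms.values()))

    @property
    def total(self) -> float:
        return self.geometry + self.density


# ---------------------------------------------------------------------------
# Compilation of a RestraintSet against a Structure

class CompiledTarget:
    """RestraintSet + Structure topology flattened into index arrays."""

    def __init__(self, s: Structure, restraints: RestraintSet,
                 density_map: DensityMap | None = None,
                 cfg: RefinementConfig | None = None):
        self.cfg = cfg or RefinementConfig()
        self.map = density_map
        # smooth (C2) density interpolant: gradients of a piecewise-linear
        # map vanish at grid nodes and trap the minimiser there
        self.map_spline = (
            CubicMapInterpolator(density_map) if density_map is not None else None
        )
        self.atom_keys = []
        self.atom_weights = []
        index = {}
        for _cid, residues in s.chains:
            for r in residues:
                for a in r.atoms:
                    key = (r.chain_id, r.seqnum, r.inscode, a.name)
                    index[key] = len(self.atom_keys)
                    self.atom_keys.append(key)
                    self.atom_weights.append(a.occ * chemdata.atomic_number(a.element))
        self.index = index
        self.atom_weights = np.array(self.atom_weights)

        def idx(keys):
            try:
                return [index[tuple(k)] for k in keys]
            except KeyError as exc:
                raise KeyError(f"restraint references missing atom {exc}") from None

        self.bond_idx = np.array([idx(b.atoms) for b in restraints.bonds],
                                 dtype=int).reshape(-1, 2)
        self.bond_t = np.array([b.target for b in restraints.bonds])
        self.bond_s = np.array([b.sigma for b in restraints.bonds])

        self.ang_idx = np.array([idx(a.atoms) for a in restraints.angles],
                                dtype=int).reshape(-1, 3)
        self.ang_t = np.array([a.target for a in restraints.angles])
        self.ang_s = np.array([a.sigma for a in restraints.angles])

        self.tor_idx = np.array([idx(t.atoms) for t in restraints.torsions],
                                dtype=int).reshape(-1, 4)
        self.tor_t = np.array([t.target for t in restraints.torsions])
        self.tor_s = np.array([t.sigma for t in restraints.torsions])
        self.tor_p = np.array([t.period for t in restraints.torsions], dtype=int)

        self.chir_idx = np.array([idx(c.atoms) for c in restraints.chirals],
                                 dtype=int).reshape(-1, 4)
        self.chir_t = np.array([c.volume for c in restraints.chirals])
        self.chir_s = np.array([c.sigma for c in restraints.chirals])

        self.planes = [
            (np.array(idx(p.atoms), dtype=int), p.sigma) for p in restraints.planes
        ]

        self.nb_idx = np.array([idx(p.atoms) for p in restraints.nonbonded],
                               dtype=int).reshape(-1, 2)
        self.nb_rmin = np.array([p.r_min for p in restraints.nonbonded])

        self.gm_idx = np.array([idx(g.atoms) for g in restraints.gm],
                               dtype=int).reshape(-1, 2)
        self.gm_t = np.array([g.target for g in restraints.gm])
        self.gm_s = np.array([g.sigma for g in restraints.gm])
        self.gm_a = np.array([g.alpha for g in restraints.gm])

    # -- energy terms -------------------------------------------------------
    def _pair_term(self, xyz, idx, fn):
        """Generic distance-based term; fn(d) -> (E_i, dE/dd_i)."""
        if len(idx) == 0:
            return 0.0, 0.0
        v = xyz[idx[:, 0]] - xyz[idx[:, 1]]
        d = np.linalg.norm(v, axis=1)
        e, dedd = fn(d)
        u = v / np.maximum(d, 1e-12)[:, None]
        g = dedd[:, None] * u
        return float(e.sum()), (idx, g)

    def energy_and_grad(self, xyz: np.ndarray):
        w = self.cfg.weights
        grad = np.zeros_like(xyz)
        terms = {}

        def accumulate(name, weight, result):
            e, gg = result
            terms[name] = weight * e
            if weight and not np.isscalar(gg):
                idx, g = gg
                np.add.at(grad, idx[:, 0], weight * g)
                np.add.at(grad, idx[:, 1], -weight * g)

        accumulate("bonds", w["bonds"], self._pair_term(
            xyz, self.bond_idx,
            lambda d: (((d - self.bond_t) / self.bond_s) ** 2,
                       2.0 * (d - self.bond_t) / self.bond_s ** 2)))
        accumulate("gm", w["gm"], self._pair_term(
            xyz, self.gm_idx, self._gm_fn))
        accumulate("nonbonded", w["nonbonded"], self._pair_term(
            xyz, self.nb_idx, self._nb_fn))

        e_ang, g_ang = self._angle_term(xyz)
        terms["angles"] = w["angles"] * e_ang
        grad += w["angles"] * g_ang

        e_tor, g_tor = self._torsion_term(xyz)
        terms["torsions"] = w["torsions"] * e_tor
        grad += w["torsions"] * g_tor

        e_pl, g_pl = self._plane_term(xyz)
        terms["planes"] = w["planes"] * e_pl
        grad += w["planes"] * g_pl

        e_ch, g_ch = self._chiral_term(xyz)
        terms["chirals"] = w["chirals"] * e_ch
        grad += w["chirals"] * g_ch

        density = 0.0
        if self.map_spline is not None and self.cfg.map_weight > 0:
            vals, dgrad = self.map_spline.evaluate(xyz)
            density = -self.cfg.map_weight * float(np.dot(self.atom_weights, vals))
            grad += -self.cfg.map_weight * self.atom_weights[:, None] * dgrad

        return ScoreBreakdown(terms, density), grad

    def _gm_fn(self, d):
        z = (d - self.gm_t) / self.gm_s
        denom = 1.0 + self.gm_a * z * z
        return z * z / denom, 2.0 * z / (denom * denom * self.gm_s)

    def _nb_fn(self, d):
        gap = np.maximum(0.0, self.nb_rmin - d)
        sigma = 0.2
        return (gap / sigma) ** 2, -2.0 * gap / sigma ** 2

    def _angle_term(self, xyz):
        grad = np.zeros_like(xyz)
        if len(self.ang_idx) == 0:
            return 0.0, grad
        ia, ib, ic = self.ang_idx.T
        u = xyz[ia] - xyz[ib]
        v = xyz[ic] - xyz[ib]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        cosang = np.clip((uh * vh).sum(axis=1), -1.0, 1.0)
        theta = np.degrees(np.arccos(cosang))
        delta = theta - self.ang_t
        e = (delta / self.ang_s) ** 2
        sin = np.sqrt(np.maximum(1e-12, 1.0 - cosang ** 2))
        # d(theta_rad)/da etc.
        dth_da = (cosang[:, None] * uh - vh) / (nu * sin)[:, None]
        dth_dc = (cosang[:, None] * vh - uh) / (nv * sin)[:, None]
        dth_db = -(dth_da + dth_dc)
        coef = (2.0 * delta / self.ang_s ** 2 * np.degrees(1.0))[:, None]
        np.add.at(grad, ia, coef * dth_da)
        np.add.at(grad, ib, coef * dth_db)
        np.add.at(grad, ic, coef * dth_dc)
        return float(e.sum()), grad

    def _torsion_term(self, xyz):
        grad = np.zeros_like(xyz)
        if len(self.tor_idx) == 0:
            return 0.0, grad
        i1, i2, i3, i4 = self.tor_idx.T
        b1 = xyz[i2] - xyz[i1]
        b2 = xyz[i3] - xyz[i2]
        b3 = xyz[i4] - xyz[i3]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        x = (n1 * n2).sum(axis=1)
        y = (np.cross(n1, n2) * (b2 / nb2[:, None])).sum(axis=1)
        phi = np.degrees(np.arctan2(y, x))
        period_step = 360.0 / self.tor_p
        delta = wrap_degrees(phi - self.tor_t)
        delta = delta - period_step * np.round(delta / period_step)
        e = (delta / self.tor_s) ** 2
        # Blondel & Karplus analytic gradient (radians), then chain to degrees
        n1sq = (n1 * n1).sum(axis=1)
        n2sq = (n2 * n2).sum(axis=1)
        f1 = -(nb2 / np.maximum(n1sq, 1e-12))[:, None] * n1
        f4 = (nb2 / np.maximum(n2sq, 1e-12))[:, None] * n2
        p = ((b1 * b2).sum(axis=1) / nb2 ** 2)[:, None]
        q = ((b3 * b2).sum(axis=1) / nb2 ** 2)[:, None]
        f2 = -(1.0 + p) * f1 + q * f4
        f3 = p * f1 - (1.0 + q) * f4
        coef = (2.0 * delta / self.tor_s ** 2 * np.degrees(1.0))[:, None]
        np.add.at(grad, i1, coef * f1)
        np.add.at(grad, i2, coef * f2)
        np.add.at(grad, i3, coef * f3)
        np.add.at(grad, i4, coef * f4)
        return float(e.sum()), grad

    def _plane_term(self, xyz):
        grad = np.zeros_like(xyz)
        total = 0.0
        for idx, sigma in self.planes:
            pts = xyz[idx]
            centred = pts - pts.mean(axis=0)
            _u, _s, vt = np.linalg.svd(centred, full_matrices=False)
            n = vt[-1]
            d = centred @ n
            total += float(((d / sigma) ** 2).sum())
            # exact at the fitted plane: derivatives through n and the
            # centroid vanish (the plane is the minimiser)
            g = np.outer(2.0 * d / sigma ** 2, n)
            g -= g.mean(axis=0)
            np.add.at(grad, idx, g)
        return total, grad

    def _chiral_term(self, xyz):
        grad = np.zeros_like(xyz)
        if len(self.chir_idx) == 0:
            return 0.0, grad
        ic, i1, i2, i3 = self.chir_idx.T
        u1 = xyz[i1] - xyz[ic]
        u2 = xyz[i2] - xyz[ic]
        u3 = xyz[i3] - xyz[ic]
        vol = (u1 * np.cross(u2, u3)).sum(axis=1)
        delta = vol - self.chir_t
        e = (delta / self.chir_s) ** 2
        coef = (2.0 * delta / self.chir_s ** 2)[:, None]
        d1 = np.cross(u2, u3)
        d2 = np.cross(u3, u1)
        d3 = np.cross(u1, u2)
        np.add.at(grad, i1, coef * d1)
        np.add.at(grad, i2, coef * d2)
        np.add.at(grad, i3, coef * d3)
        np.add.at(grad, ic, -coef * (d1 + d2 + d3))
        return float(e.sum()), grad


# ---------------------------------------------------------------------------
# Public scoring / refinement API

def total_score(
    s: Structure,
    restraints: RestraintSet,
    density_map: DensityMap | None = None,
    cfg: RefinementConfig | None = None,
):
    """Score a model: (ScoreBreakdown, per-atom gradient array)."""
    target = CompiledTarget(s, restraints, density_map, cfg)
    return target.energy_and_grad(s.coords())


def refine_zone(
    s: Structure,
    sel,
    restraints: RestraintSet,
    density_map: DensityMap | None = None,
    cfg: RefinementConfig | None = None,
):
    """Minimise the total score over the atoms of a selection.

    Atoms outside the selection are fixed but still contribute to
    restraints spanning the boundary.  Returns (refined structure,
    ScoreBreakdown, converged flag).
    """
    cfg = cfg or RefinementConfig()
    sel = ensure_selection(sel)
    target = CompiledTarget(s, restraints, density_map, cfg)
    xyz0 = s.coords()
    free = np.zeros(len(xyz0), dtype=bool)
    for i, key in enumerate(target.atom_keys):
        res = s.residue(key[0], key[1], key[2])
        atom = res.atom(key[3])
        free[i] = sel.matches_atom(res, atom)
    if not free.any():
        raise ValueError(f"selection {sel.format()!r} matches no atoms")

    xyz = xyz0.copy()

    def fun(x_free):
        xyz[free] = x_free.reshape(-1, 3)
        breakdown, grad = target.energy_and_grad(xyz)
        return breakdown.total, grad[free].ravel()

    res = minimize(
        fun,
        xyz0[free].ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": cfg.max_iter, "gtol": cfg.gtol,
                 "ftol": 1e-12, "maxls": 50},
    )
    xyz[free] = res.x.reshape(-1, 3)
    out = s.copy()
    out.set_coords(xyz)
    breakdown, _g = target.energy_and_grad(xyz)
    converged = bool(res.success) or res.status == 1  # 1 = maxiter reached
    if not res.success and res.status != 1:
        warnings.warn(f"refinement did not converge: {res.message}", stacklevel=2)
    return out, breakdown, converged


# ---------------------------------------------------------------------------
# Rigid-body refinement and jiggle fit

def _fragment_atoms(s: Structure, sel):
    sel = ensure_selection(sel)
    atoms = [a for r in s.residues() if sel.matches_residue(r)
             for a in r.atoms if sel.matches_atom(r, a)]
    if not atoms:
        raise ValueError(f"selection {sel.format()!r} matches no atoms")
    return atoms


def _map_score(m: DensityMap, xyz: np.ndarray, weights: np.ndarray) -> float:
    vals, _g, _i = _trilinear(m, xyz)
    return float(np.dot(weights, vals))


def rigid_body_refine(
    s: Structure,
    sel,
    density_map: DensityMap,
    cfg: RefinementConfig | None = None,
    _start: tuple | None = None,
):
    """Maximise the density fit over the 6 rigid-body parameters.

    Powell search over a rotation vector about the fragment centroid plus a
    translation; fragment-internal geometry is untouched.  Returns
    (RigidTransform, refined structure).
    """
    atoms = _fragment_atoms(s, sel)
    xyz0 = np.array([a.pos for a in atoms])
    if len(atoms) < 3 or np.linalg.matrix_rank(xyz0 - xyz0.mean(axis=0)) < 2:
        raise ValueError("fragment needs >= 3 non-collinear atoms")
    weights = np.array(
        [a.occ * chemdata.atomic_number(a.element) for a in atoms])
    pivot = xyz0.mean(axis=0)

    def transform(params):
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        return (xyz0 - pivot) @ rot.T + pivot + params[3:]

    def negscore(params):
        return -_map_score(density_map, transform(params), weights)

    x0 = np.zeros(6) if _start is None else np.asarray(_start, float)
    res = minimize(negscore, x0, method="Powell",
                   options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 2000})
    rot = Rotation.from_rotvec(res.x[:3]).as_matrix()
    tr = RigidTransform(rot, np.asarray(res.x[3:]), pivot)
    out = s.copy()
    new_xyz = transform(res.x)
    for a, p in zip(_fragment_atoms(out, sel), new_xyz):
        a.pos = p.copy()
    return tr, out


def jiggle_fit(
    s: Structure,
    sel,
    density_map: DensityMap,
    n_trials: int = 400,
    max_rot_deg: float = 30.0,
    max_trans_A: float = 6.0,
    n_keep: int = 20,
    cfg: RefinementConfig | None = None,
):
    """Stochastic rigid search: random rotation/translation hypotheses are
    scored against the map, the best ``n_keep`` are rigid-body refined, and
    the winner replaces the fragment only on strict improvement.

    Returns (structure, best score).  Deterministic for a fixed
    ``cfg.rng_seed``; trials are scored independently of evaluation order.
    """
    cfg = cfg or RefinementConfig()
    if n_trials < 1 or n_keep < 1 or n_keep > n_trials:
        raise ValueError("need n_trials >= 1 and 1 <= n_keep <= n_trials")
    atoms = _fragment_atoms(s, sel)
    xyz0 = np.array([a.pos for a in atoms])
    weights = np.array(
        [a.occ * chemdata.atomic_number(a.element) for a in atoms])
    pivot = xyz0.mean(axis=0)
    start_score = _map_score(density_map, xyz0, weights)

    rng = np.random.default_rng(cfg.rng_seed)
    axes = rng.normal(size=(n_trials, 3))
    axes /= np.linalg.norm(axes, axis=1)[:, None]
    angles = rng.uniform(0.0, max_rot_deg, size=n_trials)
    trans = rng.uniform(-max_trans_A, max_trans_A, size=(n_trials, 3))

    rotvecs = axes * np.radians(angles)[:, None]
    scores = np.empty(n_trials)
    for i in range(n_trials):
        R = Rotation.from_rotvec(rotvecs[i]).as_matrix()
        xyz = (xyz0 - pivot) @ R.T + pivot + trans[i]
        scores[i] = _map_score(density_map, xyz, weights)
    order = np.argsort(-scores, kind="stable")[:n_keep]

    best_score = start_score
    best_struct = None
    for i in order:
        params = np.concatenate([rotvecs[i], trans[i]])
        _tr, candidate = rigid_body_refine(s, sel, density_map, cfg, _start=params)
        cand_atoms = _fragment_atoms(candidate, sel)
        sc = _map_score(density_map, np.array([a.pos for a in cand_atoms]), weights)
        if sc > best_score:
            best_score = sc
            best_struct = candidate
    if best_struct is None:
        return s.copy(), start_score
    return best_struct, best_score


# ---------------------------------------------------------------------------
# Register nudging

def nudge_register(
    s: Structure,
    zone_sel,
    offset: int,
    density_map: DensityMap | None = None,
    cfg: RefinementConfig | None = None,
    gm_limit: float = 6.0,
    refine: bool = True,
):
    """Shift residue identities along a zone to test a register hypothesis.

    Residue i takes the type (and a rebuilt best-rotamer side chain) of
    residue i - offset within the zone; zone edges whose source falls
    outside the zone keep their backbone but are stubbed at C-beta.  The
    hypothesis is then refined against the map with self distance restraints
    generated from the pre-shift backbone.  The input model is untouched.
    """
    from .backrub import RotamerLibrary
    from .surgery import _mutate_residue

    if offset == 0:
        raise ValueError("offset 0 is not a register hypothesis")
    zone_sel = ensure_selection(zone_sel)
    zone = [r for r in s.residues() if zone_sel.matches_residue(r)]
    if len(zone) < abs(offset) + 2:
        raise ValueError(
            f"zone of {len(zone)} residues is too short for offset {offset}")
    lib = RotamerLibrary.load_default()
    out = s.copy()
    old_types = [r.res_type for r in zone]
    gm = generate_self_gm_restraints(s, zone_sel, limit=gm_limit) if refine else []
    for i, res in enumerate(zone):
        src = i - offset
        target_res = out.residue(res.chain_id, res.seqnum, res.inscode)
        if 0 <= src < len(zone):
            new_type = old_types[src]
            if new_type != target_res.res_type:
                _mutate_residue(target_res, new_type, lib)
        else:
            # no source residue: stub the side chain at CB
            keep = set(chemdata.BACKBONE_ATOMS) | {"CB"}
            target_res.atoms = [a for a in target_res.atoms if a.name in keep]
    if refine and density_map is not None:
        from .restraints import build_standard_restraints

        rset = build_standard_restraints(out, default_dictionary(), zone_sel)
        rset.gm = [g for g in gm
                   if all(k[3] in chemdata.BACKBONE_ATOMS for k in g.atoms)]
        out, _bd, _conv = refine_zone(out, zone_sel, rset, density_map, cfg)
    return out
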