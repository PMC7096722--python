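"""Density maps: MRC/CCP4 I/O, Fourier blur/sharpen, interpolation, blobs.

Maps are real-space grids on orthogonal cells (the practical case for
single-particle cryo-EM reconstructions, which are P1 with 90 degree
angles).  Grid axes are stored in (x, y, z) order; ``origin`` places grid
node (0,0,0) in cartesian space and ``spacing`` gives the voxel size along
each axis.

The blur/sharpen operation multiplies the Fourier transform by
exp(-B s^2 / 4) with s in 1/A, the crystallographic temperature-factor
convention: positive B smooths the map, negative B sharpens it, and blurring
a point spike by B produces a real-space Gaussian with sigma^2 = B/(8 pi^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import gemmi

from . import chemdata
from .model import FormatError

__all__ = [
    "DensityMap",
    "BlobHit",
    "read_map",
    "write_map",
    "sharpen_blur",
    "multi_sharpen",
    "interpolate_density",
    "density_gradient",
    "density_fit_score",
    "find_blob_along_segment",
]


@dataclass
class DensityMap:
    grid: np.ndarray          # (nx, ny, nz) float array
    cell: tuple[float, float, float]
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        # float64 in memory: Fourier sharpening amplifies high-frequency
        # roundoff by exp(B s^2/4), so float32 storage breaks invertibility
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError("grid must be 3-D with at least 2 nodes per axis")
        self.origin = np.asarray(self.origin, dtype=float)
        if any(c <= 0 for c in self.cell):
            raise ValueError("cell edges must be positive")

    @property
    def spacing(self) -> np.ndarray:
        return np.array([c / n for c, n in zip(self.cell, self.grid.shape)])

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), tuple(self.cell), self.origin.copy())

    def frac_coords(self, points: np.ndarray) -> np.ndarray:
        """Cartesian points (n,3) -> fractional grid-index coordinates."""
        return (np.atleast_2d(points) - self.origin) / self.spacing


@dataclass
class BlobHit:
    centre: np.ndarray
    peak: float
    extent: float


# ---------------------------------------------------------------------------
# I/O

def read_map(path) -> DensityMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot read CCP4/MRC map {path}: {exc}") from exc
    cell = m.grid.unit_cell
    if not (
        abs(cell.alpha - 90) < 1e-3
        and abs(cell.beta - 90) < 1e-3
        and abs(cell.gamma - 90) < 1e-3
    ):
        raise FormatError(
            f"{path}: non-orthogonal cell "
            f"({cell.alpha:g}, {cell.beta:g}, {cell.gamma:g}); only orthogonal "
            "cells are supported")
    arr = np.array(m.grid.array, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise FormatError(f"{path}: map contains non-finite values")
    return DensityMap(arr, (cell.a, cell.b, cell.c))


def write_map(m: DensityMap, path) -> None:
    g = gemmi.FloatGrid(*m.grid.shape)
    g.set_unit_cell(gemmi.UnitCell(*m.cell, 90, 90, 90))
    g.spacegroup = gemmi.SpaceGroup("P1")
    np.asarray(g.array)[:] = m.grid.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = g
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# Fourier-space blur / sharpen / resample

def _s_squared(shape, cell) -> np.ndarray:
    freqs = [np.fft.fftfreq(n, d=c / n) for n, c in zip(shape, cell)]
    fx, fy, fz = np.meshgrid(*freqs, indexing="ij")
    return fx * fx + fy * fy + fz * fz


def _resample_pad(F: np.ndarray, factor: float) -> np.ndarray:
    """Zero-pad an fftn spectrum to enlarge the grid by ``factor``."""
    old = F.shape
    new = tuple(int(round(n * factor)) for n in old)
    out = np.zeros(new, dtype=complex)
    for axis, (n_old, n_new) in enumerate(zip(old, new)):
        if n_new < n_old:
            raise ValueError("resample_factor must be >= 1")
    sl_old, sl_new = [], []
    for n_old, n_new in zip(old, new):
        half = n_old // 2
        sl_old.append((slice(0, half + n_old % 2), slice(half + n_old % 2, n_old)))
        sl_new.append((slice(0, half + n_old % 2), slice(n_new - half, n_new)))
    for i in range(2):
        for j in range(2):
            for k in range(2):
                out[sl_new[0][i], sl_new[1][j], sl_new[2][k]] = \
                    F[sl_old[0][i], sl_old[1][j], sl_old[2][k]]
    return out


def sharpen_blur(m: DensityMap, B: float, resample_factor: float = 1.0) -> DensityMap:
    """Apply exp(-B s^2/4) in Fourier space; optionally resample finer.

    B > 0 blurs, B < 0 sharpens, B = 0 with factor 1 is the identity.  The
    s = 0 term is untouched, so the map mean is preserved.  Resampling
    enlarges the grid by reciprocal-space zero padding (band-limited), which
    leaves values at the original nodes unchanged.
    """
    if not np.isfinite(B):
        raise ValueError("B must be finite")
    if resample_factor < 1:
        raise ValueError("resample_factor must be >= 1")
    F = np.fft.fftn(m.grid.astype(float))
    F *= np.exp(-B * _s_squared(m.grid.shape, m.cell) / 4.0)
    if resample_factor != 1.0:
        old_size = np.prod(m.grid.shape)
        F = _resample_pad(F, resample_factor)
        F *= np.prod(F.shape) / old_size
    out = np.fft.ifftn(F).real
    return DensityMap(out, tuple(m.cell), m.origin.copy())


def multi_sharpen(m: DensityMap, B_list) -> list[DensityMap]:
    """Series of blurred/sharpened maps sharing a single forward transform."""
    B_list = list(B_list)
    if not B_list:
        raise ValueError("B_list must be non-empty")
    F = np.fft.fftn(m.grid.astype(float))
    s2 = _s_squared(m.grid.shape, m.cell)
    out = []
    for B in B_list:
        if not np.isfinite(B):
            raise ValueError("B must be finite")
        g = np.fft.ifftn(F * np.exp(-B * s2 / 4.0)).real
        out.append(DensityMap(g, tuple(m.cell), m.origin.copy()))
    return out


# ---------------------------------------------------------------------------
# Interpolation and scoring

def _trilinear(m: DensityMap, points: np.ndarray):
    """Values and gradients of trilinear interpolation at cartesian points.

    Points outside the grid (beyond the last node along any axis) get value
    0 and gradient 0.  Returns (values, gradients, inside_mask).
    """
    pts = np.atleast_2d(np.asarray(points, float))
    f = m.frac_coords(pts)
    shape = np.array(m.grid.shape)
    inside = np.all((f >= 0) & (f <= shape - 1), axis=1)
    fc = np.clip(f, 0, shape - 1 - 1e-9)
    i0 = np.floor(fc).astype(int)
    i0 = np.minimum(i0, shape - 2)
    t = fc - i0
    g = m.grid
    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    c = np.empty(pts.shape[0:1] + (2, 2, 2))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                c[:, dx, dy, dz] = g[ix + dx, iy + dy, iz + dz]
    tx, ty, tz = t[:, 0], t[:, 1], t[:, 2]
    wx = np.stack([1 - tx, tx], axis=1)
    wy = np.stack([1 - ty, ty], axis=1)
    wz = np.stack([1 - tz, tz], axis=1)
    vals = np.einsum("nijk,ni,nj,nk->n", c, wx, wy, wz)
    dwx = np.stack([-np.ones_like(tx), np.ones_like(tx)], axis=1)
    gx = np.einsum("nijk,ni,nj,nk->n", c, dwx, wy, wz) / m.spacing[0]
    gy = np.einsum("nijk,ni,nj,nk->n", c, wx, dwx, wz) / m.spacing[1]
    gz = np.einsum("nijk,ni,nj,nk->n", c, wx, wy, dwx) / m.spacing[2]
    grads = np.stack([gx, gy, gz], axis=1)
    vals = np.where(inside, vals, 0.0)
    grads = np.where(inside[:, None], grads, 0.0)
    return vals, grads, inside


class CubicMapInterpolator:
    """Cubic B-spline interpolation of a map with analytic gradients.

    Trilinear interpolation is piecewise linear, so its local maxima sit on
    grid nodes; gradient-based refinement against it stalls with atoms
    snapped toward nodes.  The refinement engine therefore evaluates the
    density through a C2-continuous cubic B-spline representation whose
    value and gradient are exact derivatives of one smooth function.
    Outside the grid both are zero.
    """

    def __init__(self, m: DensityMap):
        from scipy.ndimage import spline_filter

        self.map = m
        self.coeff = spline_filter(m.grid.astype(float), order=3, mode="constant")
        self.shape = np.array(m.grid.shape)

    @staticmethod
    def _b3(t):
        at = np.abs(t)
        out = np.zeros_like(at)
        m1 = at < 1
        m2 = (at >= 1) & (at < 2)
        out[m1] = (4.0 - 6.0 * at[m1] ** 2 + 3.0 * at[m1] ** 3) / 6.0
        out[m2] = (2.0 - at[m2]) ** 3 / 6.0
        return out

    @staticmethod
    def _b3p(t):
        at = np.abs(t)
        s = np.sign(t)
        out = np.zeros_like(at)
        m1 = at < 1
        m2 = (at >= 1) & (at < 2)
        out[m1] = s[m1] * (-2.0 * at[m1] + 1.5 * at[m1] ** 2)
        out[m2] = s[m2] * (-0.5) * (2.0 - at[m2]) ** 2
        return out

    def evaluate(self, points: np.ndarray):
        """Values and gradients at cartesian points; (n,), (n, 3)."""
        pts = np.atleast_2d(np.asarray(points, float))
        f = self.map.frac_coords(pts)
        inside = np.all((f >= 0) & (f <= self.shape - 1), axis=1)
        base = np.floor(f).astype(int)
        offs = np.arange(-1, 3)
        # per-axis indices (n, 4) and weights
        idx = [base[:, k, None] + offs[None, :] for k in range(3)]
        t = [f[:, k, None] - idx[k] for k in range(3)]
        w = [self._b3(tk) for tk in t]
        wp = [self._b3p(tk) / self.map.spacing[k] for k, tk in enumerate(t)]
        valid = [np.clip(idx[k], 0, self.shape[k] - 1) for k in range(3)]
        inb = [(idx[k] >= 0) & (idx[k] < self.shape[k]) for k in range(3)]
        c = self.coeff[
            valid[0][:, :, None, None],
            valid[1][:, None, :, None],
            valid[2][:, None, None, :],
        ]
        c = c * (
            inb[0][:, :, None, None]
            & inb[1][:, None, :, None]
            & inb[2][:, None, None, :]
        )
        vals = np.einsum("nijk,ni,nj,nk->n", c, w[0], w[1], w[2])
        gx = np.einsum("nijk,ni,nj,nk->n", c, wp[0], w[1], w[2])
        gy = np.einsum("nijk,ni,nj,nk->n", c, w[0], wp[1], w[2])
        gz = np.einsum("nijk,ni,nj,nk->n", c, w[0], w[1], wp[2])
        grads = np.stack([gx, gy, gz], axis=1)
        vals = np.where(inside, vals, 0.0)
        grads = np.where(inside[:, None], grads, 0.0)
        return vals, grads


def interpolate_density(m: DensityMap, p, return_flag: bool = False):
    """Trilinear density at a cartesian point; 0 outside the grid."""
    vals, _g, inside = _trilinear(m, np.asarray(p, float)[None, :])
    if return_flag:
        return float(vals[0]), bool(inside[0])
    return float(vals[0])


def density_gradient(m: DensityMap, points: np.ndarray) -> np.ndarray:
    _v, grads, _i = _trilinear(m, points)
    return grads


def density_fit_score(m: DensityMap, atoms) -> float:
    """Sum over atoms of occupancy * Z * interpolated density (higher = better)."""
    atoms = list(atoms)
    if not atoms:
        raise ValueError("empty atom list")
    xyz = np.array([a.pos for a in atoms])
    w = np.array([a.occ * chemdata.atomic_number(a.element) for a in atoms])
    vals, _g, _i = _trilinear(m, xyz)
    return float(np.dot(w, vals))


def atom_weights(atoms) -> np.ndarray:
    return np.array([a.occ * chemdata.atomic_number(a.element) for a in atoms])


# ---------------------------------------------------------------------------
# Blob navigation

def find_blob_along_segment(
    m: DensityMap,
    p_front,
    p_back,
    contour: float,
    step: float | None = None,
) -> BlobHit | None:
    """Walk front -> back; return the first contiguous above-contour blob.

    The blob centre is the density-weighted mean of the samples collected
    between the first up-crossing of the contour and the next down-crossing
    (or the segment end).  Returns None when nothing exceeds the contour.
    """
    p_front = np.asarray(p_front, float)
    p_back = np.asarray(p_back, float)
    seg = p_back - p_front
    length = np.linalg.norm(seg)
    if length < 1e-12:
        raise ValueError("p_front and p_back coincide")
    if step is None:
        step = float(m.spacing.min()) / 2.0
    if step <= 0:
        raise ValueError("step must be positive")
    n = max(2, int(np.ceil(length / step)) + 1)
    ts = np.linspace(0.0, 1.0, n)
    pts = p_front[None, :] + ts[:, None] * seg[None, :]
    vals, _g, _i = _trilinear(m, pts)
    above = vals > contour
    if not above.any():
        return None
    start = int(np.argmax(above))
    end = start
    while end < n and above[end]:
        end += 1
    sel = slice(start, end)
    w = vals[sel]
    centre = (pts[sel] * w[:, None]).sum(axis=0) / w.sum()
    return BlobHit(
        centre=centre,
        peak=float(w.max()),
        extent=float((end - start - 1) * length / (n - 1)),
    )
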