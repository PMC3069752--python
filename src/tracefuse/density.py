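"""Electron-density maps and per-residue real-space cross-correlation.

The residue-vs-density agreement entering the consensus edge weights is the
standard real-space CC: the Pearson correlation, over grid points within a
mask around the residue's atoms, between the observed map and a model map
synthesized from the residue alone.

Synthetic maps are sums of spherical Gaussians, one per atom, with a width
tied to the nominal resolution through B = 79*(d/3)^2 (a fixed convention
giving B = 79 A^2 at 3 A) and an element-independent scattering weight equal
to the occupancy.  Each atom integrates to its occupancy, so the grid sum
times the voxel volume equals the total occupancy.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import gemmi
import numpy as np

from .model_io import Residue, Trace, _MAINCHAIN_ATOMS

__all__ = [
    "DensityMap",
    "ResidueDensityScore",
    "MapFormatError",
    "read_map",
    "write_map",
    "synthesize_map",
    "residue_density_cc",
]

logger = logging.getLogger(__name__)

#: minimum mask size for a trustworthy correlation
MIN_MASK_POINTS = 8


class MapFormatError(ValueError):
    """Raised for unreadable maps or cell mismatches."""


@dataclasses.dataclass
class DensityMap:
    """Density values on a grid covering the full unit cell.

    ``grid[ix, iy, iz]`` samples fractional position (ix/nx, iy/ny, iz/nz).
    """

    grid: np.ndarray
    cell: tuple[float, float, float, float, float, float]
    spacegroup: str = "P 1"

    def __post_init__(self) -> None:
        if min(self.grid.shape) < 8:
            raise MapFormatError(f"grid too coarse: {self.grid.shape}")
        if not np.all(np.isfinite(self.grid)):
            raise MapFormatError("map contains non-finite values")
        self._ucell = gemmi.UnitCell(*self.cell)
        self._orth = np.array(self._ucell.orth.mat.tolist())
        self._frac = np.linalg.inv(self._orth)

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.grid.shape

    def interpolate(self, frac_pts: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at fractional positions (periodic)."""
        from scipy.ndimage import map_coordinates

        coords = (np.asarray(frac_pts) * np.array(self.grid.shape)).T
        return map_coordinates(self.grid.astype(float), coords,
                               order=1, mode="grid-wrap")

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self._frac.T

    def check_cell(self, cell, rel_tol: float = 0.005) -> None:
        """Hard error when map and model cells disagree beyond ``rel_tol``."""
        if cell is None:
            return
        for ours, theirs in zip(self.cell[:3], cell[:3]):
            if abs(ours - theirs) > rel_tol * max(ours, theirs):
                raise MapFormatError(
                    f"map cell {self.cell[:3]} does not match model cell "
                    f"{tuple(cell[:3])} (> {rel_tol:.1%} on a length)")


@dataclasses.dataclass
class ResidueDensityScore:
    cc: float
    n_points: int
    scorable: bool = True


# ---------------------------------------------------------------------------
# I/O (CCP4/MRC via gemmi; symmetry expansion and axis normalization on load)

def read_map(path: str | Path) -> DensityMap:
    try:
        m = gemmi.read_ccp4_map(str(path), setup=True)
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"{path}: cannot read CCP4/MRC map: {exc}") from exc
    grid = np.array(m.grid, copy=True, dtype=np.float32)
    cell = m.grid.unit_cell
    sg = m.grid.spacegroup.hm if m.grid.spacegroup else "P 1"
    return DensityMap(grid, (cell.a, cell.b, cell.c,
                             cell.alpha, cell.beta, cell.gamma), sg)


def write_map(dmap: DensityMap, path: str | Path) -> None:
    g = gemmi.FloatGrid(*dmap.grid.shape)
    g.set_unit_cell(gemmi.UnitCell(*dmap.cell))
    sg = gemmi.find_spacegroup_by_name(dmap.spacegroup)
    g.spacegroup = sg if sg is not None else gemmi.find_spacegroup_by_name("P 1")
    np.array(g, copy=False)[...] = dmap.grid.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = g
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# synthesis

def _atom_table(residues, mainchain_only: bool = False) -> tuple[np.ndarray, np.ndarray]:
    xyz, occ = [], []
    for r in residues:
        for a in r.atoms:
            if mainchain_only and a.name not in _MAINCHAIN_ATOMS:
                continue
            xyz.append(a.xyz)
            occ.append(a.occ)
    if not xyz:
        return np.empty((0, 3)), np.empty(0)
    return np.array(xyz, dtype=float), np.array(occ, dtype=float)


def _accumulate_gaussians(grid: np.ndarray, cell_orth: np.ndarray,
                          frac_xyz: np.ndarray, occ: np.ndarray,
                          sigma: float, cutoff_sigmas: float = 3.5) -> None:
    """Add normalized Gaussians (integral = occ) at fractional positions,
    wrapping periodically across cell edges."""
    dims = np.array(grid.shape)
    inv = np.linalg.inv(cell_orth)
    # per-axis fractional radius covering a Cartesian sphere of r_cut
    r_cut = cutoff_sigmas * sigma
    frac_rad = r_cut * np.linalg.norm(inv, axis=1)
    amp = occ / ((2.0 * np.pi) ** 1.5 * sigma ** 3)
    two_s2 = 2.0 * sigma * sigma
    for p, a in zip(frac_xyz, amp):
        lo = np.floor((p - frac_rad) * dims).astype(int)
        hi = np.ceil((p + frac_rad) * dims).astype(int)
        axes = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
        fx = [axes[k] / dims[k] - p[k] for k in range(3)]
        # Cartesian displacement of every box point from the atom
        gx, gy, gz = np.meshgrid(*fx, indexing="ij")
        d = np.stack([gx, gy, gz], axis=-1) @ cell_orth.T
        r2 = np.sum(d * d, axis=-1)
        vals = a * np.exp(-r2 / two_s2)
        ix, iy, iz = [np.mod(axes[k], dims[k]) for k in range(3)]
        np.add.at(grid, np.ix_(ix, iy, iz), vals)


def resolution_sigma(resolution: float) -> float:
    """Gaussian width (A) for a nominal resolution via B = 79*(d/3)^2."""
    b = 79.0 * (resolution / 3.0) ** 2
    return float(np.sqrt(b / (8.0 * np.pi ** 2)))


def synthesize_map(model: Trace, resolution: float, grid_step: float | None = None,
                   noise_sigma: float = 0.0,
                   rng: np.random.Generator | None = None,
                   cell=None, dims: tuple[int, int, int] | None = None) -> DensityMap:
    """Synthesize a density map from a model on the full unit cell.

    ``noise_sigma`` adds iid Gaussian noise with standard deviation equal to
    that fraction of the noise-free map's standard deviation.  ``dims``
    forces the grid dimensions (to match an existing map's grid).
    """
    if grid_step is None:
        grid_step = resolution / 3.0
    if resolution < 2.0 * grid_step - 1e-9:
        raise ValueError("resolution must be >= 2 * grid_step (Nyquist)")
    cell = cell or model.cell
    if cell is None:
        raise ValueError("model has no unit cell")
    ucell = gemmi.UnitCell(*cell)
    if dims is None:
        dims = tuple(max(8, int(np.ceil(length / grid_step)))
                     for length in (ucell.a, ucell.b, ucell.c))
    grid = np.zeros(dims, dtype=np.float64)
    orth = np.array(ucell.orth.mat.tolist())
    xyz, occ = _atom_table(model.all_residues())
    if len(xyz) == 0:
        raise ValueError("model has no atoms")
    frac = xyz @ np.linalg.inv(orth).T
    sigma = resolution_sigma(resolution)
    # expand by crystallographic symmetry so the map covers the whole cell
    sg = gemmi.find_spacegroup_by_name(model.spacegroup or "P 1")
    ops = list(sg.operations()) if sg is not None else []
    sym = []
    for op in ops:
        den = float(op.DEN)
        R = np.array(op.rot, dtype=float) / den
        t = np.array(op.tran, dtype=float) / den
        sym.append(np.mod(frac @ R.T + t, 1.0))
    if not sym:
        sym = [np.mod(frac, 1.0)]
    for frac_img in sym:
        _accumulate_gaussians(grid, orth, frac_img, occ, sigma)
    if noise_sigma > 0.0:
        rng = rng or np.random.default_rng()
        grid += rng.normal(0.0, noise_sigma * grid.std(), size=grid.shape)
    return DensityMap(grid.astype(np.float32), tuple(cell),
                      model.spacegroup or "P 1")


# ---------------------------------------------------------------------------
# real-space CC

def residue_density_cc(residue: Residue, dmap: DensityMap,
                       mask_radius: float = 2.5, resolution: float = 2.5,
                       mainchain_only: bool = False,
                       context: tuple[Residue, ...] = ()) -> ResidueDensityScore:
    """Real-space cross-correlation of one residue against the map.

    Pearson correlation over grid points within ``mask_radius`` of any
    residue atom, between observed map values and a model density calculated
    from the residue plus any ``context`` residues (normally its bonded
    neighbours in the parent trace, whose peptide atoms contribute real
    signal just inside the mask).  The mask is defined by the residue's own
    atoms only.  Zero-variance windows score 0 by convention (keeps
    downstream edge weights finite); masks smaller than MIN_MASK_POINTS are
    flagged unscorable and also score 0.
    """
    xyz, occ = _atom_table([residue], mainchain_only=mainchain_only)
    if len(xyz) == 0:
        return ResidueDensityScore(0.0, 0, scorable=False)
    cxyz, cocc = _atom_table(context, mainchain_only=mainchain_only)
    dims = np.array(dmap.grid.shape)
    orth = dmap._orth
    frac = np.mod(xyz @ dmap._frac.T, 1.0)

    sigma = resolution_sigma(resolution)
    inv = dmap._frac
    frac_rad = mask_radius * np.linalg.norm(inv, axis=1)
    lo = np.floor((frac.min(axis=0) - frac_rad) * dims).astype(int)
    hi = np.ceil((frac.max(axis=0) + frac_rad) * dims).astype(int)
    axes = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
    box_frac = [axes[k] / dims[k] for k in range(3)]
    gx, gy, gz = np.meshgrid(*box_frac, indexing="ij")
    pts_frac = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)

    # distance of each box point to each atom (periodic in fractional space);
    # the mask comes from the residue's atoms, the model density from
    # residue + context atoms
    model_vals = np.zeros(len(pts_frac))
    min_d2 = np.full(len(pts_frac), np.inf)
    two_s2 = 2.0 * sigma * sigma
    amp = 1.0 / ((2.0 * np.pi) ** 1.5 * sigma ** 3)
    frac_ctx = np.mod(cxyz @ dmap._frac.T, 1.0) if len(cxyz) else np.empty((0, 3))
    for p, a, in_mask in [*((p, a, True) for p, a in zip(frac, occ)),
                          *((p, a, False) for p, a in zip(frac_ctx, cocc))]:
        df = pts_frac - p
        df -= np.round(df)
        d = df @ orth.T
        r2 = np.sum(d * d, axis=1)
        if in_mask:
            np.minimum(min_d2, r2, out=min_d2)
        model_vals += a * amp * np.exp(-r2 / two_s2)

    mask = min_d2 <= mask_radius ** 2
    n = int(mask.sum())
    if n < MIN_MASK_POINTS:
        logger.warning("residue %s%d: mask of %d grid points, unscorable",
                       residue.aa_type, residue.seq_num, n)
        return ResidueDensityScore(0.0, n, scorable=False)

    ix, iy, iz = (np.mod(pts_frac[mask, k] * dims[k], dims[k]).round().astype(int) % dims[k]
                  for k in range(3))
    map_vals = dmap.grid[ix, iy, iz].astype(float)
    mv = model_vals[mask]
    if map_vals.std() < 1e-12 or mv.std() < 1e-12:
        return ResidueDensityScore(0.0, n)
    cc = float(np.corrcoef(map_vals, mv)[0, 1])
    return ResidueDensityScore(cc, n)
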