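"""Real-space density forward model, map I/O, and the synthetic-map generator.

Atoms are modelled as sums of isotropic Gaussians using tabulated
multi-Gaussian scattering factors (X-ray form factors, or electron scattering
factors in EM mode), broadened by the atomic B-factor plus a
resolution-dependent blur chosen so the Gaussian FWHM of a zero-B point atom
matches the nominal resolution d.

Synthetic data emulate degraded experiments: B-factors are inflated by
1 Angstrom^2 per 0.1 Angstrom of resolution loss, coordinates are randomly
shaken with RMS amplitude 0.2*d, structure factors are computed over a P1
box and truncated at d, and per-reflection amplitude noise
``F + sqrt(F) * eps * d * 0.5`` is added before inverting back to a map.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .structure import Conformer, ResidueModel, StructureModel

__all__ = [
    "DensityMap",
    "StructureFactors",
    "SyntheticSpec",
    "resolution_blur_b",
    "compute_density",
    "solvent_mask",
    "extract_residue_subgrid",
    "shake_coordinates",
    "inflate_bfactors",
    "compute_structure_factors",
    "add_structure_factor_noise",
    "make_synthetic_map",
    "read_map",
    "write_map",
]

_EIGHT_PI2 = 8.0 * math.pi**2
_FOUR_PI2 = 4.0 * math.pi**2
#: conversion from resolution d to blur B so that FWHM = d
_B_RES_PER_D2 = _EIGHT_PI2 / (2.0 * math.sqrt(2.0 * math.log(2.0))) ** 2

#: flat background added inside the model mask for X-ray maps
XRAY_SOLVENT_LEVEL = 0.3
_MASK_VDW_SCALE = 1.1
_CUTOFF_SIGMAS = 4.0


@dataclass
class DensityMap:
    """A regular real-space density grid with cubic voxels.

    ``values[i, j, k]`` is the density at Cartesian position
    ``origin + spacing * (i, j, k)``.
    """

    values: np.ndarray
    origin: np.ndarray
    spacing: float
    resolution: float
    mode: str = "xray"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.mode not in ("xray", "em"):
            raise ValueError(f"mode must be 'xray' or 'em', got {self.mode!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")
        if self.spacing > self.resolution / 4.0 + 1e-9:
            warnings.warn(
                f"grid spacing {self.spacing:.3f} coarser than resolution/4 "
                f"({self.resolution / 4:.3f}); sampling may be inadequate",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing * np.arange(n)

    def index_of(self, pos: np.ndarray) -> np.ndarray:
        return (np.asarray(pos, float) - self.origin) / self.spacing

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at Cartesian points (n, 3); 0 outside."""
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            tuple(self.axis_coords(i) for i in range(3)),
            self.values,
            bounds_error=False,
            fill_value=0.0,
        )
        return interp(np.atleast_2d(points))

    def contains(self, pos: np.ndarray, margin: float = 0.0) -> bool:
        pos = np.asarray(pos, float)
        lo = self.origin + margin
        hi = self.origin + self.spacing * (np.array(self.shape) - 1) - margin
        return bool(np.all(pos >= lo - 1e-9) and np.all(pos <= hi + 1e-9))

    def copy(self) -> "DensityMap":
        return DensityMap(
            self.values.copy(), self.origin.copy(), self.spacing, self.resolution, self.mode
        )


@dataclass
class StructureFactors:
    """Amplitude/phase coefficients over a P1 box (half spectrum of an FFT)."""

    hkl: np.ndarray  # (n, 3) int Miller indices
    amplitude: np.ndarray  # (n,) >= 0
    phase: np.ndarray  # (n,) radians
    d_min: float
    cell: np.ndarray  # (3,) box edge lengths, Angstrom
    grid_shape: tuple[int, int, int]  # real-space grid the FFT came from

    def copy(self) -> "StructureFactors":
        return StructureFactors(
            self.hkl.copy(),
            self.amplitude.copy(),
            self.phase.copy(),
            self.d_min,
            self.cell.copy(),
            self.grid_shape,
        )

    def to_half_spectrum(self) -> np.ndarray:
        """Rebuild the rfftn-layout complex array (zeros beyond d_min)."""
        nx, ny, nz = self.grid_shape
        spec = np.zeros((nx, ny, nz // 2 + 1), dtype=complex)
        ix = self.hkl[:, 0] % nx
        iy = self.hkl[:, 1] % ny
        iz = self.hkl[:, 2]
        spec[ix, iy, iz] = self.amplitude * np.exp(1j * self.phase)
        return spec


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    target_resolution: float
    base_resolution: float = 0.8
    shake_scale: float = 0.2
    noise_scale: float = 0.5
    b_inflation_per_tenth_angstrom: float = 1.0
    seed: int = 0
    mode: str = "xray"
    # recorded for provenance; flat-mask bulk solvent is not forward-modelled
    k_sol: float = 0.4
    b_sol: float = 45.0
    box_margin: float = 10.0

    def __post_init__(self) -> None:
        if self.target_resolution < self.base_resolution - 1e-9:
            raise ValueError("target resolution must be >= base model resolution")
        if self.shake_scale < 0 or self.noise_scale < 0:
            raise ValueError("scales must be non-negative")


def resolution_blur_b(resolution: float) -> float:
    """Isotropic blur B (A^2) whose Gaussian FWHM equals the resolution."""
    return _B_RES_PER_D2 * resolution**2


def _scattering_gaussians(element: str, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """(a, b) multi-Gaussian scattering coefficients for one element.

    X-ray mode uses the 4-Gaussian-plus-constant International Tables fit
    (the constant is carried as a fifth Gaussian with b = 0); EM mode uses
    the 5-Gaussian electron scattering fit.
    """
    el = gemmi.Element(element)
    if el.atomic_number == 0:
        raise ValueError(
            f"unknown element {element!r}; supported elements are standard "
            "protein heavy atoms (C, N, O, S) and anything tabulated in the "
            "International Tables scattering coefficient sets"
        )
    if mode == "em":
        coef = el.c4322
        return np.asarray(coef.a, float), np.asarray(coef.b, float)
    coef = el.it92
    a = np.append(np.asarray(coef.a, float), coef.c)
    b = np.append(np.asarray(coef.b, float), 0.0)
    return a, b


from functools import lru_cache


@lru_cache(maxsize=4096)
def _bandlimited_profile(
    element: str, b_total: float, d_min: float, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Radial density profile of one atom low-passed at d_min.

    The scattering transform F(s) = sum_j a_j exp(-(b_j + B) s^2 / 4) is
    inverted with a sharp spherical cutoff at s = 1/d_min:
    rho(r) = int_0^{1/d} 4 pi s^2 F(s) j0(2 pi s r) ds.  This matches the
    representation of a map synthesized by Fourier truncation, ripples
    included.  Returns (r_grid, rho).
    """
    a_coefs, b_coefs = _scattering_gaussians(element, mode)
    widths = b_coefs + b_total
    s_max = 1.0 / d_min
    s = np.linspace(0.0, s_max, 512)
    F = np.zeros_like(s)
    for aj, wj in zip(a_coefs, widths):
        F += aj * np.exp(-wj * s * s / 4.0)
    sigma_max = math.sqrt(max(widths.max(), 1e-6) / _EIGHT_PI2)
    r_cut = _CUTOFF_SIGMAS * sigma_max + 1.5 * d_min
    r = np.arange(0.0, r_cut + 0.02, 0.02)
    x = 2.0 * math.pi * np.outer(s, r)  # (ns, nr)
    j0 = np.ones_like(x)
    nz = x > 1e-12
    j0[nz] = np.sin(x[nz]) / x[nz]
    integrand = (4.0 * math.pi * s * s * F)[:, None] * j0
    rho = np.trapezoid(integrand, s, axis=0)
    return r, rho


def bandlimited_cutoff_radius(
    element: str, b_total: float, d_min: float, mode: str
) -> float:
    r, _ = _bandlimited_profile(element, round(b_total, 1), d_min, mode)
    return float(r[-1])


def _atom_cutoff_radius(
    element: str, b_total: float, mode: str, band_limit: float | None
) -> float:
    a_coefs, b_coefs = _scattering_gaussians(element, mode)
    sigma_max = math.sqrt((b_coefs + b_total).max() / _EIGHT_PI2)
    r_cut = _CUTOFF_SIGMAS * sigma_max
    if band_limit is not None:
        r_cut += 1.5 * band_limit  # low-pass ripples extend past the core
    return r_cut


def _atom_block_density(
    geom_origin: np.ndarray,
    spacing: float,
    lo: np.ndarray,
    hi: np.ndarray,
    pos: np.ndarray,
    element: str,
    b_total: float,
    mode: str,
    band_limit: float | None,
    r_cut: float,
) -> np.ndarray:
    """Density of one atom over the voxel block [lo, hi] (cut beyond r_cut)."""
    axes = [
        geom_origin[i] + spacing * np.arange(lo[i], hi[i] + 1) - pos[i]
        for i in range(3)
    ]
    r2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    if band_limit is not None:
        r_grid, rho = _bandlimited_profile(
            element, round(b_total, 1), band_limit, mode
        )
        dens = np.interp(np.sqrt(r2), r_grid, rho, right=0.0)
    else:
        a_coefs, b_coefs = _scattering_gaussians(element, mode)
        widths = b_coefs + b_total
        dens = np.zeros_like(r2)
        for aj, wj in zip(a_coefs, widths):
            if wj <= 0:
                # zero-width component: a delta function; only nonzero when
                # broadened by B (b_total > 0 in practice)
                continue
            dens += (
                aj * (_FOUR_PI2 / (math.pi * wj)) ** 1.5 * np.exp(-_FOUR_PI2 * r2 / wj)
            )
    dens *= r2 <= r_cut * r_cut
    return dens


def _atom_density_into(
    grid: np.ndarray,
    geom: DensityMap,
    pos: np.ndarray,
    element: str,
    b_total: float,
    weight: float,
    mode: str,
    band_limit: float | None = None,
) -> None:
    """Accumulate one atom's density into *grid* (in place)."""
    r_cut = _atom_cutoff_radius(element, b_total, mode, band_limit)
    idx = geom.index_of(pos)
    lo = np.maximum(np.ceil(idx - r_cut / geom.spacing).astype(int), 0)
    hi = np.minimum(np.floor(idx + r_cut / geom.spacing).astype(int), np.array(grid.shape) - 1)
    if np.any(lo > hi):
        return
    dens = _atom_block_density(
        geom.origin, geom.spacing, lo, hi, pos, element, b_total, mode,
        band_limit, r_cut,
    )
    grid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] += weight * dens


def compute_density(
    conformers: list[Conformer],
    geom: DensityMap,
    resolution: float | None = None,
    mode: str | None = None,
    weights: list[float] | None = None,
    with_background: bool | None = None,
    band_limit: float | None = None,
) -> np.ndarray:
    """Forward density of weighted conformers on the geometry of *geom*.

    Each atom contributes an isotropic multi-Gaussian broadened by
    ``b_iso + resolution blur``, scaled by its occupancy times the optional
    per-conformer weight (default 1: atom occupancies alone carry the
    weighting), truncated beyond 4 sigma.  In X-ray mode (and only there) a
    flat solvent-level background is added inside the model mask; pass
    ``with_background=False`` to disable it (e.g. for fit candidates).
    """
    resolution = geom.resolution if resolution is None else resolution
    mode = geom.mode if mode is None else mode
    if weights is None:
        weights = [1.0] * len(conformers)
    if any(w < 0 for w in weights):
        raise ValueError("conformer weights must be non-negative")
    if with_background is None:
        with_background = mode == "xray"
    b_res = resolution_blur_b(resolution)
    out = np.zeros(geom.shape, dtype=float)
    for conf, w in zip(conformers, weights, strict=True):
        for atom in conf.atoms:
            if atom.is_hydrogen:
                continue
            _atom_density_into(
                out,
                geom,
                atom.pos,
                atom.element,
                atom.b_iso + b_res,
                w * atom.occupancy,
                mode,
                band_limit,
            )
    if with_background and mode == "xray":
        mask = solvent_mask(conformers, geom)
        out += XRAY_SOLVENT_LEVEL * mask
    return out


def density_columns(
    candidates: list[Conformer],
    geom: DensityMap,
    resolution: float | None = None,
    mode: str | None = None,
    band_limit: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-candidate density columns over the union footprint voxel set.

    Returns ``(columns, active)`` where ``active`` holds flat voxel indices
    of the union of the candidates' 4-sigma atom footprints and ``columns``
    is (n_active, n_candidates).  Equivalent to calling
    :func:`compute_density` per candidate and keeping the active rows, but
    without materializing full-grid columns.
    """
    resolution = geom.resolution if resolution is None else resolution
    mode = geom.mode if mode is None else mode
    b_res = resolution_blur_b(resolution)
    shape = geom.shape
    mask = np.zeros(shape, dtype=bool)
    per_atom: list[list[tuple]] = []
    for conf in candidates:
        entries = []
        for atom in conf.atoms:
            if atom.is_hydrogen:
                continue
            b_total = atom.b_iso + b_res
            r_cut = _atom_cutoff_radius(atom.element, b_total, mode, band_limit)
            idx = geom.index_of(atom.pos)
            lo = np.maximum(np.ceil(idx - r_cut / geom.spacing).astype(int), 0)
            hi = np.minimum(
                np.floor(idx + r_cut / geom.spacing).astype(int),
                np.array(shape) - 1,
            )
            if np.any(lo > hi):
                continue
            axes = [
                geom.origin[i] + geom.spacing * np.arange(lo[i], hi[i] + 1) - atom.pos[i]
                for i in range(3)
            ]
            r2 = (
                axes[0][:, None, None] ** 2
                + axes[1][None, :, None] ** 2
                + axes[2][None, None, :] ** 2
            )
            inside = r2 <= r_cut * r_cut
            mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= inside
            entries.append((atom, b_total, r_cut, lo, hi))
        per_atom.append(entries)
    active = np.where(mask.ravel())[0]
    lookup = np.full(int(np.prod(shape)), -1, dtype=np.int64)
    lookup[active] = np.arange(len(active))
    lookup = lookup.reshape(shape)
    columns = np.zeros((len(active), len(candidates)), dtype=np.float64)
    for j, entries in enumerate(per_atom):
        for atom, b_total, r_cut, lo, hi in entries:
            dens = atom.occupancy * _atom_block_density(
                geom.origin, geom.spacing, lo, hi, atom.pos, atom.element,
                b_total, mode, band_limit, r_cut,
            )
            look = lookup[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
            valid = look >= 0
            # voxel indices within one atom block are unique
            columns[look[valid], j] += dens[valid]
    return columns, active


def solvent_mask(conformers: list[Conformer], geom: DensityMap) -> np.ndarray:
    """Boolean model mask: voxels within 1.1x the vdW radius of any heavy atom."""
    from . import residues as res_info

    mask = np.zeros(geom.shape, dtype=bool)
    for conf in conformers:
        for atom in conf.atoms:
            if atom.is_hydrogen:
                continue
            r = _MASK_VDW_SCALE * res_info.VDW_RADII.get(atom.element, 1.7)
            idx = geom.index_of(atom.pos)
            lo = np.maximum(np.ceil(idx - r / geom.spacing).astype(int), 0)
            hi = np.minimum(
                np.floor(idx + r / geom.spacing).astype(int), np.array(geom.shape) - 1
            )
            if np.any(lo > hi):
                continue
            axes = [
                geom.origin[i] + geom.spacing * np.arange(lo[i], hi[i] + 1) - atom.pos[i]
                for i in range(3)
            ]
            r2 = (
                axes[0][:, None, None] ** 2
                + axes[1][None, :, None] ** 2
                + axes[2][None, None, :] ** 2
            )
            mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= r2 <= r * r
    return mask


def extract_residue_subgrid(
    dmap: DensityMap, residue: ResidueModel, padding: float = 5.0
) -> DensityMap:
    """Sub-box of the map covering the residue's atoms plus *padding*.

    Voxel values, spacing and the voxel lattice are preserved exactly; the
    box is clipped at the map bounds (no wrapping).
    """
    lo_pos, hi_pos = residue.coords_bounds()
    center_inside = any(
        dmap.contains(a.pos) for a in residue.all_atoms()
    )
    if not center_inside:
        raise ValueError(
            f"residue {residue.chain}{residue.seq_id} lies outside the map"
        )
    lo = np.floor((lo_pos - padding - dmap.origin) / dmap.spacing).astype(int)
    hi = np.ceil((hi_pos + padding - dmap.origin) / dmap.spacing).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(dmap.shape) - 1)
    values = dmap.values[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    return DensityMap(
        values.copy(),
        dmap.origin + dmap.spacing * lo,
        dmap.spacing,
        dmap.resolution,
        dmap.mode,
    )


def shake_coordinates(model: StructureModel, rmse: float, seed: int) -> StructureModel:
    """Add zero-mean Gaussian noise so the expected per-atom RMS shift is *rmse*."""
    if rmse < 0:
        raise ValueError("rmse must be non-negative")
    out = model.copy()
    if rmse == 0:
        return out
    rng = np.random.default_rng(seed)
    sigma = rmse / math.sqrt(3.0)
    for atom in out.all_atoms():
        atom.pos = atom.pos + rng.normal(0.0, sigma, size=3)
    return out


def inflate_bfactors(
    model: StructureModel,
    base_resolution: float,
    target_resolution: float,
    per_tenth_angstrom: float = 1.0,
) -> StructureModel:
    """Raise all B-factors by ``per_tenth`` A^2 per 0.1 A of resolution loss."""
    if target_resolution < base_resolution - 1e-9:
        raise ValueError("target resolution must be >= base resolution")
    delta = per_tenth_angstrom * (target_resolution - base_resolution) / 0.1
    out = model.copy()
    for atom in out.all_atoms():
        atom.b_iso += delta
        if atom.u_aniso is not None:
            atom.u_aniso = atom.u_aniso + np.eye(3) * delta / _EIGHT_PI2
    return out


def _p1_box(model: StructureModel, margin: float, spacing: float):
    lo, hi = model.coords_bounds()
    origin = lo - margin
    span = hi - lo + 2 * margin
    shape = tuple(int(math.ceil(s / spacing)) for s in span)
    # even dimensions keep FFT index bookkeeping simple
    shape = tuple(n + n % 2 for n in shape)
    return origin, shape


def compute_structure_factors(
    model: StructureModel,
    d_min: float,
    box_margin: float = 10.0,
    spacing: float | None = None,
    mode: str = "xray",
    with_background: bool | None = None,
) -> StructureFactors:
    """FFT of the real-space forward density over a P1 box, cut at d >= d_min."""
    if box_margin < 2.0:
        raise ValueError("box margin too small; model must fit with margin")
    spacing = d_min / 4.0 if spacing is None else spacing
    origin, shape = _p1_box(model, box_margin, spacing)
    geom = DensityMap(
        np.zeros(shape), origin, spacing, resolution=d_min, mode=mode
    )
    conformers = [c for r in model.residues for c in r.conformers]
    rho = compute_density(
        conformers, geom, resolution=d_min, mode=mode, with_background=with_background
    )
    spec = np.fft.rfftn(rho) * geom.voxel_volume
    cell = np.array(shape) * spacing
    nx, ny, nz = shape
    h = np.fft.fftfreq(nx, d=1.0 / nx).astype(int)
    k = np.fft.fftfreq(ny, d=1.0 / ny).astype(int)
    l = np.arange(nz // 2 + 1)
    inv_d2 = (
        (h[:, None, None] / cell[0]) ** 2
        + (k[None, :, None] / cell[1]) ** 2
        + (l[None, None, :] / cell[2]) ** 2
    )
    keep = inv_d2 <= 1.0 / d_min**2 + 1e-12
    hh, kk, ll = np.meshgrid(h, k, l, indexing="ij")
    hkl = np.stack([hh[keep], kk[keep], ll[keep]], axis=1)
    vals = spec[keep]
    return StructureFactors(
        hkl=hkl,
        amplitude=np.abs(vals),
        phase=np.angle(vals),
        d_min=d_min,
        cell=cell,
        grid_shape=shape,
    )


def add_structure_factor_noise(
    sf: StructureFactors, resolution: float, noise_scale: float, seed: int
) -> StructureFactors:
    """Per-reflection amplitude noise ``F + sqrt(F) * eps * resolution * scale``.

    Phases are untouched; negative noisy amplitudes are clamped at zero.
    """
    if np.any(sf.amplitude < 0):
        raise ValueError("amplitudes must be non-negative")
    out = sf.copy()
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(len(out.amplitude))
    out.amplitude = np.maximum(
        out.amplitude + np.sqrt(out.amplitude) * eps * resolution * noise_scale, 0.0
    )
    return out


def make_synthetic_map(
    ground_truth: StructureModel, spec: SyntheticSpec
) -> tuple[DensityMap, StructureModel]:
    """Generate a noisy map from a (multiconformer) ground-truth model.

    Pipeline: inflate B-factors for the resolution loss; shake a copy of the
    coordinates (RMS = shake_scale * target resolution); compute structure
    factors over a P1 box truncated at the target resolution; add amplitude
    noise; invert back to a real-space map.  Returns the map and the
    *unshaken* B-inflated ground truth, which is the comparison reference.
    """
    reference = inflate_bfactors(
        ground_truth,
        spec.base_resolution,
        spec.target_resolution,
        spec.b_inflation_per_tenth_angstrom,
    )
    shaken = shake_coordinates(
        reference, spec.shake_scale * spec.target_resolution, spec.seed
    )
    sf = compute_structure_factors(
        shaken,
        d_min=spec.target_resolution,
        box_margin=spec.box_margin,
        mode=spec.mode,
    )
    sf_noisy = add_structure_factor_noise(
        sf, spec.target_resolution, spec.noise_scale, spec.seed + 1
    )
    spacing = spec.target_resolution / 4.0
    values = (
        np.fft.irfftn(sf_noisy.to_half_spectrum(), s=sf.grid_shape, axes=(0, 1, 2))
        / spacing**3
    )
    origin, _ = _p1_box(shaken, spec.box_margin, spacing)
    dmap = DensityMap(
        values, origin, spacing, resolution=spec.target_resolution, mode=spec.mode
    )
    return dmap, reference


# ---------------------------------------------------------------------------
# CCP4/MRC I/O (mode 2, float32), axis order normalized to X,Y,Z on read


def write_map(dmap: DensityMap, path: str) -> None:
    grid = gemmi.FloatGrid(*dmap.shape)
    cell = np.array(dmap.shape) * dmap.spacing
    grid.set_unit_cell(gemmi.UnitCell(cell[0], cell[1], cell[2], 90, 90, 90))
    arr = np.ascontiguousarray(dmap.values, dtype=np.float32)
    np.asarray(grid)[...] = arr
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    start = np.round(dmap.origin / dmap.spacing).astype(int)
    for w, s in zip((5, 6, 7), start):
        m.set_header_i32(w, int(s))
    # float ORIGIN words (MRC-2014) carry any sub-voxel remainder
    for w, o in zip((50, 51, 52), dmap.origin):
        m.set_header_float(w, float(o))
    m.write_ccp4_map(str(path))


def read_map(path: str, resolution: float, mode: str = "xray") -> DensityMap:
    """Read a CCP4/MRC map; axis order is normalized to X,Y,Z."""
    m = gemmi.read_ccp4_map(str(path))
    word_mode = m.header_i32(4)
    if word_mode != 2:
        raise ValueError(f"unsupported CCP4 mode word {word_mode}; only mode 2")
    start = np.array([m.header_i32(w) for w in (5, 6, 7)], dtype=float)
    forigin = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=float)
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(m.grid, dtype=float)
    cell = m.grid.unit_cell
    spacings = np.array(
        [cell.a / values.shape[0], cell.b / values.shape[1], cell.c / values.shape[2]]
    )
    if np.ptp(spacings) > 0.01 * spacings.mean():
        raise ValueError(
            f"header spacing mismatch with grid dims: voxel sizes {spacings}"
        )
    spacing = float(spacings.mean())
    origin = forigin if np.any(forigin != 0) else start * spacing
    return DensityMap(values, origin, spacing, resolution=resolution, mode=mode)
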