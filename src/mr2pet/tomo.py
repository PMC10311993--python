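"""Attenuated parallel-beam projection and OSEM reconstruction.

This module is a desk-scale stand-in for a vendor PET projector and
reconstructor.  The forward model per axial slice, view angle and detector
bin is

    y = exp(-∫_LOR μ dl) · ∫_LOR x dl + b

where the attenuation line integral runs over the full chord (both
annihilation photons traverse the complete line of response) and b is an
optional additive background sinogram (scatter/randoms are excluded; b
defaults to zero).  Line integrals are computed by ray marching with a step
of half the in-plane voxel size and bilinear interpolation; the operator is
materialized once per (grid, geometry) pair as a sparse matrix, so the
backprojector is its exact adjoint by construction and OSEM updates reduce
to sparse matrix products applied to all slices at once.

Time-of-flight binning, PSF modeling and detector-efficiency normalization
are deliberately out of scope: the quantification experiments in this
package measure attenuation-map effects, which a non-ToF parallel-beam
projector exercises at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, sparse

from .volume import Volume3D, require_same_grid

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...

#: ray-marching step as a fraction of the in-plane voxel size
RAY_STEP_FRACTION = 0.5


@dataclass(frozen=True)
class ProjectionGeometry:
    """Per-slice parallel-beam geometry tied to an image grid.

    Angles are uniform over [0, 180) degrees; detector bins are centred on
    the grid and cover the transverse field of view.
    """

    image_shape: tuple[int, int, int]
    voxel_spacing_mm: tuple[float, float, float]
    n_angles: int = 180
    n_bins: int = 0          # 0 -> derived to cover the slice diagonal
    bin_spacing_mm: float = 0.0  # 0 -> min in-plane voxel spacing

    def __post_init__(self) -> None:
        if self.n_angles < 1:
            raise ValueError("need at least one projection angle")
        if self.bin_spacing_mm == 0.0:
            object.__setattr__(self, "bin_spacing_mm", float(min(self.voxel_spacing_mm[:2])))
        if self.n_bins == 0:
            nx, ny = self.image_shape[:2]
            sx, sy = self.voxel_spacing_mm[:2]
            diag = float(np.hypot(nx * sx, ny * sy))
            object.__setattr__(self, "n_bins", int(np.ceil(diag / self.bin_spacing_mm)) + 1)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * (180.0 / self.n_angles)

    @classmethod
    def for_volume(cls, vol: Volume3D, n_angles: int = 180, **kwargs) -> "ProjectionGeometry":
        return cls(
            image_shape=tuple(int(s) for s in vol.shape),
            voxel_spacing_mm=tuple(float(s) for s in vol.spacing_mm),
            n_angles=n_angles,
            **kwargs,
        )

    def matches_volume(self, vol: Volume3D) -> bool:
        return tuple(vol.shape) == self.image_shape and np.allclose(
            vol.spacing_mm, self.voxel_spacing_mm
        )

    def to_dict(self) -> dict:
        return {
            "image_shape": list(self.image_shape),
            "voxel_spacing_mm": list(self.voxel_spacing_mm),
            "n_angles": self.n_angles,
            "n_bins": self.n_bins,
            "bin_spacing_mm": self.bin_spacing_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionGeometry":
        return cls(
            image_shape=tuple(d["image_shape"]),
            voxel_spacing_mm=tuple(d["voxel_spacing_mm"]),
            n_angles=int(d["n_angles"]),
            n_bins=int(d["n_bins"]),
            bin_spacing_mm=float(d["bin_spacing_mm"]),
        )


@dataclass
class Sinogram:
    """Projection data: array (slice, angle, bin) plus geometry and background."""

    data: np.ndarray
    geometry: ProjectionGeometry
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        expected = (self.geometry.image_shape[2], self.geometry.n_angles, self.geometry.n_bins)
        if self.data.shape != expected:
            raise ValueError(f"sinogram shape {self.data.shape} != geometry {expected}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram data must be finite")
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=np.float64)
            if self.background.shape != self.data.shape:
                raise ValueError("background shape must match sinogram data")

    def copy(self) -> "Sinogram":
        return Sinogram(
            self.data.copy(),
            self.geometry,
            None if self.background is None else self.background.copy(),
        )

    def save(self, path: str | Path) -> Path:
        """Compressed array container with a JSON geometry header."""
        path = Path(path)
        arrays = {"data": self.data, "geometry_json": np.frombuffer(
            json.dumps(self.geometry.to_dict()).encode(), dtype=np.uint8)}
        if self.background is not None:
            arrays["background"] = self.background
        np.savez_compressed(path, **arrays)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "Sinogram":
        with np.load(path) as f:
            geom = ProjectionGeometry.from_dict(
                json.loads(bytes(f["geometry_json"]).decode()))
            bg = f["background"] if "background" in f else None
            return cls(f["data"].copy(), geom, None if bg is None else bg.copy())


# ---------------------------------------------------------------------
# sparse per-slice system matrix
# ---------------------------------------------------------------------

_MATRIX_CACHE: dict[tuple, sparse.csr_matrix] = {}


def slice_system_matrix(geom: ProjectionGeometry) -> sparse.csr_matrix:
    """Unattenuated line-integration operator for one axial slice.

    Rows are (angle, bin) pairs in C order, columns are in-plane voxels
    ``i*ny + j``.  Entries are bilinear interpolation weights times the
    marching step length (mm), so ``P @ x`` is a discrete line integral in
    mm.  Cached per geometry.
    """
    key = (geom.image_shape[:2], geom.voxel_spacing_mm[:2],
           geom.n_angles, geom.n_bins, geom.bin_spacing_mm)
    if key in _MATRIX_CACHE:
        return _MATRIX_CACHE[key]

    nx, ny = geom.image_shape[:2]
    sx, sy = geom.voxel_spacing_mm[:2]
    cx, cy = nx * sx / 2.0, ny * sy / 2.0
    half_diag = 0.5 * float(np.hypot(nx * sx, ny * sy))
    step = RAY_STEP_FRACTION * min(sx, sy)
    n_steps = int(np.ceil(2.0 * (half_diag + step) / step))
    t = (np.arange(n_steps) + 0.5) * step - (n_steps * step) / 2.0

    offsets = (np.arange(geom.n_bins) - (geom.n_bins - 1) / 2.0) * geom.bin_spacing_mm

    rows_all, cols_all, vals_all = [], [], []
    for a, theta in enumerate(np.deg2rad(geom.angles_deg)):
        d = np.array([np.cos(theta), np.sin(theta)])
        n = np.array([-np.sin(theta), np.cos(theta)])
        # sample points for all (bin, step) pairs
        px = cx + offsets[:, None] * n[0] + t[None, :] * d[0]
        py = cy + offsets[:, None] * n[1] + t[None, :] * d[1]
        gx = px / sx - 0.5
        gy = py / sy - 0.5
        i0 = np.floor(gx).astype(np.int64)
        j0 = np.floor(gy).astype(np.int64)
        fx = gx - i0
        fy = gy - j0
        ray_index = np.broadcast_to(np.arange(geom.n_bins)[:, None], gx.shape)
        for di, dj, w in (
            (0, 0, (1 - fx) * (1 - fy)),
            (1, 0, fx * (1 - fy)),
            (0, 1, (1 - fx) * fy),
            (1, 1, fx * fy),
        ):
            ii = i0 + di
            jj = j0 + dj
            ok = (ii >= 0) & (ii < nx) & (jj >= 0) & (jj < ny) & (w > 0)
            rows_all.append(a * geom.n_bins + ray_index[ok])
            cols_all.append(ii[ok] * ny + jj[ok])
            vals_all.append(w[ok] * step)

    P = sparse.coo_matrix(
        (np.concatenate(vals_all),
         (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(geom.n_angles * geom.n_bins, nx * ny),
    ).tocsr()
    P.sum_duplicates()
    _MATRIX_CACHE[key] = P
    return P


def _as_slice_stack(vol: Volume3D) -> np.ndarray:
    """(nx, ny, nz) volume -> (nx*ny, nz) column-per-slice matrix."""
    nx, ny, nz = vol.shape
    return np.asarray(vol.data, dtype=np.float64).reshape(nx * ny, nz)


def _rays_to_sino(rays: np.ndarray, geom: ProjectionGeometry) -> np.ndarray:
    """(n_angles*n_bins, nz) ray values -> (nz, n_angles, n_bins)."""
    return rays.reshape(geom.n_angles, geom.n_bins, -1).transpose(2, 0, 1)


def _sino_to_rays(data: np.ndarray, geom: ProjectionGeometry) -> np.ndarray:
    return data.transpose(1, 2, 0).reshape(geom.n_angles * geom.n_bins, -1)


def attenuation_factors(mu: Volume3D, geom: ProjectionGeometry) -> np.ndarray:
    """exp(-∫ μ dl) per (angle·bin, slice); μ in per-mm units."""
    if not geom.matches_volume(mu):
        raise ValueError("attenuation map grid does not match geometry")
    P = slice_system_matrix(geom)
    return np.exp(-(P @ _as_slice_stack(mu)))


def forward_project(
    activity: Volume3D,
    mu: Volume3D | None,
    geom: ProjectionGeometry,
    background: Sinogram | None = None,
) -> Sinogram:
    """Attenuated forward projection of an activity volume.

    ``mu=None`` projects without attenuation.  ``background`` (the b term)
    is added to the attenuated line integrals; it must share the geometry.
    """
    if not geom.matches_volume(activity):
        raise ValueError("activity grid does not match geometry")
    if np.any(activity.data < 0):
        raise ValueError("activity must be nonnegative")
    if mu is not None:
        require_same_grid(activity, mu)
        if np.any(mu.data < 0):
            raise ValueError("attenuation map must be nonnegative")
    P = slice_system_matrix(geom)
    rays = P @ _as_slice_stack(activity)
    if mu is not None:
        rays = attenuation_factors(mu, geom) * rays
    data = _rays_to_sino(rays, geom)
    if background is not None:
        if background.data.shape != data.shape:
            raise ValueError("background sinogram shape mismatch")
        data = data + background.data
        return Sinogram(data, geom, background=background.data.copy())
    return Sinogram(data, geom)


def back_project(sino: Sinogram, geom: ProjectionGeometry | None = None) -> Volume3D:
    """Exact adjoint of the unattenuated line-integration operator."""
    geom = geom or sino.geometry
    if geom.to_dict() != sino.geometry.to_dict():
        raise ValueError("sinogram geometry does not match requested geometry")
    P = slice_system_matrix(geom)
    vols = P.T @ _sino_to_rays(sino.data, geom)
    nx, ny, nz = geom.image_shape
    return Volume3D(vols.reshape(nx, ny, nz), geom.voxel_spacing_mm, "suv")


@dataclass(frozen=True)
class ReconConfig:
    """OSEM reconstruction parameters (clinical-style defaults)."""

    subsets: int = 28
    iterations: int = 2
    filter_fwhm_transverse_mm: float = 2.0
    filter_fwhm_axial_mm: float = 4.0
    matrix: tuple[int, int] = (256, 256)
    fov_mm: float = 600.0

    def __post_init__(self) -> None:
        if self.subsets < 1 or self.iterations < 1:
            raise ValueError("subsets and iterations must be >= 1")
        if self.filter_fwhm_transverse_mm < 0 or self.filter_fwhm_axial_mm < 0:
            raise ValueError("filter FWHM must be nonnegative")


def _subset_rows(geom: ProjectionGeometry, n_subsets: int) -> list[np.ndarray]:
    """Interleaved angle subsets; unequal sizes allowed when subsets do not
    divide the angle count."""
    n_subsets = min(n_subsets, geom.n_angles)
    out = []
    for s in range(n_subsets):
        angles = np.arange(s, geom.n_angles, n_subsets)
        rows = (angles[:, None] * geom.n_bins + np.arange(geom.n_bins)[None, :]).ravel()
        out.append(rows)
    return out


def osem_reconstruct(
    sino: Sinogram,
    mu_ac: Volume3D | None,
    geom: ProjectionGeometry | None = None,
    cfg: ReconConfig = ReconConfig(),
) -> Volume3D:
    """Ordered-subset EM reconstruction with attenuation in the system model.

    Multiplicative updates with the attenuation factors from ``mu_ac``
    folded into the system matrix; the image is initialized to a uniform
    positive value, voxels with zero sensitivity are frozen at 0, and the
    result is Gaussian post-filtered per the configuration.
    """
    if np.any(sino.data < 0):
        raise ValueError("sinogram must be nonnegative")
    geom = geom or sino.geometry
    P = slice_system_matrix(geom)
    atten = attenuation_factors(mu_ac, geom) if mu_ac is not None else \
        np.ones((geom.n_angles * geom.n_bins, geom.image_shape[2]))
    y = _sino_to_rays(sino.data, geom)
    b = _sino_to_rays(sino.background, geom) if sino.background is not None else 0.0

    nx, ny, nz = geom.image_shape
    X = np.ones((nx * ny, nz), dtype=np.float64)
    total_sens = P.T @ atten
    X[total_sens <= 0] = 0.0

    subsets = _subset_rows(geom, cfg.subsets)
    Ps = [P[rows] for rows in subsets]
    tiny = 1e-30
    for _ in range(cfg.iterations):
        for rows, P_s in zip(subsets, Ps):
            a_s = atten[rows]
            y_s = y[rows]
            b_s = b[rows] if isinstance(b, np.ndarray) else 0.0
            fwd = a_s * (P_s @ X) + b_s
            ratio = np.where(fwd > tiny, y_s / np.maximum(fwd, tiny), 0.0)
            sens = P_s.T @ a_s
            upd = P_s.T @ (a_s * ratio)
            X *= np.where(sens > 0, upd / np.maximum(sens, tiny), 1.0)
    vol = Volume3D(X.reshape(nx, ny, nz), geom.voxel_spacing_mm, "suv")
    if cfg.filter_fwhm_transverse_mm > 0 or cfg.filter_fwhm_axial_mm > 0:
        vol = gaussian_postfilter(
            vol, cfg.filter_fwhm_transverse_mm, cfg.filter_fwhm_axial_mm)
    return vol


def gaussian_postfilter(
    vol: Volume3D,
    fwhm_transverse_mm: float,
    fwhm_axial_mm: float,
) -> Volume3D:
    """Separable Gaussian smoothing; σ = FWHM / 2.3548 per axis, 0 = identity."""
    if fwhm_transverse_mm < 0 or fwhm_axial_mm < 0:
        raise ValueError("FWHM must be nonnegative")
    if fwhm_transverse_mm == 0 and fwhm_axial_mm == 0:
        return vol.copy()
    sx, sy, sz = vol.spacing_mm
    sigma = (
        fwhm_transverse_mm / FWHM_TO_SIGMA / sx,
        fwhm_transverse_mm / FWHM_TO_SIGMA / sy,
        fwhm_axial_mm / FWHM_TO_SIGMA / sz,
    )
    return vol.with_data(ndimage.gaussian_filter(np.asarray(vol.data, float), sigma))


def hu_to_mu511(ct_hu: Volume3D, mu_water: float = 0.0096, mu_bone_1000hu: float = 0.0150) -> Volume3D:
    """Bilinear CT-number to 511-keV attenuation conversion (per mm).

    Below 0 HU: μ = μ_water · (1 + HU/1000), clamped at zero.  Above 0 HU
    the slope follows the bone segment so that 1000 HU maps to the default
    cortical-bone coefficient; at 511 keV the bone segment is shallower
    than a water-scaled extrapolation, as in standard bilinear curves.
    """
    hu = np.asarray(ct_hu.data, dtype=np.float64)
    if not np.all(np.isfinite(hu)):
        raise ValueError("CT volume must be finite")
    mu = np.where(
        hu <= 0.0,
        mu_water * (1.0 + hu / 1000.0),
        mu_water + hu * (mu_bone_1000hu - mu_water) / 1000.0,
    )
    return ct_hu.with_data(np.clip(mu, 0.0, None), "mu_per_mm")


def poisson_sample(sino: Sinogram, seed: int, counts_scale: float = 1.0) -> Sinogram:
    """Optional Poisson resampling of a sinogram (off by default in pipelines).

    Values are scaled by ``counts_scale``, Poisson-sampled, and scaled back,
    emulating count statistics that the noiseless forward model omits.
    """
    if counts_scale <= 0:
        raise ValueError("counts_scale must be positive")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(np.clip(sino.data, 0, None) * counts_scale) / counts_scale
    return Sinogram(noisy.astype(np.float64), sino.geometry, sino.background)
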