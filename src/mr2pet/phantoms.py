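"""Seeded digital phantoms: paired pseudo-MRI, pseudo-PET, and attenuation maps.

Each phantom is an elliptical "body" containing randomly placed ellipsoidal
organs whose uptake spans the disparate SUV ranges seen in whole-body FDG
exams — near-zero background, moderate-uptake organs of a few SUV, and hot
structures above 20 SUV (brain/bladder-like) — plus a bone structure with
high 511-keV attenuation and a lungs-like low-attenuation region.  The MRI
channel is an affine function of the tissue label modulated by a smooth
multiplicative bias field and additive noise: structurally correlated with
uptake but not determined by it (one organ per case receives uptake drawn
independently of its MR intensity, emulating variable-uptake organs such as
heart and bladder).

A CT-derived attenuation map (mu_ct) assigns literature-scale linear
attenuation coefficients at 511 keV, and a degraded "MRAC" map (mu_mrac)
reassigns bone to soft tissue, the characteristic failure mode of 2-point
Dixon MR-based attenuation correction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volume import Volume3D, require_same_grid, voxel_centers_mm

logger = logging.getLogger(__name__)

# -- tissue label codes ------------------------------------------------
AIR, SOFT, LUNG, BONE = 0, 1, 2, 3
ORGAN_BASE = 4  # organs are labelled ORGAN_BASE, ORGAN_BASE+1, ...

#: default linear attenuation coefficients at 511 keV (per mm),
#: literature-scale constants (configurable via the ``mu_table`` argument)
MU_DEFAULTS = {"air": 0.0, "lung": 0.0030, "soft": 0.0096, "bone": 0.0150}

#: default SUV histogram bin edges (last bin open-ended); see losses module
DEFAULT_BIN_EDGES = (0.0, 1.0, 4.0, 10.0, 20.0)

MIN_SHAPE = 32

# organ uptake anchor levels chosen so every default SUV bin is populated:
# background soft tissue sits in [0,1), and the anchor organs cover [1,4),
# [4,10), [10,20) and the open [20, inf) bin (hot brain/bladder-like
# structure).  One organ per case is "variable" and draws its uptake
# independently; the anchors are assigned to the remaining organs.
_ORGAN_SUV_LEVELS = (2.5, 6.5, 14.0, 26.0)
_SOFT_SUV = 0.35
_LUNG_SUV = 0.20
_BONE_SUV = 0.55

# MR intensity per label (arbitrary units); organs get distinct values
_MR_LEVELS = {AIR: 0.0, SOFT: 0.45, LUNG: 0.12, BONE: 0.25}
_ORGAN_MR_LEVELS = (0.75, 0.60, 0.90, 0.35, 0.55, 0.68, 0.82)


@dataclass
class PhantomCase:
    """One paired pseudo-MRI / pseudo-PET / attenuation-map phantom."""

    mri: Volume3D
    pet_truth: Volume3D
    mu_ct: Volume3D
    mu_mrac: Volume3D
    body_mask: Volume3D
    tissue_labels: Volume3D
    seed: int

    def validate(self) -> None:
        """Assert the construction invariants; raises ``AssertionError``."""
        require_same_grid(
            self.mri, self.pet_truth, self.mu_ct, self.mu_mrac,
            self.body_mask, self.tissue_labels,
        )
        pet = self.pet_truth.data
        body = self.body_mask.data.astype(bool)
        assert np.all(pet >= 0), "pet_truth must be nonnegative"
        assert np.all(pet[~body] == 0), "pet_truth must vanish outside the body"
        assert np.all(self.mu_ct.data >= self.mu_mrac.data - 1e-12), \
            "mu_mrac may only remove/reduce attenuation"
        counts, _ = suv_bin_counts(pet, DEFAULT_BIN_EDGES, mask=body)
        assert np.all(counts > 0), f"empty SUV bin(s): counts={counts}"

    def save(self, directory: str | Path) -> Path:
        """Write the case as NIfTI files plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.mri.to_nifti(directory / "mri.nii.gz")
        self.pet_truth.to_nifti(directory / "pet.nii.gz")
        self.mu_ct.to_nifti(directory / "mu_ct.nii.gz")
        self.mu_mrac.to_nifti(directory / "mu_mrac.nii.gz")
        self.body_mask.to_nifti(directory / "mask.nii.gz")
        self.tissue_labels.to_nifti(directory / "labels.nii.gz")
        sidecar = {
            "seed": int(self.seed),
            "spacing_mm": list(self.mri.spacing_mm),
            "tissue_table": {
                "air": AIR, "soft": SOFT, "lung": LUNG, "bone": BONE,
                "organ_base": ORGAN_BASE,
            },
        }
        (directory / "case.json").write_text(json.dumps(sidecar, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "PhantomCase":
        directory = Path(directory)
        sidecar = json.loads((directory / "case.json").read_text())
        return cls(
            mri=Volume3D.from_nifti(directory / "mri.nii.gz", "arbitrary"),
            pet_truth=Volume3D.from_nifti(directory / "pet.nii.gz", "suv"),
            mu_ct=Volume3D.from_nifti(directory / "mu_ct.nii.gz", "mu_per_mm"),
            mu_mrac=Volume3D.from_nifti(directory / "mu_mrac.nii.gz", "mu_per_mm"),
            body_mask=Volume3D.from_nifti(directory / "mask.nii.gz", "mask"),
            tissue_labels=Volume3D.from_nifti(directory / "labels.nii.gz", "label"),
            seed=int(sidecar["seed"]),
        )


def suv_bin_counts(
    pet: np.ndarray,
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel counts per SUV bin; the last bin is open-ended ([edges[-1], inf))."""
    vals = pet[mask] if mask is not None else pet.ravel()
    full_edges = np.concatenate([np.asarray(edges, float), [np.inf]])
    counts, _ = np.histogram(vals, bins=full_edges)
    return counts, full_edges


def _ellipsoid_mask(
    shape: Sequence[int],
    spacing: Sequence[float],
    center_mm: np.ndarray,
    semi_axes_mm: np.ndarray,
) -> np.ndarray:
    cx, cy, cz = voxel_centers_mm(shape, spacing)
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    return (
        ((X - center_mm[0]) / semi_axes_mm[0]) ** 2
        + ((Y - center_mm[1]) / semi_axes_mm[1]) ** 2
        + ((Z - center_mm[2]) / semi_axes_mm[2]) ** 2
    ) <= 1.0


def generate_phantom(
    seed: int,
    shape: Sequence[int] = (96, 96, 48),
    spacing_mm: float | Sequence[float] = 2.0,
    n_organs: int = 5,
    mri_noise_sigma: float = 0.02,
    mu_table: dict[str, float] | None = None,
) -> PhantomCase:
    """Generate one deterministic phantom case.

    Parameters
    ----------
    seed:
        Seed for the generator; identical seeds give voxel-identical cases.
    shape:
        Grid dimensions; every axis must be at least 32 voxels.
    spacing_mm:
        Isotropic (scalar) or per-axis voxel spacing in mm.
    n_organs:
        Number of organ ellipsoids (at least 5, so uptake covers every
        default SUV bin).
    mri_noise_sigma:
        Standard deviation of the additive i.i.d. MR noise.
    mu_table:
        Override for the 511-keV attenuation constants (keys: air, lung,
        soft, bone; units per mm).
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < MIN_SHAPE for s in shape):
        raise ValueError(f"phantom shape must be >= {MIN_SHAPE} voxels per axis, got {shape}")
    spacing = np.atleast_1d(np.asarray(spacing_mm, float))
    if spacing.size == 1:
        spacing = np.repeat(spacing, 3)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    if n_organs < 5:
        raise ValueError("need at least 5 organs to cover the default SUV bins")
    mu = dict(MU_DEFAULTS)
    if mu_table:
        mu.update(mu_table)

    rng = np.random.default_rng(seed)
    extent_mm = np.asarray(shape) * spacing

    labels = np.full(shape, AIR, dtype=np.int16)

    # elliptical body filling most of the grid
    body_center = extent_mm / 2
    body_axes = extent_mm * rng.uniform(0.38, 0.44, size=3)
    body = _ellipsoid_mask(shape, spacing, body_center, body_axes)
    labels[body] = SOFT

    # lungs-like low-attenuation region: two ellipsoids in the upper body
    lung_offset = body_axes * np.array([0.35, 0.0, 0.45])
    lung_axes = body_axes * np.array([0.22, 0.30, 0.28])
    for side in (-1.0, 1.0):
        c = body_center + side * np.array([lung_offset[0], 0.0, 0.0]) \
            + np.array([0.0, 0.0, lung_offset[2]])
        m = _ellipsoid_mask(shape, spacing, c, lung_axes) & body
        labels[m] = LUNG

    # bone: spine-like vertical cylinder (ellipsoid elongated along z)
    bone_center = body_center + np.array([0.0, -0.45 * body_axes[1], 0.0])
    bone_axes = np.array([0.10 * body_axes[0], 0.10 * body_axes[1], 0.85 * body_axes[2]])
    bone = _ellipsoid_mask(shape, spacing, bone_center, bone_axes) & body
    labels[bone] = BONE

    # organ ellipsoids with rejection sampling to avoid mutual overlap and
    # to stay inside the body and clear of bone/lung
    organ_radii_frac = rng.uniform(0.10, 0.18, size=n_organs)
    placed: list[tuple[np.ndarray, float]] = []
    for k in range(n_organs):
        r_mm = organ_radii_frac[k] * float(np.min(body_axes))
        axes_k = r_mm * rng.uniform(0.8, 1.25, size=3)
        ok = False
        for _ in range(200):
            u = rng.uniform(-0.7, 0.7, size=3)
            c = body_center + u * body_axes
            if any(np.linalg.norm(c - pc) < 1.15 * (r_mm + pr) for pc, pr in placed):
                continue
            m = _ellipsoid_mask(shape, spacing, c, axes_k)
            if not m.any():
                continue
            region = labels[m]
            if np.all(region == SOFT):  # inside body, clear of lung/bone/organs
                labels[m] = ORGAN_BASE + k
                placed.append((c, float(np.max(axes_k))))
                ok = True
                break
        if not ok:
            # fall back: shrink and drop the overlap constraint against organs
            axes_k = axes_k * 0.6
            for _ in range(400):
                u = rng.uniform(-0.6, 0.6, size=3)
                c = body_center + u * body_axes
                m = _ellipsoid_mask(shape, spacing, c, axes_k)
                if m.any() and np.all(labels[m] == SOFT):
                    labels[m] = ORGAN_BASE + k
                    placed.append((c, float(np.max(axes_k))))
                    ok = True
                    break
        if not ok:
            raise RuntimeError(f"could not place organ {k}; grid too small for n_organs={n_organs}")

    body_mask = labels != AIR

    # -- PET uptake (SUV), piecewise constant --------------------------
    pet = np.zeros(shape, dtype=np.float64)
    pet[labels == SOFT] = _SOFT_SUV
    pet[labels == LUNG] = _LUNG_SUV
    pet[labels == BONE] = _BONE_SUV
    # one organ's uptake is drawn independently of its MR intensity; the
    # remaining organs carry the anchor levels (with small in-bin jitter)
    # so each of the bins [1,4), [4,10), [10,20), [20,inf) stays populated
    variable_organ = int(rng.integers(0, n_organs))
    organ_suv = np.empty(n_organs, dtype=float)
    anchor = 0
    for k in range(n_organs):
        if k == variable_organ:
            organ_suv[k] = rng.uniform(1.5, 28.0)
        else:
            level = _ORGAN_SUV_LEVELS[anchor % len(_ORGAN_SUV_LEVELS)]
            organ_suv[k] = level * float(rng.uniform(0.96, 1.04))
            if level == _ORGAN_SUV_LEVELS[-1]:
                organ_suv[k] = max(organ_suv[k], DEFAULT_BIN_EDGES[-1] + 1.0)
            anchor += 1
    for k in range(n_organs):
        pet[labels == ORGAN_BASE + k] = organ_suv[k]
    pet[~body_mask] = 0.0

    # -- attenuation maps ----------------------------------------------
    mu_ct = np.full(shape, mu["air"], dtype=np.float64)
    mu_ct[labels == SOFT] = mu["soft"]
    mu_ct[labels >= ORGAN_BASE] = mu["soft"]
    mu_ct[labels == LUNG] = mu["lung"]
    mu_ct[labels == BONE] = mu["bone"]

    # -- MRI: affine in label, smooth multiplicative bias, additive noise
    mr_base = np.zeros(shape, dtype=np.float64)
    for lbl, val in _MR_LEVELS.items():
        mr_base[labels == lbl] = val
    for k in range(n_organs):
        mr_base[labels == ORGAN_BASE + k] = _ORGAN_MR_LEVELS[k % len(_ORGAN_MR_LEVELS)]
    bias = rng.standard_normal(shape)
    sigma_vox = 12.0 / spacing  # ~12 mm correlation length
    bias = ndimage.gaussian_filter(bias, sigma=sigma_vox)
    bias = 1.0 + 0.15 * bias / max(float(np.std(bias)), 1e-12)
    mri = mr_base * bias + mri_noise_sigma * rng.standard_normal(shape)
    mri = np.clip(mri, 0.0, None)
    mri[~body_mask] *= 0.05  # faint air background

    sp = tuple(float(s) for s in spacing)
    labels_vol = Volume3D(labels, sp, "label")
    mu_ct_vol = Volume3D(mu_ct, sp, "mu_per_mm")
    mu_mrac_vol = degrade_to_mrac(mu_ct_vol, labels_vol, soft_mu=mu["soft"])
    case = PhantomCase(
        mri=Volume3D(mri, sp, "arbitrary"),
        pet_truth=Volume3D(pet, sp, "suv"),
        mu_ct=mu_ct_vol,
        mu_mrac=mu_mrac_vol,
        body_mask=Volume3D(body_mask.astype(np.uint8), sp, "mask"),
        tissue_labels=labels_vol,
        seed=int(seed),
    )
    return case


def degrade_to_mrac(
    mu_ct: Volume3D,
    tissue_labels: Volume3D,
    soft_mu: float = MU_DEFAULTS["soft"],
) -> Volume3D:
    """Emulate Dixon-style MR attenuation maps: bone is misassigned soft tissue.

    Bone has high 511-keV attenuation but a rapid T2 decay, so 2-point Dixon
    segmentation cannot see it; the degraded map therefore replaces the bone
    attenuation coefficient with the soft-tissue value and leaves every other
    voxel untouched.
    """
    require_same_grid(mu_ct, tissue_labels)
    out = mu_ct.data.astype(np.float64).copy()
    bone = tissue_labels.data == BONE
    if not bone.any():
        logger.warning("degrade_to_mrac: no bone voxels in label volume; returning input unchanged")
        return mu_ct.with_data(out, "mu_per_mm")
    out[bone] = soft_mu
    return mu_ct.with_data(out, "mu_per_mm")


def make_cohort(
    n: int,
    base_seed: int,
    shape: Sequence[int] = (96, 96, 48),
    spacing_mm: float | Sequence[float] = 2.0,
    **kwargs,
) -> list[PhantomCase]:
    """Generate ``n`` cases with seeds ``base_seed .. base_seed+n-1``."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    return [
        generate_phantom(base_seed + i, shape=shape, spacing_mm=spacing_mm, **kwargs)
        for i in range(n)
    ]
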