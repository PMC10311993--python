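"""Preprocessing: SUV conversion, MRI contrast normalization, resampling.

Raw PET activity concentration (Bq/mL) is converted to the standardized
uptake value, SUV = activity × body weight / decay-corrected injected dose,
using the SUV-bw convention with half-life decay ``2^(-Δt/T½)`` applied to
the injected dose.  MRI volumes are normalized with contrast-limited
adaptive histogram equalization (CLAHE) so structures are identifiable
across scanners, and all volumes can be resampled to an isotropic grid
(1 mm by default) prior to patch-based inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure

from .volume import Volume3D


@dataclass(frozen=True)
class SUVParams:
    """Quantities required for SUV conversion.

    injected_dose_bq:
        Injected activity at injection time (Bq).
    body_weight_kg:
        Patient body weight (kg).
    half_life_s:
        Radionuclide half-life (s); 6586.2 s for F-18.
    elapsed_time_s:
        Time from injection to acquisition (s).
    positron_fraction:
        Branching ratio of positron emission in (0, 1]; only used when
        converting counts-mode data to Bq/mL via ``calibration_factor``.
    """

    injected_dose_bq: float
    body_weight_kg: float
    half_life_s: float = 6586.2
    elapsed_time_s: float = 0.0
    positron_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.injected_dose_bq <= 0 or self.body_weight_kg <= 0 or self.half_life_s <= 0:
            raise ValueError("dose, weight and half-life must be positive")
        if self.elapsed_time_s < 0:
            raise ValueError("elapsed time must be nonnegative")
        if not (0.0 < self.positron_fraction <= 1.0):
            raise ValueError("positron fraction must lie in (0, 1]")

    @property
    def decayed_dose_bq(self) -> float:
        """Injected dose decay-corrected to acquisition time."""
        return self.injected_dose_bq * 2.0 ** (-self.elapsed_time_s / self.half_life_s)


def activity_to_suv(
    activity: Volume3D,
    params: SUVParams,
    counts_mode: bool = False,
    calibration_factor: float = 1.0,
) -> Volume3D:
    """Convert activity concentration (Bq/mL) to SUV.

    SUV(v) = activity(v) · (weight_kg · 1000 g/kg) / (dose_Bq · 2^(−Δt/T½)).

    When ``counts_mode`` is set, voxel values are first divided by the
    positron fraction and the scanner ``calibration_factor`` to obtain
    Bq/mL; the calibration factor is a configuration input because the
    counts→Bq/mL chain is scanner-specific.
    """
    data = np.asarray(activity.data, dtype=np.float64)
    if np.any(data < 0):
        raise ValueError("activity must be nonnegative")
    if counts_mode:
        if calibration_factor <= 0:
            raise ValueError("calibration factor must be positive")
        data = data / (params.positron_fraction * calibration_factor)
    suv = data * (params.body_weight_kg * 1000.0) / params.decayed_dose_bq
    return activity.with_data(suv, "suv")


def clahe_normalize(
    mri: Volume3D,
    kernel_mm: float = 100.0,
    clip_limit: float = 0.05,
) -> Volume3D:
    """Contrast-limited adaptive histogram equalization of an MRI volume.

    The tile size is ``round(kernel_mm / spacing)`` voxels per axis (3-D
    tiles with trilinear blending between tile mappings); output is scaled
    to [0, 1].  A constant input is returned as a constant volume.
    """
    data = np.asarray(mri.data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("MRI volume must be finite")
    if kernel_mm < max(mri.spacing_mm):
        raise ValueError("CLAHE kernel must be at least one voxel")
    lo, hi = float(data.min()), float(data.max())
    if hi - lo < 1e-12:
        # constant image: histogram equalization is undefined; pass through
        # as a constant mid-range volume
        return mri.with_data(np.full_like(data, 0.5), "arbitrary")
    scaled = (data - lo) / (hi - lo)
    kernel = tuple(
        int(np.clip(round(kernel_mm / s), 1, n))
        for s, n in zip(mri.spacing_mm, mri.shape)
    )
    out = exposure.equalize_adapthist(scaled, kernel_size=kernel, clip_limit=clip_limit)
    return mri.with_data(np.clip(out, 0.0, 1.0), "arbitrary")


def resample_isotropic(
    vol: Volume3D,
    target_mm: float = 1.0,
    mode: str = "linear",
) -> Volume3D:
    """Resample to an isotropic grid with ``target_mm`` spacing.

    ``mode='linear'`` (trilinear) for intensity volumes, ``mode='nearest'``
    for masks and label maps.  The world-space extent is preserved to
    within one voxel; a volume already on the target grid is returned
    unchanged.
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    spacing = np.asarray(vol.spacing_mm, float)
    if np.allclose(spacing, target_mm):
        return vol.copy()
    zoom = spacing / target_mm
    order = 1 if mode == "linear" else 0
    data = ndimage.zoom(
        np.asarray(vol.data, dtype=np.float64 if mode == "linear" else vol.data.dtype),
        zoom=zoom,
        order=order,
        mode="nearest",
        grid_mode=True,
    )
    out = Volume3D(data, (target_mm,) * 3, vol.units)
    return out


def split_cohort(
    case_ids: list,
    n_train: int,
    n_test: int,
    n_validation: int = 0,
    seed: int = 0,
) -> dict[str, list]:
    """Seeded train/test/validation split over a cohort manifest.

    Mirrors the study-style 40/16/20 exam split as a config-driven utility;
    the three counts must not exceed the cohort size.
    """
    total = n_train + n_test + n_validation
    if total > len(case_ids):
        raise ValueError(f"split {n_train}+{n_test}+{n_validation} exceeds cohort of {len(case_ids)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(case_ids)))
    ids = [case_ids[i] for i in order]
    return {
        "train": ids[:n_train],
        "test": ids[n_train:n_train + n_test],
        "validation": ids[n_train + n_test:total],
    }
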