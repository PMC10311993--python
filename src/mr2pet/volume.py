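"""3-D scalar volumes with voxel spacing and a units tag.

``Volume3D`` is the package's canonical in-memory container: a float (or
integer, for masks/labels) array indexed ``(x, y, z)`` with isotropic or
anisotropic voxel spacing in millimetres and a ``units`` tag recording what
the voxel values mean (MR arbitrary units, SUV, linear attenuation per mm,
or a binary/integer mask).  I/O goes through nibabel so volumes round-trip
as ordinary NIfTI files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

#: recognised values for :attr:`Volume3D.units`
UNITS = ("arbitrary", "suv", "mu_per_mm", "mask", "label", "bq_per_ml")


@dataclass
class Volume3D:
    """A 3-D scalar field plus voxel spacing (mm) and a units tag."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D requires a 3-D array, got ndim={self.data.ndim}")
        spacing = tuple(float(s) for s in np.atleast_1d(self.spacing_mm).ravel())
        if len(spacing) == 1:
            spacing = spacing * 3
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing_mm must be 3 positive floats, got {self.spacing_mm!r}")
        self.spacing_mm = spacing
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {UNITS}")

    # -- convenience ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def same_grid(self, other: "Volume3D", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing_mm, other.spacing_mm, atol=atol
        )

    def with_data(self, data: np.ndarray, units: str | None = None) -> "Volume3D":
        """New volume on this grid holding ``data`` (units default: unchanged)."""
        return replace(self, data=np.asarray(data), units=units or self.units)

    def copy(self) -> "Volume3D":
        return replace(self, data=self.data.copy())

    # -- I/O -----------------------------------------------------------
    def to_nifti(self, path: str | Path) -> Path:
        """Write as NIfTI with a diagonal affine built from the spacing."""
        affine = np.diag(list(self.spacing_mm) + [1.0])
        img = nib.Nifti1Image(np.asarray(self.data), affine)
        img.header.set_zooms(self.spacing_mm)
        path = Path(path)
        nib.save(img, str(path))
        return path

    @classmethod
    def from_nifti(cls, path: str | Path, units: str = "arbitrary") -> "Volume3D":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if any(z <= 0 for z in zooms):
            raise ValueError(f"{path}: NIfTI header has no usable voxel spacing {zooms}")
        data = np.asanyarray(img.dataobj)
        return cls(np.asarray(data), tuple(float(z) for z in zooms), units)


def require_same_grid(*vols: Volume3D) -> None:
    """Raise ``ValueError`` unless all volumes share shape and spacing."""
    first = vols[0]
    for v in vols[1:]:
        if not first.same_grid(v):
            raise ValueError(
                f"volumes not on the same grid: {first.shape}@{first.spacing_mm} "
                f"vs {v.shape}@{v.spacing_mm}"
            )


def voxel_centers_mm(shape: Sequence[int], spacing_mm: Sequence[float]) -> tuple[np.ndarray, ...]:
    """Per-axis physical coordinates (mm) of voxel centres, origin at volume corner."""
    return tuple(
        (np.arange(n) + 0.5) * s for n, s in zip(shape, spacing_mm)
    )
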