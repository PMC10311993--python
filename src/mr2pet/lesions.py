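"""Spherical lesion rasterization and sinogram-space insertion.

Lesions are purely additive in sinogram space: a sphere of given diameter
and activity is rasterized into a zero-filled volume, forward projected
with the CT-based attenuation map, and the resulting lesion sinogram is
added to the source sinogram.  Nothing in the source volume is replaced,
so insertion is exactly linear and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import phantoms
from .tomo import ProjectionGeometry, Sinogram, forward_project
from .volume import Volume3D, voxel_centers_mm

#: study-style default lesion: 12 mm sphere at SUV 8
DEFAULT_DIAMETER_MM = 12.0
DEFAULT_SUV = 8.0


@dataclass(frozen=True)
class LesionSpec:
    """A spherical lesion: centre (mm), diameter (mm), activity (SUV)."""

    center_mm: tuple[float, float, float]
    diameter_mm: float = DEFAULT_DIAMETER_MM
    suv: float = DEFAULT_SUV
    label: str = "lesion"

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError(f"lesion {self.label!r}: diameter must be positive")
        if self.suv <= 0:
            raise ValueError(f"lesion {self.label!r}: SUV must be positive")
        object.__setattr__(self, "center_mm", tuple(float(c) for c in self.center_mm))


def lesion_mask(spec: LesionSpec, grid: Volume3D) -> np.ndarray:
    """Boolean mask of voxels whose centres fall inside the sphere."""
    cx, cy, cz = voxel_centers_mm(grid.shape, grid.spacing_mm)
    r = spec.diameter_mm / 2.0
    dx2 = (cx - spec.center_mm[0]) ** 2
    dy2 = (cy - spec.center_mm[1]) ** 2
    dz2 = (cz - spec.center_mm[2]) ** 2
    return (dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]) <= r * r


def rasterize_lesions(specs: list[LesionSpec], grid: Volume3D) -> Volume3D:
    """Zero-filled volume with each sphere's interior set to its SUV.

    Overlapping spheres take the voxel-wise maximum.  A sphere with no
    voxel centre inside the grid is rejected by name.
    """
    out = np.zeros(grid.shape, dtype=np.float64)
    for spec in specs:
        m = lesion_mask(spec, grid)
        if not m.any():
            raise ValueError(f"lesion {spec.label!r} at {spec.center_mm} lies fully outside the grid")
        out[m] = np.maximum(out[m], spec.suv)
    return grid.with_data(out, "suv")


def insert_lesions(
    source_sino: Sinogram,
    lesion_vol: Volume3D,
    mu: Volume3D | None,
    geom: ProjectionGeometry | None = None,
) -> Sinogram:
    """Add the forward projection of a lesion volume to a source sinogram."""
    geom = geom or source_sino.geometry
    if geom.to_dict() != source_sino.geometry.to_dict():
        raise ValueError("sinogram geometry mismatch")
    lesion_sino = forward_project(lesion_vol, mu, geom, background=None)
    out = source_sino.copy()
    out.data = out.data + lesion_sino.data
    return out


def default_lesion_sites(case: "phantoms.PhantomCase",
                         diameter_mm: float = DEFAULT_DIAMETER_MM,
                         suv: float = DEFAULT_SUV) -> list[LesionSpec]:
    """Programmatic lesion placement on a phantom case.

    Mirrors a radiologist's challenge sites without an annotator: one sphere
    adjacent to bone, one inside bone, one in deep soft tissue, and one near
    the body edge — placements chosen to stress MR-based attenuation
    correction where activity is surrounded by soft tissue and bone.
    """
    labels = case.tissue_labels.data
    spacing = np.asarray(case.tissue_labels.spacing_mm)
    body = case.body_mask.data.astype(bool)
    bone = labels == phantoms.BONE
    r_vox = np.ceil(diameter_mm / 2.0 / spacing).astype(int)

    # distance (voxels) from non-body and from bone
    dist_edge = ndimage.distance_transform_edt(body, sampling=spacing)
    dist_bone = ndimage.distance_transform_edt(~bone, sampling=spacing)
    soft = labels == phantoms.SOFT
    fits = dist_edge > diameter_mm / 2.0 + float(np.max(spacing))

    def centre_of(mask: np.ndarray, what: str) -> tuple[float, float, float]:
        if not mask.any():
            raise ValueError(f"no valid site for lesion {what!r} on this phantom")
        idx = np.unravel_index(int(np.argmax(mask.astype(np.int8) * (1 + dist_edge))), mask.shape)
        return tuple((np.asarray(idx) + 0.5) * spacing)

    near_bone = soft & fits & (dist_bone > diameter_mm / 2.0) & (dist_bone < diameter_mm * 1.5)
    in_bone = bone & (dist_edge > diameter_mm / 2.0)
    if not in_bone.any():
        in_bone = bone  # thin bone: allow the sphere to straddle it
    deep_soft = soft & fits & (dist_bone > diameter_mm * 3.0)
    near_edge = soft & (dist_edge > diameter_mm / 2.0) & (dist_edge < diameter_mm * 1.2)

    return [
        LesionSpec(centre_of(near_bone, "acetabulum"), diameter_mm, suv, "acetabulum"),
        LesionSpec(centre_of(in_bone, "sacrum"), diameter_mm, suv, "sacrum"),
        LesionSpec(centre_of(deep_soft, "rectum"), diameter_mm, suv, "rectum"),
        LesionSpec(centre_of(near_edge, "lymph"), diameter_mm, suv, "lymph"),
    ]
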