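"""Training objectives: balanced histogram loss and tomographic LOR loss.

The total objective is J_total = J + λ·J_LOR.

J partitions target voxels into SUV histogram bins and mixes per-bin mean
absolute error (weights ᾱ) with per-bin mean relative error (weights β̄,
stabilized by ε in the denominator).  With the default five bins
[0,1), [1,4), [4,10), [10,20), [20,∞) and ᾱ=[1,1,1,1,0], β̄=[0,0,1,1,1],
low-uptake bins are supervised in absolute terms and hot bins in relative
terms, so neither end of the large SUV dynamic range dominates.

J_LOR integrates the relative-error volume along hypothetical PET lines of
response — a parallel projection along sampled directions (θ, φ) in a
uniform isotropic attenuating medium — and penalizes the L2 norm of the
projected values, averaged over the sampled directions.  This supervises
the coarse per-line scale of predictions the way tomographic data
collection would.

Both losses also come in ``*_with_grad`` variants returning the analytic
gradient with respect to the prediction, which the training loop feeds
into the network's backward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .volume import Volume3D

DEFAULT_EDGES = (0.0, 1.0, 4.0, 10.0, 20.0)
DEFAULT_ALPHA = (1.0, 1.0, 1.0, 1.0, 0.0)
DEFAULT_BETA = (0.0, 0.0, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class HistogramBinning:
    """SUV bin edges with absolute (ᾱ) and relative (β̄) weights.

    ``edges`` defines B bins; the last bin is open-ended.  ``eps``
    stabilizes the relative error denominator (1e-3 prevents overflow for
    near-zero targets).
    """

    edges: tuple[float, ...] = DEFAULT_EDGES
    alpha: tuple[float, ...] = DEFAULT_ALPHA
    beta: tuple[float, ...] = DEFAULT_BETA
    eps: float = 1e-3

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        alpha = tuple(float(a) for a in self.alpha)
        beta = tuple(float(b) for b in self.beta)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing")
        if len(alpha) != len(edges) or len(beta) != len(edges):
            raise ValueError("alpha and beta must have one weight per bin")
        if any(a < 0 for a in alpha) or any(b < 0 for b in beta):
            raise ValueError("weights must be nonnegative")
        if not any(alpha) and not any(beta):
            raise ValueError("at least one weight must be nonzero")

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    def bin_of(self, target: np.ndarray) -> np.ndarray:
        """Bin index per voxel (targets below the first edge land in bin 0)."""
        return np.clip(np.digitize(target, self.edges) - 1, 0, self.n_bins - 1)


def _as_array(v) -> np.ndarray:
    return np.asarray(v.data if isinstance(v, Volume3D) else v, dtype=np.float64)


def balanced_loss_with_grad(
    pred, target, bins: HistogramBinning = HistogramBinning()
) -> tuple[float, np.ndarray]:
    """Balanced histogram loss and its gradient w.r.t. the prediction."""
    p = _as_array(pred)
    y = _as_array(target)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {y.shape}")
    if np.any(y < 0):
        raise ValueError("target must be nonnegative (SUV)")
    err = p - y
    abs_err = np.abs(err)
    sgn = np.sign(err)
    idx = bins.bin_of(y)
    denom = y + bins.eps

    loss = 0.0
    grad = np.zeros_like(p)
    for j in range(bins.n_bins):
        sel = idx == j
        n_j = int(sel.sum())
        if n_j == 0:
            continue  # empty bins contribute nothing
        a, b = bins.alpha[j], bins.beta[j]
        if a:
            loss += a * float(abs_err[sel].mean())
            grad[sel] += a * sgn[sel] / n_j
        if b:
            loss += b * float((abs_err[sel] / denom[sel]).mean())
            grad[sel] += b * sgn[sel] / denom[sel] / n_j
    return float(loss), grad


def balanced_loss(pred, target, bins: HistogramBinning = HistogramBinning()) -> float:
    """Weighted per-bin mean absolute plus mean relative error (scalar)."""
    return balanced_loss_with_grad(pred, target, bins)[0]


# ---------------------------------------------------------------------
# parallel line-integration operator for arbitrary 3-D directions
# ---------------------------------------------------------------------

_LOR_CACHE: dict[tuple, sparse.csr_matrix] = {}

#: marching step along a LOR, in voxel units (patches are isotropic)
LOR_STEP_VOX = 0.5


def direction_vector(theta: float, phi: float) -> np.ndarray:
    """Unit vector for polar angle θ and azimuth φ (radians)."""
    return np.array([
        np.sin(theta) * np.cos(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(theta),
    ])


def sample_directions(n: int, rng: np.random.Generator) -> list[tuple[float, float]]:
    """(θ, φ) pairs uniform over the sphere."""
    out = []
    for _ in range(n):
        phi = float(rng.uniform(0.0, 2.0 * np.pi))
        theta = float(np.arccos(rng.uniform(-1.0, 1.0)))
        out.append((theta, phi))
    return out


def lor_projector(shape: tuple[int, int, int], theta: float, phi: float) -> sparse.csr_matrix:
    """Sparse parallel line-integration operator along (θ, φ).

    Rays form a 2-D detector grid (1-voxel pitch) perpendicular to the
    direction, marched with a half-voxel step and trilinear interpolation;
    operates in voxel units (training patches are isotropic).  Cached per
    (shape, direction).
    """
    key = (tuple(shape), round(float(theta), 9), round(float(phi), 9))
    if key in _LOR_CACHE:
        return _LOR_CACHE[key]

    u = direction_vector(theta, phi)
    # orthonormal detector basis
    helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)

    nx, ny, nz = shape
    center = np.array([nx, ny, nz], dtype=float) / 2.0
    diag = float(np.linalg.norm([nx, ny, nz]))
    n_det = int(np.ceil(diag)) + 1
    det = np.arange(n_det) - (n_det - 1) / 2.0
    step = LOR_STEP_VOX
    n_steps = int(np.ceil((diag + 2 * step) / step))
    t = (np.arange(n_steps) + 0.5) * step - n_steps * step / 2.0

    A, B = np.meshgrid(det, det, indexing="ij")
    base = center[None, :] + A.ravel()[:, None] * e1[None, :] + B.ravel()[:, None] * e2[None, :]
    n_rays = base.shape[0]

    rows_all, cols_all, vals_all = [], [], []
    # chunk over steps to bound memory
    pts = base[:, None, :] + t[None, :, None] * u[None, None, :]
    g = pts - 0.5  # voxel centres at i + 0.5
    i0 = np.floor(g).astype(np.int64)
    f = g - i0
    ray_idx = np.broadcast_to(np.arange(n_rays)[:, None], i0.shape[:2])
    for dx in (0, 1):
        wx = f[..., 0] if dx else 1 - f[..., 0]
        ix = i0[..., 0] + dx
        for dy in (0, 1):
            wy = f[..., 1] if dy else 1 - f[..., 1]
            iy = i0[..., 1] + dy
            for dz in (0, 1):
                wz = f[..., 2] if dz else 1 - f[..., 2]
                iz = i0[..., 2] + dz
                w = wx * wy * wz
                ok = (
                    (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
                    & (iz >= 0) & (iz < nz) & (w > 0)
                )
                rows_all.append(ray_idx[ok])
                cols_all.append((ix[ok] * ny + iy[ok]) * nz + iz[ok])
                vals_all.append(w[ok] * step)
    P = sparse.coo_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(n_rays, nx * ny * nz),
    ).tocsr()
    P.sum_duplicates()
    _LOR_CACHE[key] = P
    return P


def lor_loss_with_grad(
    pred, target, angles: list[tuple[float, float]], eps: float = 1e-3
) -> tuple[float, np.ndarray]:
    """LOR loss and its gradient w.r.t. the prediction."""
    p = _as_array(pred)
    y = _as_array(target)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {y.shape}")
    if not angles:
        raise ValueError("at least one projection direction is required")
    denom = y + eps
    r = ((p - y) / denom).ravel()
    loss = 0.0
    grad_flat = np.zeros_like(r)
    for theta, phi in angles:
        P = lor_projector(p.shape, theta, phi)
        proj = P @ r
        norm = float(np.linalg.norm(proj))
        loss += norm
        if norm > 0:
            grad_flat += (P.T @ proj) / norm
    n = len(angles)
    grad = grad_flat.reshape(p.shape) / denom / n
    return loss / n, grad


def lor_loss(pred, target, angles: list[tuple[float, float]], eps: float = 1e-3) -> float:
    """L2 norm of the line-projected relative error, averaged over angles."""
    return lor_loss_with_grad(pred, target, angles, eps)[0]


def total_loss_with_grad(
    pred,
    target,
    bins: HistogramBinning = HistogramBinning(),
    angles: list[tuple[float, float]] | None = None,
    lambda_lor: float = 1.0,
) -> tuple[float, float, float, np.ndarray]:
    """(J_total, J, J_LOR, dJ_total/dpred)."""
    if lambda_lor < 0:
        raise ValueError("lambda must be nonnegative")
    j, grad = balanced_loss_with_grad(pred, target, bins)
    j_lor = 0.0
    if lambda_lor > 0 and angles:
        j_lor, g_lor = lor_loss_with_grad(pred, target, angles, bins.eps)
        grad = grad + lambda_lor * g_lor
    return j + lambda_lor * j_lor, j, j_lor, grad


def total_loss(
    pred,
    target,
    bins: HistogramBinning = HistogramBinning(),
    angles: list[tuple[float, float]] | None = None,
    lambda_lor: float = 1.0,
) -> float:
    """J_total = J + λ·J_LOR."""
    return total_loss_with_grad(pred, target, bins, angles, lambda_lor)[0]
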