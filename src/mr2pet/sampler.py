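"""Phenotype cataloging and round-robin patch sampling.

Training patches are grouped into "phenotypes" by k-means clustering of
their normalized PET-SUV intensity histograms (K=10 by default); batches
then cycle the clusters round-robin so that rare phenotypes (hot organs,
near-empty background) are sampled as often as common ones.  Within a
cluster, patches are drawn in a seeded random order without replacement
and reshuffled on exhaustion, so draw counts per cluster never differ by
more than one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .model import patch_grid
from .phantoms import PhantomCase

logger = logging.getLogger(__name__)

#: histogram feature used for phenotype clustering: bin count and SUV range
PHENOTYPE_HIST_BINS = 16
PHENOTYPE_HIST_RANGE = (0.0, 32.0)


@dataclass
class PhenotypeCatalog:
    """All training patches, their histogram features and cluster labels."""

    patch_index: list[tuple[int, tuple[int, int, int]]]
    histograms: np.ndarray
    cluster_of: np.ndarray
    n_clusters: int
    patch_vox: int

    def __post_init__(self) -> None:
        if len(self.patch_index) != len(self.cluster_of):
            raise ValueError("one cluster label per patch is required")

    def __len__(self) -> int:
        return len(self.patch_index)


def extract_patch(
    case: PhantomCase, corner: tuple[int, int, int], patch_vox: int
) -> tuple[np.ndarray, np.ndarray]:
    """(mri, pet) patch pair at a voxel corner."""
    i, j, k = corner
    sl = (slice(i, i + patch_vox), slice(j, j + patch_vox), slice(k, k + patch_vox))
    return case.mri.data[sl], case.pet_truth.data[sl]


def patch_histogram(pet_patch: np.ndarray) -> np.ndarray:
    """Normalized SUV histogram of one patch (the clustering feature)."""
    h, _ = np.histogram(pet_patch, bins=PHENOTYPE_HIST_BINS, range=PHENOTYPE_HIST_RANGE)
    total = h.sum()
    return (h / total) if total else h.astype(float)


def catalog_phenotypes(
    cases: Sequence[PhantomCase],
    patch_vox: int,
    n_clusters: int = 10,
    seed: int = 0,
) -> PhenotypeCatalog:
    """Catalog all systematic (non-overlapping, end-aligned) patches and
    cluster their SUV histograms with seeded k-means."""
    index: list[tuple[int, tuple[int, int, int]]] = []
    feats: list[np.ndarray] = []
    for ci, case in enumerate(cases):
        grids = [patch_grid(n, patch_vox, patch_vox) for n in case.pet_truth.shape]
        for i in grids[0]:
            for j in grids[1]:
                for k in grids[2]:
                    _, pet = extract_patch(case, (i, j, k), patch_vox)
                    if pet.shape != (patch_vox,) * 3:
                        continue
                    index.append((ci, (i, j, k)))
                    feats.append(patch_histogram(pet))
    if not index:
        raise ValueError(f"no {patch_vox}^3 patches fit in the provided cases")
    X = np.stack(feats)
    k_eff = min(n_clusters, len(index))
    if k_eff < n_clusters:
        logger.warning("only %d patches available; reducing K from %d to %d",
                       len(index), n_clusters, k_eff)
    km = KMeans(n_clusters=k_eff, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    return PhenotypeCatalog(index, X, labels.astype(np.int64), k_eff, patch_vox)


def round_robin_draws(catalog: PhenotypeCatalog, seed: int = 0) -> Iterator[int]:
    """Infinite stream of patch indices cycling clusters 0..K-1.

    Empty clusters are skipped from the cycle; within a cluster patches are
    drawn without replacement in seeded random order, reshuffled when
    exhausted.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    rng = np.random.default_rng(seed)
    members = [np.flatnonzero(catalog.cluster_of == k) for k in range(catalog.n_clusters)]
    members = [m for m in members if m.size]
    queues: list[list[int]] = [[] for _ in members]
    while True:
        for ci, m in enumerate(members):
            if not queues[ci]:
                queues[ci] = [int(x) for x in rng.permutation(m)]
            yield queues[ci].pop(0)


def round_robin_batches(
    catalog: PhenotypeCatalog, batch_size: int, seed: int = 0
) -> Iterator[list[int]]:
    """Batches of patch indices chunked from the round-robin draw stream."""
    if batch_size < 1:
        raise ValueError("batch size must be >= 1")
    draws = round_robin_draws(catalog, seed)
    while True:
        yield [next(draws) for _ in range(batch_size)]
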