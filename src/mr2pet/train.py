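"""Training loop and the scikit-learn-style translator estimator.

Optimization uses Adam with gradient accumulation over the effective
batch (one patch passes through the network at a time, so memory stays
flat), the balanced histogram + LOR objective, and the phenotype
round-robin patch sampler.  Everything is seeded: one training seed fans
out to the catalog, the sampler, the LOR direction pool and the weight
initialization, so two runs with the same configuration produce identical
loss traces on CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .losses import HistogramBinning, sample_directions, total_loss_with_grad
from .model import UNet3D, UNetConfig, build_unet, predict_wholebody
from .nn import Adam
from .nn.layers import DTYPE
from .phantoms import PhantomCase
from .sampler import PhenotypeCatalog, catalog_phenotypes, extract_patch, round_robin_draws
from .volume import Volume3D


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults follow the training recipe)."""

    lr: float = 1e-4
    weight_decay: float = 1e-3
    effective_batch: int = 16
    patch_mm: int = 128
    lambda_lor: float = 1.0
    n_lor_angles: int = 4
    steps: int = 100
    seed: int = 0
    k_phenotypes: int = 10
    lor_pool_size: int = 8

    def __post_init__(self) -> None:
        if min(self.lr, self.weight_decay, self.effective_batch, self.patch_mm,
               self.steps, self.k_phenotypes) <= 0 or self.n_lor_angles < 1:
            raise ValueError("all training parameters must be positive")
        if self.lambda_lor < 0:
            raise ValueError("lambda must be nonnegative")


def resolve_patch_vox(cases: Sequence[PhantomCase], patch_mm: float, divisor: int) -> int:
    """Largest multiple of ``divisor`` that fits both the requested physical
    patch size and the smallest case dimension."""
    min_spacing = min(min(c.pet_truth.spacing_mm) for c in cases)
    min_dim = min(min(c.pet_truth.shape) for c in cases)
    want = int(round(patch_mm / min_spacing))
    vox = min(want, min_dim)
    vox -= vox % divisor
    if vox < divisor:
        raise ValueError(
            f"cases too small for any {divisor}-divisible patch (requested {patch_mm} mm)")
    return vox


def train(
    model: UNet3D,
    cases: Sequence[PhantomCase],
    bins: HistogramBinning = HistogramBinning(),
    cfg: TrainConfig = TrainConfig(),
) -> tuple[UNet3D, pd.DataFrame]:
    """Optimize the total objective; returns the model and per-step loss trace."""
    if not cases:
        raise ValueError("at least one training case is required")
    rng = np.random.default_rng(cfg.seed)
    patch_vox = resolve_patch_vox(cases, cfg.patch_mm, model.cfg.divisor)
    catalog = catalog_phenotypes(
        cases, patch_vox, n_clusters=cfg.k_phenotypes,
        seed=int(rng.integers(0, 2**31 - 1)))
    draws = round_robin_draws(catalog, seed=int(rng.integers(0, 2**31 - 1)))
    pool = sample_directions(cfg.lor_pool_size, rng) if cfg.lambda_lor > 0 else []
    opt = Adam(model.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)

    records = []
    for step in range(cfg.steps):
        opt.zero_grad()
        j_tot = j_bal = j_lor = 0.0
        for _ in range(cfg.effective_batch):
            ci, corner = catalog.patch_index[next(draws)]
            mri_patch, pet_patch = extract_patch(cases[ci], corner, patch_vox)
            pred = model.forward(mri_patch[None].astype(DTYPE))
            angles = (
                [pool[i] for i in rng.choice(len(pool), cfg.n_lor_angles, replace=False)]
                if pool else None
            )
            jt, j, jl, grad = total_loss_with_grad(
                pred[0], pet_patch, bins, angles, cfg.lambda_lor)
            model.backward((grad / cfg.effective_batch)[None])
            j_tot += jt / cfg.effective_batch
            j_bal += j / cfg.effective_batch
            j_lor += jl / cfg.effective_batch
        if not np.isfinite(j_tot):
            raise RuntimeError(
                f"non-finite loss at step {step}: J_total={j_tot} (J={j_bal}, J_LOR={j_lor}); "
                "check the learning rate and input scaling")
        opt.step()
        records.append({"step": step, "j_total": j_tot, "j": j_bal, "j_lor": j_lor})
    return model, pd.DataFrame.from_records(records)


class MRToPETTranslator(BaseEstimator):
    """MRI→PET domain translator with the balanced histogram + LOR objective.

    A scikit-learn-style estimator: ``fit`` trains the 3-D residual UNet on
    a sequence of phantom cases (or ``(mri, pet)`` Volume3D pairs) and
    ``predict`` assembles whole-volume SUV predictions by overlap-averaged
    patch inference.

    Parameters mirror :class:`UNetConfig` and :class:`TrainConfig`; fitted
    state lives in ``model_`` (the network) and ``loss_trace_`` (per-step
    DataFrame of J_total, J, J_LOR).
    """

    def __init__(
        self,
        encoder_channels: tuple[int, ...] = (32, 64, 128, 256, 512),
        decoder_channels: tuple[int, ...] = (256, 128, 64, 32),
        bin_edges: tuple[float, ...] = HistogramBinning().edges,
        alpha: tuple[float, ...] = HistogramBinning().alpha,
        beta: tuple[float, ...] = HistogramBinning().beta,
        eps: float = 1e-3,
        lr: float = 1e-4,
        weight_decay: float = 1e-3,
        effective_batch: int = 16,
        patch_mm: int = 128,
        lambda_lor: float = 1.0,
        n_lor_angles: int = 4,
        steps: int = 100,
        seed: int = 0,
        predict_patch_vox: int = 128,
        predict_overlap: float = 0.5,
    ) -> None:
        self.encoder_channels = encoder_channels
        self.decoder_channels = decoder_channels
        self.bin_edges = bin_edges
        self.alpha = alpha
        self.beta = beta
        self.eps = eps
        self.lr = lr
        self.weight_decay = weight_decay
        self.effective_batch = effective_batch
        self.patch_mm = patch_mm
        self.lambda_lor = lambda_lor
        self.n_lor_angles = n_lor_angles
        self.steps = steps
        self.seed = seed
        self.predict_patch_vox = predict_patch_vox
        self.predict_overlap = predict_overlap

    # -- helpers -------------------------------------------------------
    def _bins(self) -> HistogramBinning:
        return HistogramBinning(self.bin_edges, self.alpha, self.beta, self.eps)

    @staticmethod
    def _as_cases(X) -> list[PhantomCase]:
        cases = []
        for item in X:
            if isinstance(item, PhantomCase):
                cases.append(item)
            else:
                mri, pet = item
                cases.append(PhantomCase(
                    mri=mri, pet_truth=pet, mu_ct=pet.with_data(
                        np.zeros(pet.shape), "mu_per_mm"),
                    mu_mrac=pet.with_data(np.zeros(pet.shape), "mu_per_mm"),
                    body_mask=pet.with_data(
                        (pet.data > 0).astype(np.uint8), "mask"),
                    tissue_labels=pet.with_data(
                        np.zeros(pet.shape, dtype=np.int16), "label"),
                    seed=-1))
        return cases

    # -- estimator API -------------------------------------------------
    def fit(self, X, y=None) -> "MRToPETTranslator":
        cases = self._as_cases(X)
        cfg = UNetConfig(
            encoder_channels=tuple(self.encoder_channels),
            decoder_channels=tuple(self.decoder_channels))
        model = build_unet(cfg, seed=self.seed)
        tcfg = TrainConfig(
            lr=self.lr, weight_decay=self.weight_decay,
            effective_batch=self.effective_batch, patch_mm=self.patch_mm,
            lambda_lor=self.lambda_lor, n_lor_angles=self.n_lor_angles,
            steps=self.steps, seed=self.seed)
        self.model_, self.loss_trace_ = train(model, cases, self._bins(), tcfg)
        self.patch_vox_ = resolve_patch_vox(cases, self.patch_mm, cfg.divisor)
        return self

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")
        single = isinstance(X, Volume3D)
        vols = [X] if single else list(X)
        patch = self.predict_patch_vox
        out = [
            predict_wholebody(self.model_, v, patch_vox=patch, overlap=self.predict_overlap)
            for v in vols
        ]
        return out[0] if single else out
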