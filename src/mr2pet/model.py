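"""3-D residual UNet and overlap-averaged whole-volume inference.

The network is the classic encoder–decoder UNet with residual conv blocks,
2×2×2 max pooling, strided transposed-convolution upsampling, skip
connections by channel concatenation at matching scales, and a final
softplus so predicted uptake is strictly nonnegative (SUV is physical).
Whole-body volumes are translated patch-wise: overlapping patches (50%
overlap by default) are predicted independently and each voxel of the
output is the arithmetic mean of every patch prediction covering it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import Conv3d, ConvTranspose3d, MaxPool3d, Param, ResBlock, Softplus
from .nn.layers import DTYPE
from .volume import Volume3D


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters for the residual UNet."""

    in_channels: int = 1
    out_channels: int = 1
    encoder_channels: tuple[int, ...] = (32, 64, 128, 256, 512)
    decoder_channels: tuple[int, ...] = (256, 128, 64, 32)
    conv_kernel: int = 3
    pool_kernel: int = 2

    def __post_init__(self) -> None:
        enc = tuple(int(c) for c in self.encoder_channels)
        dec = tuple(int(c) for c in self.decoder_channels)
        object.__setattr__(self, "encoder_channels", enc)
        object.__setattr__(self, "decoder_channels", dec)
        if len(dec) != len(enc) - 1:
            raise ValueError("decoder must have one fewer stage than the encoder")
        if any(c <= 0 for c in enc + dec) or self.in_channels <= 0 or self.out_channels <= 0:
            raise ValueError("all channel counts must be positive")
        if self.conv_kernel != 3 or self.pool_kernel != 2:
            raise ValueError("this architecture uses 3x3x3 convolutions and 2x2x2 pooling")

    @property
    def n_pools(self) -> int:
        return len(self.encoder_channels) - 1

    @property
    def divisor(self) -> int:
        """Input dimensions must be divisible by 2^(number of poolings)."""
        return 2 ** self.n_pools


class UNet3D:
    """Residual UNet operating on single-sample (C, D, H, W) float32 tensors."""

    def __init__(self, cfg: UNetConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        enc = cfg.encoder_channels
        dec = cfg.decoder_channels
        self.enc_blocks: list[ResBlock] = []
        prev = cfg.in_channels
        for i, c in enumerate(enc):
            self.enc_blocks.append(ResBlock(prev, c, rng, f"enc{i}"))
            prev = c
        self.pools = [MaxPool3d() for _ in range(cfg.n_pools)]
        self.ups: list[ConvTranspose3d] = []
        self.dec_blocks: list[ResBlock] = []
        for i, c in enumerate(dec):
            self.ups.append(ConvTranspose3d(prev, c, rng, f"up{i}"))
            skip_c = enc[len(enc) - 2 - i]
            self.dec_blocks.append(ResBlock(c + skip_c, c, rng, f"dec{i}"))
            prev = c
        self.head = Conv3d(prev, cfg.out_channels, 1, rng, "head")
        self.act = Softplus()
        self._skip_channels = [enc[len(enc) - 2 - i] for i in range(len(dec))]

    # -- parameters ----------------------------------------------------
    def params(self) -> list[Param]:
        out: list[Param] = []
        for b in self.enc_blocks:
            out += b.params()
        for u, b in zip(self.ups, self.dec_blocks):
            out += u.params() + b.params()
        out += self.head.params()
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    # -- forward / backward --------------------------------------------
    def _check_shape(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[0] != self.cfg.in_channels:
            raise ValueError(f"expected ({self.cfg.in_channels}, D, H, W) input, got {x.shape}")
        d = self.cfg.divisor
        if any(s % d for s in x.shape[1:]):
            raise ValueError(
                f"input dims {x.shape[1:]} must be divisible by {d}; "
                "the inference layer is responsible for padding")

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        self._check_shape(x)
        skips = []
        h = x
        for i, block in enumerate(self.enc_blocks):
            h = block.forward(h)
            if i < len(self.pools):
                skips.append(h)
                h = self.pools[i].forward(h)
        for i, (up, dec) in enumerate(zip(self.ups, self.dec_blocks)):
            h = up.forward(h)
            skip = skips[len(skips) - 1 - i]
            h = np.concatenate([h, skip], axis=0)
            h = dec.forward(h)
        return self.act.forward(self.head.forward(h))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.head.backward(self.act.backward(np.asarray(dy, dtype=DTYPE)))
        dskips: list[np.ndarray | None] = [None] * len(self.pools)
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            d = self.dec_blocks[i].backward(d)
            n_up = d.shape[0] - self._skip_channels[i]
            d_up, d_skip = d[:n_up], d[n_up:]
            dskips[len(dskips) - 1 - i] = d_skip
            d = self.ups[i].backward(np.ascontiguousarray(d_up))
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            if i < len(self.pools):
                d = self.pools[i].backward(d)
                d = d + dskips[i]
            d = self.enc_blocks[i].backward(d)
        return d

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    # -- checkpointing -------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Single-file checkpoint with the architecture config embedded."""
        path = Path(path)
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.params())}
        cfg = {
            "in_channels": self.cfg.in_channels,
            "out_channels": self.cfg.out_channels,
            "encoder_channels": list(self.cfg.encoder_channels),
            "decoder_channels": list(self.cfg.decoder_channels),
        }
        arrays["config_json"] = np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8)
        np.savez_compressed(path, **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "UNet3D":
        with np.load(path) as f:
            cfg = json.loads(bytes(f["config_json"]).decode())
            model = cls(UNetConfig(
                in_channels=cfg["in_channels"], out_channels=cfg["out_channels"],
                encoder_channels=tuple(cfg["encoder_channels"]),
                decoder_channels=tuple(cfg["decoder_channels"])))
            for i, p in enumerate(model.params()):
                p.data = f[f"param_{i}"].astype(DTYPE)
                p.grad = np.zeros_like(p.data)
        return model


def build_unet(cfg: UNetConfig | None = None, seed: int = 0) -> UNet3D:
    """Construct a seeded residual UNet from a configuration."""
    return UNet3D(cfg or UNetConfig(), seed=seed)


def patch_grid(n: int, patch: int, stride: int) -> list[int]:
    """Start offsets tiling [0, n) with the given patch and stride; the final
    patch is aligned to the end so the whole extent is covered."""
    if patch >= n:
        return [0]
    starts = list(range(0, n - patch + 1, stride))
    if starts[-1] != n - patch:
        starts.append(n - patch)
    return starts


def predict_wholebody(
    model: UNet3D,
    mri: Volume3D,
    patch_vox: int = 128,
    overlap: float = 0.5,
) -> Volume3D:
    """Overlap-averaged patch inference over an arbitrarily sized volume.

    The volume is reflect-padded up to the patch tiling, every patch is
    predicted independently, each voxel of the assembled output is the
    arithmetic mean of all patch predictions covering it, and the padding
    is cropped away.  Output is nonnegative with the input's shape.
    """
    if patch_vox % 32:
        raise ValueError(f"patch size must be divisible by 32, got {patch_vox}")
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must lie in [0, 1)")
    data = np.asarray(mri.data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("MRI volume must be finite")
    stride = max(1, int(round(patch_vox * (1.0 - overlap))))

    pads = []
    for n in data.shape:
        if n >= patch_vox:
            rem = (n - patch_vox) % stride
            pads.append(0 if rem == 0 else stride - rem)
        else:
            pads.append(patch_vox - n)
    padded = data
    for ax, p in enumerate(pads):
        if p:
            width = [(0, 0)] * 3
            width[ax] = (0, p)
            mode = "reflect" if p < padded.shape[ax] else "edge"
            padded = np.pad(padded, width, mode=mode)

    acc = np.zeros(padded.shape, dtype=np.float64)
    cnt = np.zeros(padded.shape, dtype=np.float64)
    grids = [patch_grid(n, patch_vox, stride) for n in padded.shape]
    for i in grids[0]:
        for j in grids[1]:
            for k in grids[2]:
                patch = padded[i:i + patch_vox, j:j + patch_vox, k:k + patch_vox]
                pred = model.forward(patch[None].astype(DTYPE))[0]
                acc[i:i + patch_vox, j:j + patch_vox, k:k + patch_vox] += pred
                cnt[i:i + patch_vox, j:j + patch_vox, k:k + patch_vox] += 1.0
    out = acc / cnt
    nx, ny, nz = data.shape
    return mri.with_data(np.clip(out[:nx, :ny, :nz], 0.0, None), "suv")
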