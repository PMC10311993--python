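"""Shared fixtures: small seeded phantoms and geometries.

Everything is generated programmatically at test time; session scope keeps
the phantom and projector caches warm across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import mr2pet as m


@pytest.fixture(scope="session")
def case48() -> m.PhantomCase:
    """A 48x48x32 phantom at 3 mm used across the tomographic tests."""
    return m.generate_phantom(7, shape=(48, 48, 32), spacing_mm=3.0)


@pytest.fixture(scope="session")
def geom48(case48: m.PhantomCase) -> m.ProjectionGeometry:
    return m.ProjectionGeometry.for_volume(case48.pet_truth, n_angles=60)


@pytest.fixture(scope="session")
def tiny_unet() -> m.UNet3D:
    """A small 3-stage residual UNet (divisor 4) for shape/gradient tests."""
    cfg = m.UNetConfig(encoder_channels=(4, 8, 16), decoder_channels=(8, 4))
    return m.build_unet(cfg, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
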