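from __future__ import annotations

import numpy as np
import pytest

from geoparticle.morphometry import ParticleRegion


def region_from_mask(mask: np.ndarray) -> ParticleRegion:
    """Wrap a binary mask (single component assumed) as a ParticleRegion."""
    return ParticleRegion(pixels=np.argwhere(mask))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
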