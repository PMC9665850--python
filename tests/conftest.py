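from __future__ import annotations

import numpy as np
import pytest

import netquant as nq


@pytest.fixture(scope="session")
def recovery_field():
    """One well-separated d3d9-like field: 12 resting + 8 NETs at 20x."""
    return nq.generate_field(12, 0, 8, "d3d9_like", (512, 512), "20x", seed=1)


@pytest.fixture(scope="session")
def default_config():
    return nq.RunConfig()


def draw_squares(shape, positions, size, value, background=10):
    """Hand-built field helper: uniform bright squares on a dim background."""
    img = np.full(shape, background, dtype=np.uint8)
    for r, c in positions:
        img[r : r + size, c : c + size] = value
    return img
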