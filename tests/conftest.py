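import math

import numpy as np
import pytest

from tatnet import simulate


@pytest.fixture
def small_network_spec():
    """Compact cell used for fast full-pipeline recovery tests."""
    return simulate.NetworkSpec(
        cell_length=30.0, cell_width=10.0,
        segment_length_mean=5.0, segment_length_sd=2.0,
    )


@pytest.fixture
def sted_imaging():
    return simulate.ImagingSpec()  # STED defaults: 16.23 nm px, 60 nm PSF


def line_pixels(angle_deg: float, n: int = 100, start=(10, 10)) -> set:
    """Rasterised straight 1-px line in the package (x=col, y=row) frame."""
    pts = set()
    r0, c0 = start
    for i in range(n):
        x = c0 + i * math.cos(math.radians(angle_deg))
        y = r0 + i * math.sin(math.radians(angle_deg))
        pts.add((int(round(y)), int(round(x))))
    return pts


def pixels_to_mask(pixels: set, shape=None) -> np.ndarray:
    rows = [p[0] for p in pixels]
    cols = [p[1] for p in pixels]
    if shape is None:
        shape = (max(rows) + 3, max(cols) + 3)
    m = np.zeros(shape, dtype=bool)
    m[rows, cols] = True
    return m
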