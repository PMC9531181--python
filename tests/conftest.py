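"""Shared fixtures: independent spot rendering and small canned inputs."""

from __future__ import annotations

import numpy as np
import pytest


def render_spots(shape, spots, background=0.0):
    """Render 2D Gaussian spots over a uniform background, full-frame.

    ``spots`` is an iterable of (x, y, amplitude, sigma_x, sigma_y) tuples.
    Independent of the package's renderer (no support cutoff).
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    img = np.full(shape, float(background))
    for x, y, a, sx, sy in spots:
        img += a * np.exp(-((xx - x) ** 2 / (2 * sx**2) + (yy - y) ** 2 / (2 * sy**2)))
    return img


@pytest.fixture
def spot_renderer():
    return render_spots


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
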