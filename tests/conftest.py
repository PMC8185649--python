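"""Shared test helpers: analytic boundaries and simple raster shapes."""

from __future__ import annotations

import numpy as np
import pytest

from memcurv.segmentation import Boundary


def circle_points(
    r: float,
    center: tuple[float, float] = (128.0, 128.0),
    n: int = 1000,
    hole: bool = False,
) -> np.ndarray:
    """Analytic circle sampled at equal arc length, as (x, y) points.

    With ``hole=False`` the traversal keeps the disk interior on the left
    (convex region, kappa = -1/r); ``hole=True`` reverses it so the region
    lies outside the circle (a hole, kappa = +1/r).
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    if hole:
        theta = -theta
    return np.column_stack(
        [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
    )


def circle_boundary(r: float, **kw) -> Boundary:
    return Boundary(circle_points(r, **kw))


def disk_mask(
    shape: tuple[int, int], center: tuple[float, float], r: float
) -> np.ndarray:
    """Boolean raster disk; center given as (x, y)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= r * r


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
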