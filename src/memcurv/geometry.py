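"""Quantitative boundary geometry: curvature, velocity, profiles, circles.

Curvature is the inverse radius of the osculating circle estimated from three
boundary points: the point P and the two points S index offsets away on the
equal-arc-length resampled contour.  The scale parameter S controls the
spatial scale of the estimate; defaults are S=10 (hole/TEM boundaries, 50
angular bins) and S=44 (whole migrating-cell boundaries, 1000 bins).

Sign convention: curvature is POSITIVE when the circumcircle center lies on
the outward (non-region) side of the boundary.  A circular hole inside a cell
therefore has kappa = +1/r everywhere, a convex cell bulge kappa = -1/r.

Edge velocity at a boundary point is the central difference of the signed
Euclidean distance transform (positive inside the region) between frames
t-1 and t+1, interpolated at the sub-pixel point: positive values mean the
edge is advancing (cell protruding, hole closing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .segmentation import Boundary

__all__ = [
    "CircleFit",
    "signed_curvature",
    "signed_distance_transform",
    "edge_velocity",
    "angular_profile",
    "fit_circle",
    "ring_diameter",
    "contour_perimeter",
    "ring_table",
    "px_per_frame_to_um_per_min",
]

_COLLINEAR_EPS = 1e-12


def signed_curvature(
    boundary: Boundary, S: int, region_mask: np.ndarray | None = None
) -> np.ndarray:
    """Per-point signed curvature (1/px) from three-point osculating circles.

    At each point P the unique circle through the points S indices before and
    after P (periodic) is computed; kappa = sign / radius with the sign set by
    which side of the boundary the circle center falls on (positive =
    outward / non-region side).  Three collinear points give kappa = 0.

    ``region_mask`` optionally re-checks the boundary orientation against the
    mask before signing; normally the Boundary's stored orientation suffices.
    """
    n = len(boundary)
    if not 1 <= S < n / 2:
        raise ValueError(f"S must satisfy 1 <= S < N/2 (N={n})")
    if region_mask is not None:
        from .segmentation import _orient

        boundary = _orient(boundary, region_mask)
    p = boundary.points
    a = np.roll(p, S, axis=0)
    c = np.roll(p, -S, axis=0)
    center, radius, degenerate = _circumcircle(a, p, c)
    kappa = np.zeros(n)
    ok = ~degenerate
    # outward normal = rightward perpendicular of the tangent (interior left)
    t = c - a
    n_out = np.column_stack([t[:, 1], -t[:, 0]])
    side = np.einsum("ij,ij->i", center - p, n_out)
    kappa[ok] = np.sign(side[ok]) / radius[ok]
    kappa[ok & (side == 0)] = 0.0
    return kappa


def _circumcircle(
    a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized circumcircle through point triples; flags collinear ones."""
    d = 2.0 * (
        a[:, 0] * (b[:, 1] - c[:, 1])
        + b[:, 0] * (c[:, 1] - a[:, 1])
        + c[:, 0] * (a[:, 1] - b[:, 1])
    )
    scale = np.maximum(
        np.max(np.abs(np.stack([a, b, c])), axis=(0, 2)) ** 2, 1.0
    )
    degenerate = np.abs(d) < _COLLINEAR_EPS * scale
    d_safe = np.where(degenerate, 1.0, d)
    a2 = np.einsum("ij,ij->i", a, a)
    b2 = np.einsum("ij,ij->i", b, b)
    c2 = np.einsum("ij,ij->i", c, c)
    ux = (a2 * (b[:, 1] - c[:, 1]) + b2 * (c[:, 1] - a[:, 1]) + c2 * (a[:, 1] - b[:, 1])) / d_safe
    uy = (a2 * (c[:, 0] - b[:, 0]) + b2 * (a[:, 0] - c[:, 0]) + c2 * (b[:, 0] - a[:, 0])) / d_safe
    center = np.column_stack([ux, uy])
    radius = np.hypot(b[:, 0] - ux, b[:, 1] - uy)
    return center, radius, degenerate


def signed_distance_transform(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance to the mask interface, positive inside the region.

    The raw EDT measures to the nearest pixel *center* of the opposite class,
    which overestimates the distance to the inter-pixel interface by half a
    pixel on each side; the half-pixel is subtracted so the zero level sits
    on the interface.
    """
    mask = np.asarray(mask, dtype=bool)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    sdt = inside - outside
    return sdt - 0.5 * np.sign(sdt)


def edge_velocity(
    boundary: Boundary,
    mask_prev: np.ndarray,
    mask_next: np.ndarray,
    mode: str = "central",
) -> np.ndarray:
    """Edge velocity (px/frame) at each boundary point of frame t.

    ``mode="central"``: v = (sdt(t+1) - sdt(t-1)) / 2 evaluated at P with
    bilinear interpolation, where sdt is the inside-positive signed distance
    transform.  Positive = edge advancing (cell protruding / TEM closing).

    ``mode="literal_average"``: (sdt(t+1) + sdt(t-1)) / 2 — the literal
    average of the two distance transforms, retained for comparison; for
    steady motion it measures the residual distance offset, not a speed.
    """
    if mode not in ("central", "literal_average"):
        raise ValueError(f"unknown mode {mode!r}")
    H, W = np.asarray(mask_prev).shape
    x, y = boundary.x, boundary.y
    if np.any((x < -0.5) | (x > W - 0.5) | (y < -0.5) | (y > H - 0.5)):
        raise ValueError("boundary point outside the masks' bounding box")
    sd_prev = signed_distance_transform(mask_prev)
    sd_next = signed_distance_transform(mask_next)
    coords = np.vstack([y, x])
    vp = ndimage.map_coordinates(sd_prev, coords, order=1, mode="nearest")
    vn = ndimage.map_coordinates(sd_next, coords, order=1, mode="nearest")
    if mode == "central":
        return (vn - vp) / 2.0
    return (vn + vp) / 2.0


def px_per_frame_to_um_per_min(
    v: np.ndarray | float, pixel_size_nm: float, frame_interval_s: float
) -> np.ndarray | float:
    """Convert px/frame to micrometres per minute."""
    return v * (pixel_size_nm / 1000.0) * (60.0 / frame_interval_s)


def angular_profile(
    values: np.ndarray,
    coords: np.ndarray,
    center: tuple[float, float],
    n_bins: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of ``values`` in equal angular bins around ``center``.

    coords is (M, 2) of (x, y).  The angle is atan2(y - cy, x - cx) mapped to
    [0, 360); sample i goes to bin floor(theta / (360/n_bins)).  Returns
    (bin_means, bin_centers_deg); empty bins are NaN (missing, never zero).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    cx, cy = center
    theta = np.degrees(np.arctan2(coords[:, 1] - cy, coords[:, 0] - cx)) % 360.0
    idx = np.floor(theta / (360.0 / n_bins)).astype(int) % n_bins
    finite = np.isfinite(values)
    counts = np.bincount(idx[finite], minlength=n_bins)
    if finite.any() and (counts > 0).sum() == 1:
        warnings.warn("all samples fall in a single angular bin", stacklevel=2)
    sums = np.bincount(idx[finite], weights=values[finite], minlength=n_bins)
    means = np.full(n_bins, np.nan)
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]
    centers = (np.arange(n_bins) + 0.5) * (360.0 / n_bins)
    return means, centers


@dataclass(frozen=True)
class CircleFit:
    center: tuple[float, float]
    radius: float
    kappa: float
    degenerate: bool = False


def fit_circle(points: np.ndarray) -> CircleFit:
    """Circle through (3 points: circumcircle) or algebraic least-squares fit.

    Collinear input returns kappa = 0 with the ``degenerate`` flag (infinite
    radius), not an error.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 (x, y) points")
    if len(np.unique(pts, axis=0)) < 3:
        raise ValueError("need at least 3 non-coincident points")
    if len(pts) == 3:
        center, radius, degenerate = _circumcircle(pts[:1], pts[1:2], pts[2:3])
        if degenerate[0]:
            return CircleFit((np.nan, np.nan), np.inf, 0.0, True)
        return CircleFit(tuple(center[0]), float(radius[0]), float(1 / radius[0]))
    # Kasa algebraic fit: minimize ||x^2+y^2 - 2ax - 2by - c||
    A = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(len(pts))])
    rhs = (pts**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 3:
        return CircleFit((np.nan, np.nan), np.inf, 0.0, True)
    cx, cy, c = sol
    r2 = c + cx**2 + cy**2
    if r2 <= 0 or not np.isfinite(r2):
        return CircleFit((np.nan, np.nan), np.inf, 0.0, True)
    r = float(np.sqrt(r2))
    return CircleFit((float(cx), float(cy)), r, 1.0 / r)


def ring_diameter(perimeter: float) -> float:
    """Diameter of the perfect circle with the given perimeter: d = C / pi."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return perimeter / np.pi


def contour_perimeter(particle: np.ndarray, presmooth_sigma: float = 0.8) -> float:
    """Arc length (px) of the sub-pixel 0.5 iso-contour of a particle mask.

    The binary is lightly Gaussian-smoothed first so the polygon length is not
    inflated by the rasterization staircase.  Particles touching the image
    border are measured but trigger a warning (perimeter underestimated).
    """
    mask = np.asarray(particle, dtype=bool)
    npix = int(mask.sum())
    if npix < 8:
        raise ValueError("particle must have at least 8 pixels")
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        warnings.warn("particle touches the image border; perimeter underestimated",
                      stacklevel=2)
    smooth = ndimage.gaussian_filter(mask.astype(float), presmooth_sigma)
    contours = measure.find_contours(smooth, 0.5)
    if not contours:
        contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("no contour found for particle")
    c = max(contours, key=lambda c: len(c))
    d = np.diff(np.vstack([c, c[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def ring_table(labels: np.ndarray, pixel_size_nm: float) -> pd.DataFrame:
    """Per-ring morphometrics: perimeter, equivalent-circle diameter, centroid.

    The measured circumference of an annular particle is the mean of its outer
    and inner (hole) contour lengths — the center-line perimeter; particles
    without a resolved hole use the outer contour alone.  Diameter = C / pi,
    reported in px and nm.
    """
    rows = []
    for region in measure.regionprops(labels):
        sl = region.slice
        pad = np.pad(region.image, 2)  # isolate; avoids border warnings
        try:
            c_out = contour_perimeter(pad)
        except ValueError:
            continue
        filled = ndimage.binary_fill_holes(pad)
        hole = filled & ~pad
        c_in = None
        if hole.sum() >= 8:
            try:
                c_in = contour_perimeter(hole)
            except ValueError:
                c_in = None
        C = (c_out + c_in) / 2.0 if c_in is not None else c_out
        d_px = ring_diameter(C)
        cy, cx = region.centroid
        rows.append(
            {
                "ring": region.label,
                "perimeter_px": C,
                "perimeter_outer_px": c_out,
                "has_hole": c_in is not None,
                "diameter_px": d_px,
                "diameter_nm": d_px * pixel_size_nm,
                "cx": cx,
                "cy": cy,
                "area_px2": float(region.area),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ring", "perimeter_px", "perimeter_outer_px", "has_hole",
            "diameter_px", "diameter_nm", "cx", "cy", "area_px2",
        ],
    )
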