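"""Mask, boundary and band construction.

Masks are plain boolean Y x X arrays.  Boundaries are closed, spline-smoothed
contours resampled to equal arc length, carried by :class:`Boundary`.

Coordinate convention (used everywhere in the package): 0-based, x = column,
y = row, y increases downward; contours live at the 0.5 iso-level of the
binary mask, i.e. sub-pixel.  A :class:`Boundary` is oriented so that the
segmented region's interior lies to the LEFT of the traversal direction,
where for tangent (tx, ty) "left" is the perpendicular (-ty, tx); the outward
normal is therefore the rightward perpendicular (ty, -tx).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import filters, measure, morphology

__all__ = [
    "Boundary",
    "NoRegionFoundError",
    "segment_region",
    "extract_boundary",
    "intensity_boundary",
    "make_doughnuts",
    "boundary_band",
    "segment_rings",
    "align_masks",
]


class NoRegionFoundError(ValueError):
    """Raised when segmentation yields no foreground region."""


@dataclass
class Boundary:
    """Ordered closed contour, equally spaced in arc length.

    points : (N, 2) float array of (x, y) pixel coordinates; point N wraps to
             point 0.  Interior of the segmented region is to the left of the
             traversal direction.
    frame  : source frame index, if any.
    """

    points: np.ndarray
    frame: int | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 3:
            raise ValueError("points must be (N, 2) with N >= 3")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def arc_length(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def tangents(self) -> np.ndarray:
        """Unit tangents by central difference over the closed polyline."""
        t = np.roll(self.points, -1, axis=0) - np.roll(self.points, 1, axis=0)
        norm = np.hypot(t[:, 0], t[:, 1])
        return t / norm[:, None]

    def left_normals(self) -> np.ndarray:
        """Unit normals pointing into the region interior."""
        t = self.tangents()
        return np.column_stack([-t[:, 1], t[:, 0]])

    def centroid(self) -> tuple[float, float]:
        return float(self.points[:, 0].mean()), float(self.points[:, 1].mean())


def segment_region(
    frame: np.ndarray,
    smoothing_sigma: float = 2.0,
    threshold: float | str = "otsu",
    erosion_radius: float = 2,
) -> np.ndarray:
    """Three-step segmentation: Gaussian smoothing, thresholding, erosion.

    Returns the largest connected component; interior holes are preserved so
    TEMs remain detectable.  ``threshold="otsu"`` picks a per-frame Otsu
    threshold on the smoothed image; a float fixes a global threshold.
    Raises :class:`NoRegionFoundError` if nothing survives.
    """
    frame = np.asarray(frame, dtype=float)
    if np.any(frame < 0):
        raise ValueError("frame must be nonnegative")
    if erosion_radius < 0:
        raise ValueError("erosion_radius must be >= 0")
    smoothed = ndimage.gaussian_filter(frame, smoothing_sigma) if smoothing_sigma > 0 else frame
    if threshold == "otsu":
        if smoothed.max() == smoothed.min():
            raise NoRegionFoundError("no region found: constant frame")
        thr = filters.threshold_otsu(smoothed)
    else:
        thr = float(threshold)
    mask = smoothed > thr
    if erosion_radius > 0:
        mask = ndimage.binary_erosion(
            mask, structure=morphology.disk(int(round(erosion_radius)))
        )
    if not mask.any():
        raise NoRegionFoundError("no region found after threshold/erosion")
    labels = measure.label(mask, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return labels == largest


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return mask
    return labels == (np.argmax(np.bincount(labels.ravel())[1:]) + 1)


def _holes_of(mask: np.ndarray) -> np.ndarray:
    return ndimage.binary_fill_holes(mask) & ~mask


def extract_boundary(
    mask: np.ndarray,
    n_points: int = 1000,
    which: str = "outer",
    frame: int | None = None,
    anchor: tuple[float, float] | None = None,
    smoothing: float = 1.0,
) -> Boundary:
    """Sub-pixel closed boundary of a mask, resampled to equal arc length.

    The 0.5 iso-contour of the binary is resampled densely at equal arc
    length, smoothed with a periodic Gaussian of SD ``smoothing`` (px of arc
    length) to suppress the rasterization staircase, then resampled to
    ``n_points`` equal arc-length positions.  ``which="hole"`` extracts the
    boundary of the largest interior hole (or the hole containing
    ``anchor``).  Orientation follows the Boundary contract: mask interior to
    the left.
    """
    mask = np.asarray(mask, dtype=bool)
    if which == "outer":
        target = ndimage.binary_fill_holes(_largest_component(mask))
    elif which == "hole":
        holes = _holes_of(mask)
        if not holes.any():
            raise ValueError("mask has no interior hole")
        labels = measure.label(holes, connectivity=2)
        if anchor is not None:
            lab = labels[int(round(anchor[1])), int(round(anchor[0]))]
            if lab == 0:
                raise ValueError("anchor does not fall inside a hole")
        else:
            lab = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        target = labels == lab
    else:
        raise ValueError("which must be 'outer' or 'hole'")

    contours = measure.find_contours(target.astype(float), 0.5)
    if not contours:
        raise ValueError("no contour found")
    contour = max(contours, key=lambda c: len(c))  # (row, col)
    xy = contour[:, ::-1]
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    if len(xy) < 8:
        raise ValueError("contour too short to fit")

    dense, spacing = _resample_closed(xy, max(1024, 4 * len(xy), 2 * n_points))
    if smoothing > 0:
        sig = smoothing / spacing
        dense = np.column_stack(
            [
                ndimage.gaussian_filter1d(dense[:, 0], sig, mode="wrap"),
                ndimage.gaussian_filter1d(dense[:, 1], sig, mode="wrap"),
            ]
        )
    pts, _ = _resample_closed(dense, n_points)
    bnd = Boundary(points=pts, frame=frame)
    return _orient(bnd, mask)


def _resample_closed(pts: np.ndarray, n: int) -> tuple[np.ndarray, float]:
    """Resample a closed polyline to n points at equal arc length."""
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    t = np.linspace(0, total, n, endpoint=False)
    x = np.interp(t, arc, closed[:, 0])
    y = np.interp(t, arc, closed[:, 1])
    return np.column_stack([x, y]), total / n


def intensity_boundary(
    frame: np.ndarray,
    anchor: tuple[float, float] | None = None,
    n_points: int = 1000,
    smoothing_sigma: float = 3.0,
    arc_smoothing: float = 3.0,
    threshold: float | str = "otsu",
    frame_index: int | None = None,
) -> Boundary:
    """Sub-pixel boundary from an intensity iso-contour (no binarization).

    The frame is Gaussian-smoothed (``smoothing_sigma``) and the iso-contour
    at the threshold level (per-frame Otsu by default) is traced directly on
    the smoothed intensities, so the boundary position is interpolated
    between pixels rather than snapped to a binary lattice.  With ``anchor``
    set, the shortest contour enclosing that (x, y) point is used — the
    natural choice for a hole (TEM) boundary with the hole center as anchor;
    without an anchor the longest contour is used (outer cell boundary).

    Rationale: curvature at the scales used here is badly corrupted by the
    staircase noise of binarized masks; intensity iso-contours avoid the
    lattice entirely.  The dense contour is additionally smoothed along arc
    length (periodic Gaussian, ``arc_smoothing`` px) before resampling to
    ``n_points``.  Orientation follows the Boundary contract (region with
    intensity above the threshold lies to the left).
    """
    frame = np.asarray(frame, dtype=float)
    sm = ndimage.gaussian_filter(frame, smoothing_sigma)
    level = filters.threshold_otsu(sm) if threshold == "otsu" else float(threshold)
    contours = measure.find_contours(sm, level)
    if not contours:
        raise NoRegionFoundError("no iso-contour at the threshold level")
    chosen = None
    if anchor is not None:
        pt = np.array([[anchor[1], anchor[0]]])  # (row, col) for points_in_poly
        for c in contours:
            if measure.points_in_poly(pt, c)[0] and (
                chosen is None or len(c) < len(chosen)
            ):
                chosen = c
        if chosen is None:
            raise NoRegionFoundError("no contour encloses the anchor point")
    else:
        chosen = max(contours, key=len)
    xy = chosen[:, ::-1]
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    if len(xy) < 8:
        raise NoRegionFoundError("contour too short to resample")
    dense, spacing = _resample_closed(xy, max(1024, 4 * len(xy), 2 * n_points))
    if arc_smoothing > 0:
        sig = arc_smoothing / spacing
        dense = np.column_stack(
            [
                ndimage.gaussian_filter1d(dense[:, 0], sig, mode="wrap"),
                ndimage.gaussian_filter1d(dense[:, 1], sig, mode="wrap"),
            ]
        )
    pts, _ = _resample_closed(dense, n_points)
    return _orient(Boundary(points=pts, frame=frame_index), sm >= level)


def _orient(boundary: Boundary, mask: np.ndarray, probe_dist: float = 2.0) -> Boundary:
    """Flip traversal direction if needed so mask interior is to the left."""
    H, W = mask.shape

    def in_frac(b: Boundary) -> float:
        p = b.points + probe_dist * b.left_normals()
        xi = np.clip(np.rint(p[:, 0]).astype(int), 0, W - 1)
        yi = np.clip(np.rint(p[:, 1]).astype(int), 0, H - 1)
        return float(mask[yi, xi].mean())

    fwd = in_frac(boundary)
    rev = Boundary(points=boundary.points[::-1].copy(), frame=boundary.frame)
    return boundary if fwd >= in_frac(rev) else rev


def make_doughnuts(
    tem_mask: np.ndarray,
    d1: int = 3,
    d2: int = 3,
    cell_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Concentric signal/background bands by successive dilations of a TEM mask.

    signal_band = dilate(tem, d1) \\ tem;
    background_band = dilate(dilate(tem, d1), d2) \\ dilate(tem, d1).
    Bands are clipped to ``cell_mask`` when given; clipped pixels trigger a
    warning with their count.
    """
    if d1 < 1 or d2 < 1:
        raise ValueError("dilation radii must be >= 1")
    tem = np.asarray(tem_mask, dtype=bool)
    dil1 = ndimage.binary_dilation(tem, structure=morphology.disk(int(d1)))
    dil2 = ndimage.binary_dilation(dil1, structure=morphology.disk(int(d2)))
    signal = dil1 & ~tem
    background = dil2 & ~dil1
    if cell_mask is not None:
        cell = np.asarray(cell_mask, dtype=bool)
        clipped = int((signal & ~cell).sum() + (background & ~cell).sum())
        total = int(signal.sum() + background.sum())
        # light clipping along a ragged cell edge is routine; only warn when
        # a substantial fraction of the bands is lost
        if total and clipped / total > 0.25:
            warnings.warn(
                f"doughnut bands clipped to the cell mask ({clipped} of "
                f"{total} px removed)",
                stacklevel=2,
            )
        signal &= cell
        background &= cell
    return signal, background


def boundary_band(
    boundary: Boundary, half_width: float, shape: tuple[int, int]
) -> np.ndarray:
    """Pixels whose centers lie within ``half_width`` (Euclidean px) of the
    boundary polyline (sub-pixel: distance measured to the polyline samples,
    not to rounded pixel positions)."""
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    H, W = shape
    tree = cKDTree(boundary.points)
    x0 = max(0, int(np.floor(boundary.x.min() - half_width - 1)))
    x1 = min(W - 1, int(np.ceil(boundary.x.max() + half_width + 1)))
    y0 = max(0, int(np.floor(boundary.y.min() - half_width - 1)))
    y1 = min(H - 1, int(np.ceil(boundary.y.max() + half_width + 1)))
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    dist, _ = tree.query(pts, k=1)
    band = np.zeros((H, W), dtype=bool)
    band[yy.ravel(), xx.ravel()] = dist <= half_width
    return band


def segment_rings(
    frame: np.ndarray,
    background_radius: float = 20.0,
    min_area: float = 20.0,
    max_area: float = 2000.0,
    smoothing_sigma: float = 1.0,
    threshold: float | str = "otsu",
) -> np.ndarray:
    """Label candidate ring particles.

    Rolling-ball background subtraction, light smoothing, thresholding and
    connected-component labeling with an area filter.  Returns an int label
    image (0 = background); an empty label set is allowed.
    """
    from skimage.restoration import rolling_ball

    frame = np.asarray(frame, dtype=float)
    if np.any(frame < 0):
        raise ValueError("frame must be nonnegative")
    sub = frame - rolling_ball(frame, radius=background_radius)
    if smoothing_sigma > 0:
        sub = ndimage.gaussian_filter(sub, smoothing_sigma)
    if threshold == "otsu":
        if sub.max() == sub.min():
            return np.zeros(frame.shape, dtype=int)
        thr = filters.threshold_otsu(sub)
    else:
        thr = float(threshold)
    mask = sub > thr
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return labels
    areas = np.bincount(labels.ravel())
    keep = np.flatnonzero((areas >= min_area) & (areas <= max_area))
    keep = keep[keep > 0]
    out = np.zeros_like(labels)
    for new, lab in enumerate(keep, start=1):
        out[labels == lab] = new
    return out


def align_masks(
    mask_ref: np.ndarray, mask_mov: np.ndarray, max_shift: int = 5
) -> tuple[np.ndarray, tuple[int, int]]:
    """Integer-pixel translation of ``mask_mov`` maximizing overlap with
    ``mask_ref`` (drift correction).  Returns (shifted mask, (dy, dx))."""
    best = (-1, (0, 0))
    mov = np.asarray(mask_mov, dtype=bool)
    ref = np.asarray(mask_ref, dtype=bool)
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            shifted = np.roll(np.roll(mov, dy, axis=0), dx, axis=1)
            score = int((shifted & ref).sum())
            if score > best[0]:
                best = (score, (dy, dx))
    dy, dx = best[1]
    return np.roll(np.roll(mov, dy, axis=0), dx, axis=1), (dy, dx)
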