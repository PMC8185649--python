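"""Segmentation: masks, boundaries, orientation contract, bands, rings."""

import numpy as np
import pytest
from scipy import ndimage

from memcurv.geometry import signed_curvature
from memcurv.segmentation import (
    NoRegionFoundError,
    align_masks,
    boundary_band,
    extract_boundary,
    intensity_boundary,
    make_doughnuts,
    segment_region,
    segment_rings,
)

from conftest import disk_mask


def _blurred_disk(shape=(128, 128), center=(64, 64), r=40.0, hi=200.0, lo=10.0):
    img = np.where(disk_mask(shape, center, r), hi, lo)
    return ndimage.gaussian_filter(img, 1.5)


# ---------------------------------------------------------------------------
# segment_region
# ---------------------------------------------------------------------------

def test_segment_region_recovers_disk():
    mask = segment_region(_blurred_disk(), erosion_radius=0)
    truth = disk_mask((128, 128), (64, 64), 40.0)
    inter = (mask & truth).sum()
    union = (mask | truth).sum()
    assert inter / union > 0.95


def test_segment_region_blank_raises():
    with pytest.raises(NoRegionFoundError):
        segment_region(np.zeros((64, 64)))


def test_segment_region_fixed_threshold_and_erosion():
    img = _blurred_disk()
    m0 = segment_region(img, threshold=100.0, erosion_radius=0)
    m2 = segment_region(img, threshold=100.0, erosion_radius=2)
    assert m2.sum() < m0.sum()
    assert not (m2 & ~m0).any()


# ---------------------------------------------------------------------------
# boundary extraction and orientation contract
# ---------------------------------------------------------------------------

def test_extract_boundary_orientation_disk():
    # interior on the left of traversal -> convex region has kappa < 0
    mask = disk_mask((128, 128), (64, 64), 40.0)
    b = extract_boundary(mask, n_points=1000, smoothing=3.0)
    kappa = signed_curvature(b, S=10)
    assert np.mean(kappa) < 0
    assert abs(np.mean(kappa) * 40.0 + 1.0) < 0.1


def test_extract_boundary_orientation_hole():
    cell = disk_mask((256, 256), (128, 128), 100.0)
    hole = disk_mask((256, 256), (128, 128), 30.0)
    b = extract_boundary(cell & ~hole, which="hole", anchor=(128.0, 128.0),
                         smoothing=3.0)
    kappa = signed_curvature(b, S=10)
    assert np.mean(kappa) > 0
    assert abs(np.mean(kappa) * 30.0 - 1.0) < 0.1


def test_boundary_equal_arc_resampling():
    mask = disk_mask((128, 128), (64, 64), 40.0)
    b = extract_boundary(mask, n_points=500)
    seg = np.diff(np.vstack([b.points, b.points[:1]]), axis=0)
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    assert lengths.std() / lengths.mean() < 0.05
    assert b.arc_length == pytest.approx(2 * np.pi * 40, rel=0.05)


def test_intensity_boundary_subpixel_radius():
    img = _blurred_disk(r=50.0)
    b = intensity_boundary(img, smoothing_sigma=1.0, arc_smoothing=1.0)
    radii = np.hypot(b.x - 64.0, b.y - 64.0)
    assert abs(radii.mean() - 50.0) < 1.0
    assert radii.std() < 0.5


def test_intensity_boundary_anchor_selects_hole():
    cell = disk_mask((256, 256), (128, 128), 100.0)
    hole = disk_mask((256, 256), (100, 128), 20.0)
    img = ndimage.gaussian_filter(np.where(cell & ~hole, 200.0, 10.0), 1.5)
    b = intensity_boundary(img, anchor=(100.0, 128.0))
    radii = np.hypot(b.x - 100.0, b.y - 128.0)
    assert abs(radii.mean() - 20.0) < 1.5
    # hole boundary of the cell region: positive curvature
    assert signed_curvature(b, S=10).mean() > 0


# ---------------------------------------------------------------------------
# doughnut masks and boundary bands
# ---------------------------------------------------------------------------

def test_make_doughnuts_geometry():
    hole = disk_mask((128, 128), (64, 64), 15.0)
    signal, background = make_doughnuts(hole, d1=3, d2=3)
    assert not (signal & hole).any()
    assert not (signal & background).any()
    assert not (background & hole).any()
    from skimage import morphology

    d1 = ndimage.binary_dilation(hole, structure=morphology.disk(3))
    assert (signal == (d1 & ~hole)).all()
    # annulus areas: ~2*pi*r*width each
    assert signal.sum() == pytest.approx(np.pi * (18**2 - 15**2), rel=0.1)
    assert background.sum() == pytest.approx(np.pi * (21**2 - 18**2), rel=0.1)


def test_make_doughnuts_clipped_by_cell_mask():
    hole = disk_mask((128, 128), (64, 64), 15.0)
    cell = disk_mask((128, 128), (64, 64), 19.0)
    with pytest.warns(UserWarning):
        signal, background = make_doughnuts(hole, d1=3, d2=3, cell_mask=cell)
    assert not (signal & ~cell).any()
    assert not (background & ~cell).any()
    # background band (radii ~18-21) mostly falls outside the r=19 cell
    full_background = np.pi * (21**2 - 18**2)
    assert background.sum() < 0.35 * full_background


def test_boundary_band_annulus_area():
    from conftest import circle_boundary

    band = boundary_band(circle_boundary(30.0, center=(64.0, 64.0)), 2.0,
                         (128, 128))
    assert band.sum() == pytest.approx(np.pi * (32**2 - 28**2), rel=0.05)


def test_boundary_band_straight_segment():
    from memcurv.segmentation import Boundary

    pts = np.column_stack([np.linspace(20.0, 80.0, 200),
                           np.full(200, 50.0)])
    pts = np.vstack([pts, pts[::-1] + [0.0, 0.01]])  # closed degenerate loop
    band = boundary_band(Boundary(pts), 1.0, (100, 100))
    # half_width 1 on a straight segment of length 60 -> area ~= 2 * 60
    assert band.sum() == pytest.approx(120, rel=0.15)


# ---------------------------------------------------------------------------
# rings and drift alignment
# ---------------------------------------------------------------------------

def test_segment_rings_counts_and_blank():
    from memcurv.synthetic import make_ring_field

    stack, _ = make_ring_field(n_rings=10, diameter_dist=(230.0, 0.0), seed=0)
    labels = segment_rings(stack.frame(0, 0), smoothing_sigma=0.5)
    assert labels.max() == 10
    blank = segment_rings(np.full((64, 64), 7.0))
    assert blank.max() == 0
    with pytest.raises(ValueError):
        segment_rings(np.full((32, 32), -1.0))


def test_align_masks_recovers_shift():
    ref = disk_mask((64, 64), (30, 30), 10.0)
    mov = np.roll(np.roll(ref, 3, axis=0), -2, axis=1)
    aligned, (dy, dx) = align_masks(ref, mov)
    assert (dy, dx) == (-3, 2)
    assert (aligned == ref).all()
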