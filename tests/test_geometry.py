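"""Geometry oracles: curvature, velocity, profiles, circle fits, perimeters."""

import numpy as np
import pandas as pd
import pytest

from memcurv.geometry import (
    angular_profile,
    contour_perimeter,
    edge_velocity,
    fit_circle,
    px_per_frame_to_um_per_min,
    ring_diameter,
    ring_table,
    signed_curvature,
    signed_distance_transform,
)
from memcurv.segmentation import Boundary

from conftest import circle_boundary, circle_points, disk_mask


# ---------------------------------------------------------------------------
# signed curvature
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("r", [15.0, 25.0, 50.0, 100.0])
@pytest.mark.parametrize("S", [5, 10, 44])
def test_curvature_circle_oracle(r, S):
    k_disk = signed_curvature(circle_boundary(r), S)
    k_hole = signed_curvature(circle_boundary(r, hole=True), S)
    assert np.max(np.abs(k_disk * r + 1.0)) < 0.01
    assert np.max(np.abs(k_hole * r - 1.0)) < 0.01


def test_curvature_straight_segments_zero():
    # square boundary: points on the flat sides, away from corners, are
    # collinear triples -> kappa exactly 0
    side = np.linspace(10.0, 110.0, 100, endpoint=False)
    pts = np.concatenate([
        np.column_stack([side, np.full(100, 10.0)]),
        np.column_stack([np.full(100, 110.0), side]),
        np.column_stack([side[::-1] + 1.0, np.full(100, 110.0)]),
        np.column_stack([np.full(100, 10.0), side[::-1] + 1.0]),
    ])
    kappa = signed_curvature(Boundary(pts), S=3)
    mid = np.abs(kappa[40:60])  # middle of the first side
    assert np.all(mid == 0.0)


def test_curvature_scale_parameter_validation():
    b = circle_boundary(20.0, n=100)
    with pytest.raises(ValueError):
        signed_curvature(b, S=0)
    with pytest.raises(ValueError):
        signed_curvature(b, S=50)


# ---------------------------------------------------------------------------
# signed distance transform and edge velocity
# ---------------------------------------------------------------------------

def test_sdt_interface_convention():
    mask = disk_mask((64, 64), (32, 32), 10.0)
    sdt = signed_distance_transform(mask)
    assert sdt[32, 32] > 8.0
    assert np.all(sdt[mask] > 0) and np.all(sdt[~mask] < 0)
    # pixels adjacent to the interface sit half a pixel from it
    inner_edge = mask & ~np.roll(mask, 1, axis=1)
    assert np.allclose(sdt[inner_edge].min(), 0.5)


@pytest.mark.parametrize("speed", [0.5, -0.5, 0.0])
def test_edge_velocity_oracle(speed):
    b = Boundary(circle_points(30.0, center=(64.0, 64.0)))
    prev = disk_mask((128, 128), (64, 64), 30.0 - speed)
    nxt = disk_mask((128, 128), (64, 64), 30.0 + speed)
    v = edge_velocity(b, prev, nxt)
    assert np.max(np.abs(v - speed)) < 0.5
    assert abs(v.mean() - speed) < 0.1


def test_edge_velocity_hole_closing_positive():
    # region = cell with a shrinking hole; closing hole -> advancing edge -> v > 0
    cell_prev = disk_mask((128, 128), (64, 64), 50.0) & ~disk_mask(
        (128, 128), (64, 64), 20.5
    )
    cell_next = disk_mask((128, 128), (64, 64), 50.0) & ~disk_mask(
        (128, 128), (64, 64), 19.5
    )
    b = Boundary(circle_points(20.0, center=(64.0, 64.0), hole=True))
    v = edge_velocity(b, cell_prev, cell_next)
    assert abs(v.mean() - 0.5) < 0.1


def test_edge_velocity_literal_average_mode():
    # for steady motion the literal average of the two SDTs measures the
    # residual distance offset at the frame-t boundary, ~0 here, not a speed
    b = Boundary(circle_points(30.0, center=(64.0, 64.0)))
    prev = disk_mask((128, 128), (64, 64), 29.5)
    nxt = disk_mask((128, 128), (64, 64), 30.5)
    v = edge_velocity(b, prev, nxt, mode="literal_average")
    assert abs(v.mean()) < 0.2
    with pytest.raises(ValueError):
        edge_velocity(b, prev, nxt, mode="nope")


# ---------------------------------------------------------------------------
# angular profiles
# ---------------------------------------------------------------------------

def test_angular_profile_recovers_binned_function():
    pts = circle_points(40.0, center=(0.0, 0.0), n=2000)
    theta = np.arctan2(pts[:, 1], pts[:, 0])
    values = np.cos(3.0 * theta)
    means, centers = angular_profile(values, pts, (0.0, 0.0), n_bins=50)
    assert centers.shape == (50,)
    # bin means approximate cos(3 theta) at the returned bin centers
    assert np.max(np.abs(means - np.cos(3.0 * np.radians(centers)))) < 0.05


def test_angular_profile_empty_bins_nan():
    pts = np.array([[1.0, 0.0], [0.0, 1.0]])  # bins 0 and 2 of 8
    means, centers = angular_profile(np.array([2.0, 4.0]), pts, (0.0, 0.0), 8)
    assert means[0] == 2.0 and means[2] == 4.0
    assert np.isnan(means[[1, 3, 4, 5, 6, 7]]).all()


# ---------------------------------------------------------------------------
# circle fits and ring morphometry
# ---------------------------------------------------------------------------

def test_fit_circle_exact():
    pts = circle_points(17.0, center=(5.0, -3.0), n=200)
    fit = fit_circle(pts)
    assert not fit.degenerate
    assert fit.radius == pytest.approx(17.0, abs=1e-9)
    assert fit.center[0] == pytest.approx(5.0, abs=1e-9)
    assert fit.center[1] == pytest.approx(-3.0, abs=1e-9)
    assert fit.kappa == pytest.approx(1 / 17.0, rel=1e-9)


def test_fit_circle_collinear_degenerate():
    pts = np.column_stack([np.linspace(0, 10, 20), np.linspace(0, 5, 20)])
    assert fit_circle(pts).degenerate


def test_ring_diameter_is_c_over_pi():
    assert ring_diameter(np.pi * 42.0) == pytest.approx(42.0)


def test_contour_perimeter_disk_and_square():
    disk = disk_mask((64, 64), (32, 32), 20.0)
    assert contour_perimeter(disk) == pytest.approx(2 * np.pi * 20, rel=0.02)
    square = np.zeros((64, 64), dtype=bool)
    square[20:41, 20:41] = True
    assert contour_perimeter(square) == pytest.approx(4 * 21, rel=0.05)
    with pytest.raises(ValueError):
        contour_perimeter(np.zeros((8, 8), dtype=bool))


def test_contour_perimeter_border_warning():
    m = np.zeros((32, 32), dtype=bool)
    m[0:10, 5:15] = True
    with pytest.warns(UserWarning, match="border"):
        contour_perimeter(m)


def test_ring_table_annulus_diameter():
    outer = disk_mask((64, 64), (32, 32), 12.0)
    inner = disk_mask((64, 64), (32, 32), 8.0)
    labels = (outer & ~inner).astype(int)
    tab = ring_table(labels, pixel_size_nm=23.0)
    assert len(tab) == 1
    assert bool(tab.loc[0, "has_hole"])
    # center-line diameter = 20 px
    assert tab.loc[0, "diameter_px"] == pytest.approx(20.0, rel=0.05)
    assert tab.loc[0, "diameter_nm"] == pytest.approx(20.0 * 23.0, rel=0.05)


def test_ring_table_empty():
    tab = ring_table(np.zeros((32, 32), dtype=int), pixel_size_nm=23.0)
    assert len(tab) == 0
    assert "diameter_nm" in tab.columns


def test_px_per_frame_conversion():
    # 1 px/frame at 160 nm pixels and 5 s interval = 0.16 um / (1/12) min
    assert px_per_frame_to_um_per_min(1.0, 160.0, 5.0) == pytest.approx(1.92)
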