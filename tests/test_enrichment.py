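"""Enrichment statistics: doughnut factors, classification, rotation scan,
colocalization and protrusion morphometrics."""

import numpy as np
import pandas as pd
import pytest

from memcurv.enrichment import (
    FLATTENING,
    LAGGING,
    NEITHER,
    background_correct,
    classify_regions,
    compartment_ratio,
    fold_enrichment,
    manders_m1,
    normalized_probe,
    perimeter_trend,
    protrusion_metrics,
    rotation_scan,
    scramble_control,
    tem_enrichment,
    velocity_signal_correlation,
)
from memcurv.segmentation import make_doughnuts

from conftest import disk_mask


# ---------------------------------------------------------------------------
# doughnut enrichment factor
# ---------------------------------------------------------------------------

def test_uniform_enrichment_is_exactly_one():
    cell = disk_mask((256, 256), (128, 128), 100.0)
    hole = disk_mask((256, 256), (128, 128), 20.0)
    frame = np.where(cell & ~hole, 137.0, 0.0)
    E, ipp = tem_enrichment(frame, hole, cell_mask=cell)
    assert E == pytest.approx(1.0, abs=1e-12)
    assert ipp == pytest.approx(0.0, abs=1e-9)


def test_doubled_signal_band_gives_factor_two():
    hole = disk_mask((128, 128), (64, 64), 15.0)
    signal, background = make_doughnuts(hole, 3, 3)
    frame = np.zeros((128, 128))
    frame[signal] = 20.0
    frame[background] = 10.0
    E, _ = tem_enrichment(frame, hole, 3, 3)
    assert E == pytest.approx(2.0, abs=1e-12)


def test_tem_enrichment_matches_brute_force(rng):
    hole = disk_mask((128, 128), (60, 70), 12.0)
    frame = rng.uniform(5.0, 50.0, size=(128, 128))
    signal, background = make_doughnuts(hole, 3, 3)
    E, ipp = tem_enrichment(frame, hole, 3, 3, perimeter=2 * np.pi * 12)
    bg_pa = frame[background].sum() / background.sum()
    E_ref = (frame[signal].sum() / signal.sum()) / bg_pa
    ipp_ref = (frame[signal].sum() - bg_pa * signal.sum()) / (2 * np.pi * 12)
    assert E == pytest.approx(E_ref, rel=1e-12)
    assert ipp == pytest.approx(ipp_ref, rel=1e-9)


# ---------------------------------------------------------------------------
# classification and fold enrichment
# ---------------------------------------------------------------------------

def test_classify_regions_rules():
    kappa = np.array([1.0, 1.0, -1.0, 1.0, np.nan])
    dk = np.array([-0.1, 0.2, -0.1, 0.0, -0.1])
    labels = classify_regions(kappa, dk)
    assert labels.tolist() == [FLATTENING, LAGGING, NEITHER, NEITHER, NEITHER]


def test_fold_enrichment_pools_and_handles_missing():
    labels = np.array([[FLATTENING, LAGGING], [FLATTENING, LAGGING]])
    normalized = np.array([[3.0, 1.0], [1.0, 1.0]])
    assert fold_enrichment(normalized, labels) == pytest.approx(2.0)
    assert fold_enrichment(np.ones((2, 2)), labels) == pytest.approx(1.0)
    only_flat = np.full((2, 2), FLATTENING, dtype=object)
    assert np.isnan(fold_enrichment(normalized, only_flat))


def test_normalized_probe_masks_nonpositive_membrane():
    probe = np.array([2.0, 4.0, 6.0])
    mem = np.array([1.0, 0.0, 2.0])
    out = normalized_probe(probe, mem)
    assert out[0] == 2.0 and out[2] == 3.0 and np.isnan(out[1])
    with pytest.raises(ValueError):
        normalized_probe(probe, np.zeros(3))


# ---------------------------------------------------------------------------
# rotation scan
# ---------------------------------------------------------------------------

def _enriched_tem(seed, n_frames=6, n_bins=50, fold=2.0):
    rng = np.random.default_rng(seed)
    labels = np.empty((n_frames, n_bins), dtype=object)
    labels[:] = NEITHER
    labels[:, :10] = FLATTENING
    labels[:, 25:35] = LAGGING
    normalized = rng.normal(1.0, 0.01, size=(n_frames, n_bins))
    normalized[:, :10] *= fold
    return normalized, labels


def test_rotation_scan_offset_zero_matches_fold_enrichment():
    tems = [_enriched_tem(s) for s in range(3)]
    res = rotation_scan([n for n, _ in tems], [l for _, l in tems])
    per_tem = [fold_enrichment(n, l) for n, l in tems]
    assert res.folds.shape == (50, 3)
    assert np.allclose(res.folds[0], per_tem)
    row0 = res.table.loc[res.table.offset == 0].iloc[0]
    assert row0["mean"] == pytest.approx(np.mean(per_tem))
    assert row0["n"] == 3
    # enrichment is aligned with the labels: zero offset is the scan maximum
    assert res.table.loc[res.table["mean"].idxmax(), "offset"] == 0
    assert row0["p"] < 0.05


def test_rotation_scan_uniform_probe_flat():
    rng = np.random.default_rng(1)
    tems = [_enriched_tem(s, fold=1.0) for s in range(3)]
    res = rotation_scan([n for n, _ in tems], [l for _, l in tems])
    assert np.nanmax(np.abs(res.table["mean"] - 1.0)) < 0.02


def test_rotation_scan_full_turn_closure():
    tems = [_enriched_tem(s) for s in range(2)]
    res = rotation_scan([n for n, _ in tems], [l for _, l in tems])
    # shifting by a full turn reproduces offset 0 exactly
    full_turn = [
        fold_enrichment(np.roll(n, 50, axis=1), l) for n, l in tems
    ]
    assert np.allclose(res.folds[0], full_turn)
    with pytest.raises(ValueError):
        rotation_scan([tems[0][0]], [tems[0][1]])


# ---------------------------------------------------------------------------
# background correction
# ---------------------------------------------------------------------------

def test_background_correct_constant_region_mean(rng):
    frame = np.full((64, 64), 7.0)
    frame[10:20, 10:20] += 100.0
    region = np.zeros((64, 64), dtype=bool)
    region[40:60, 40:60] = True
    out = background_correct(frame, mode="constant", region=region)
    assert np.allclose(out[region], 0.0)
    assert np.allclose(out[12, 12], 100.0)
    same = background_correct(frame, mode="none")
    assert same is not frame and np.array_equal(same, frame)
    with pytest.raises(ValueError):
        background_correct(frame, mode="constant")


def test_background_correct_rolling_ball_removes_offset():
    rng = np.random.default_rng(0)
    frame = 50.0 + rng.normal(0, 2, size=(128, 128))
    frame[60:68, 60:68] += 200.0
    out = background_correct(frame, mode="rolling_ball", radius=20)
    flat = np.ones((128, 128), dtype=bool)
    flat[50:78, 50:78] = False
    assert abs(out[flat].mean()) < 3.0
    assert out[60:68, 60:68].mean() > 150.0


# ---------------------------------------------------------------------------
# trends, correlations, colocalization
# ---------------------------------------------------------------------------

def test_perimeter_trend_monotone():
    assert perimeter_trend(np.array([5.0, 4.0, 3.0, 2.0])) == pytest.approx(-1.0)
    assert perimeter_trend(np.array([1.0, 2.0, 3.0])) == pytest.approx(1.0)
    assert np.isnan(perimeter_trend(np.array([2.0, 2.0, 2.0])))
    with pytest.raises(ValueError):
        perimeter_trend(np.array([1.0, 2.0]))


def test_velocity_signal_correlation_monotone():
    v = np.linspace(-1, 1, 40)
    df = pd.DataFrame({"v": v, "normalized": np.exp(v)})
    assert velocity_signal_correlation(df) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        velocity_signal_correlation(df.head(5))


def test_compartment_ratio_constructed():
    frame = np.full((64, 64), 10.0)  # cytosol level 10
    target = disk_mask((64, 64), (20, 20), 6.0)
    ref = disk_mask((64, 64), (45, 45), 8.0)
    cyt = ~(target | ref)
    frame[target] = 50.0  # corrected 40
    frame[ref] = 30.0  # corrected 20
    assert compartment_ratio(frame, target, ref, cyt) == pytest.approx(2.0)
    frame[ref] = 10.0  # corrected reference 0 -> undefined
    assert np.isnan(compartment_ratio(frame, target, ref, cyt))


def test_manders_m1_extremes():
    roi = np.ones((32, 32), dtype=bool)
    b = np.zeros((32, 32))
    b[:, 16:] = 10.0
    a_in = np.where(b > 0, 5.0, 0.0)
    a_out = np.where(b > 0, 0.0, 5.0)
    assert manders_m1(a_in, b, roi, b_threshold=1.0) == pytest.approx(1.0)
    assert manders_m1(a_out, b, roi, b_threshold=1.0) == pytest.approx(0.0)
    assert np.isnan(manders_m1(np.zeros((32, 32)), b, roi, b_threshold=1.0))


def test_scramble_control_uniform_and_enriched(rng):
    mask = disk_mask((64, 64), (32, 32), 10.0)
    uniform = np.full((64, 64), 3.0)
    m_sig, m_scr = scramble_control(uniform, mask, seed=0)
    assert m_sig == pytest.approx(m_scr)
    enriched = np.where(mask, 10.0, 1.0)
    m_sig, m_scr = scramble_control(enriched, mask, seed=0)
    assert m_sig > m_scr
    again = scramble_control(enriched, mask, seed=0)
    assert again == (m_sig, m_scr)


# ---------------------------------------------------------------------------
# protrusions
# ---------------------------------------------------------------------------

def test_protrusion_metrics_rectangle():
    m0 = np.zeros((64, 64), dtype=bool)
    m0[40:, :] = True  # flat front at y = 40
    m1 = m0.copy()
    m1[30:40, 20:24] = True  # 10 x 4 rectangular protrusion
    out = protrusion_metrics(m0, m1, elapsed=60.0)
    assert len(out) == 1
    row = out.iloc[0]
    assert row["area_px2"] == 40
    assert row["length_px"] == pytest.approx(10.0, abs=0.5)
    assert row["width_px"] == pytest.approx(4.0, abs=0.5)
    assert row["speed_px_per_min"] == pytest.approx(row["length_px"])


def test_protrusion_metrics_empty_and_min_area():
    m0 = np.zeros((32, 32), dtype=bool)
    m0[20:, :] = True
    out = protrusion_metrics(m0, m0, elapsed=60.0)
    assert len(out) == 0
    m1 = m0.copy()
    m1[19, 5:7] = True  # 2 px, below min_area
    assert len(protrusion_metrics(m0, m1, elapsed=60.0, min_area=4)) == 0
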