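"""Fluorescence-enrichment scoring against membrane geometry.

Implements the quantitative read-outs of the analysis: doughnut enrichment at
transendothelial macroaperture (TEM) rims, background-corrected intensity per
unit perimeter, the normalized probe (probe/membrane) signal, classification
of boundary bins into flattening vs lagging regions, the rotation null for
the flattening enrichment score, compartment ratios, Manders colocalization,
a scrambled-image control and protrusion morphometrics.

Conventions
-----------
* "Flattening" means positive curvature becoming less positive over time
  (kappa > 0 and d kappa/dt < 0); "lagging" means positive curvature growing
  (kappa > 0 and d kappa/dt > 0); everything else is "neither".
* Fold enrichment for one TEM pools all (frame, bin) samples of that TEM:
  mean normalized probe over flattening bins / mean over lagging bins.
* Undefined scores propagate as NaN, never as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import filters, restoration

from .geometry import contour_perimeter
from .segmentation import make_doughnuts

__all__ = [
    "FLATTENING",
    "LAGGING",
    "NEITHER",
    "RotationNullTable",
    "TemSeries",
    "background_correct",
    "classify_regions",
    "compartment_ratio",
    "fold_enrichment",
    "manders_m1",
    "normalized_probe",
    "perimeter_trend",
    "protrusion_metrics",
    "rotation_scan",
    "scramble_control",
    "tem_enrichment",
    "velocity_signal_correlation",
]

FLATTENING = "flattening"
LAGGING = "lagging"
NEITHER = "neither"


@dataclass
class TemSeries:
    """Per-frame morphometrics and angular profiles of one TEM.

    Attributes
    ----------
    table:
        One row per frame: frame, perimeter_px, perimeter_um, area_px2,
        enrichment_factor, intensity_per_perimeter.
    profiles:
        Per-channel (n_frames, n_bins) arrays of background-corrected mean
        band fluorescence per angular bin.
    """

    table: pd.DataFrame
    profiles: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# background correction
# ---------------------------------------------------------------------------

def background_correct(
    frame: np.ndarray,
    mode: str = "rolling_ball",
    *,
    radius: float = 50.0,
    constant: float | None = None,
    region: np.ndarray | None = None,
    smooth_sigma: float = 2.0,
    shrink: int = 4,
) -> np.ndarray:
    """Return a background-corrected copy of ``frame``.

    Parameters
    ----------
    mode:
        ``"rolling_ball"`` subtracts a rolling-ball background of the given
        ``radius``; ``"constant"`` subtracts a single offset, either the
        explicit ``constant`` or (if ``region`` is given) the mean intensity
        inside that boolean mask — the mean, not the median, because the
        mean of shot-noise counts estimates the true level without bias;
        ``"none"`` returns the frame unchanged.
    smooth_sigma:
        Rolling-ball only: the background is estimated on a Gaussian-smoothed
        copy (then subtracted from the original), so the ball rides on the
        signal rather than sinking into the pixel-noise floor — the same
        reason ImageJ's rolling ball smooths before estimating.
    shrink:
        Rolling-ball only: estimate the background on an image downscaled by
        this integer factor (ball radius scaled accordingly) and upsample the
        result — ImageJ's "shrink" speed-up; the background is smooth at the
        ball scale, so the approximation error is negligible.  1 disables.
    """
    frame = np.asarray(frame, dtype=float)
    if mode == "none":
        return frame.copy()
    if mode == "rolling_ball":
        est = ndimage.gaussian_filter(frame, smooth_sigma) if smooth_sigma > 0 else frame
        shrink = max(1, int(shrink))
        if shrink > 1 and min(frame.shape) >= 8 * shrink:
            small = ndimage.zoom(est, 1.0 / shrink, order=1)
            bg_small = restoration.rolling_ball(
                small, radius=max(1.0, radius / shrink)
            )
            bg = ndimage.zoom(bg_small, np.array(frame.shape) / np.array(bg_small.shape), order=1)
            # zoom rounding can leave a 1-px size mismatch; crop/pad to match
            bg = bg[: frame.shape[0], : frame.shape[1]]
            if bg.shape != frame.shape:
                bg = np.pad(bg, ((0, frame.shape[0] - bg.shape[0]),
                                 (0, frame.shape[1] - bg.shape[1])), mode="edge")
        else:
            bg = restoration.rolling_ball(est, radius=radius)
        return frame - bg
    if mode == "constant":
        if constant is None:
            if region is None:
                raise ValueError("constant mode needs `constant` or `region`")
            region = np.asarray(region, dtype=bool)
            if not region.any():
                raise ValueError("background region is empty")
            constant = float(frame[region].mean())
        return frame - float(constant)
    raise ValueError(f"unknown background mode {mode!r}")


# ---------------------------------------------------------------------------
# TEM doughnut enrichment
# ---------------------------------------------------------------------------

def tem_enrichment(
    frame: np.ndarray,
    tem_mask: np.ndarray,
    d1: int = 3,
    d2: int = 3,
    *,
    cell_mask: np.ndarray | None = None,
    perimeter: float | None = None,
) -> tuple[float, float]:
    """Doughnut enrichment factor and corrected intensity per unit perimeter.

    The signal band is the ``d1``-pixel dilation ring around the TEM mask and
    the background band the next ``d2``-pixel ring (see
    :func:`memcurv.segmentation.make_doughnuts`).  The enrichment factor is
    the RAW ratio of per-area mean intensities,

        E = (sum signal / area_signal) / (sum background / area_background),

    so a spatially uniform image scores exactly 1.  The per-perimeter
    quantity uses the background-corrected band sum,

        corrected = sum signal - (sum background / area_background) * area_signal,

    divided by the TEM boundary perimeter (computed from ``tem_mask`` unless
    ``perimeter`` is supplied).  Negative corrected intensity is reported
    as-is.
    """
    frame = np.asarray(frame, dtype=float)
    signal_band, background_band = make_doughnuts(
        tem_mask, d1=d1, d2=d2, cell_mask=cell_mask
    )
    area_sig = int(signal_band.sum())
    area_bg = int(background_band.sum())
    if area_sig == 0:
        raise ValueError("signal band is empty")
    if area_bg == 0:
        raise ValueError("background band is empty")
    sum_sig = float(frame[signal_band].sum())
    sum_bg = float(frame[background_band].sum())
    per_area_bg = sum_bg / area_bg
    if per_area_bg == 0:
        raise ValueError("background band has zero mean intensity")
    enrichment = (sum_sig / area_sig) / per_area_bg
    corrected = sum_sig - per_area_bg * area_sig
    if perimeter is None:
        perimeter = contour_perimeter(np.asarray(tem_mask, dtype=bool))
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return enrichment, corrected / perimeter


# ---------------------------------------------------------------------------
# normalized probe & classification
# ---------------------------------------------------------------------------

def normalized_probe(
    probe_profile: np.ndarray, membrane_profile: np.ndarray
) -> np.ndarray:
    """Elementwise probe/membrane ratio of background-corrected bin means.

    Bins with nonpositive membrane signal become NaN; if every membrane bin
    is nonpositive the ratio is undefined and an error is raised.  NaNs in
    either input propagate.
    """
    probe = np.asarray(probe_profile, dtype=float)
    membrane = np.asarray(membrane_profile, dtype=float)
    if probe.shape != membrane.shape:
        raise ValueError("profiles must share binning (same shape)")
    valid = membrane > 0
    if not valid.any():
        raise ValueError("all membrane bins are nonpositive")
    out = np.full(probe.shape, np.nan)
    out[valid] = probe[valid] / membrane[valid]
    return out


def classify_regions(
    kappa: np.ndarray, dkappa_dt: np.ndarray
) -> np.ndarray:
    """Label bins flattening / lagging / neither from curvature dynamics.

    flattening: kappa > 0 and d kappa/dt < 0 (becoming less positively curved)
    lagging:    kappa > 0 and d kappa/dt > 0
    neither:    kappa <= 0, d kappa/dt == 0, or either input NaN
    """
    kappa = np.asarray(kappa, dtype=float)
    dk = np.asarray(dkappa_dt, dtype=float)
    if kappa.shape != dk.shape:
        raise ValueError("kappa and dkappa_dt must share shape")
    labels = np.full(kappa.shape, NEITHER, dtype=object)
    with np.errstate(invalid="ignore"):
        labels[(kappa > 0) & (dk < 0)] = FLATTENING
        labels[(kappa > 0) & (dk > 0)] = LAGGING
    return labels


def fold_enrichment(normalized: np.ndarray, labels: np.ndarray) -> float:
    """Pooled fold enrichment: mean over flattening bins / mean over lagging.

    ``normalized`` and ``labels`` may be any matching shape (typically
    frames x bins for one TEM); all samples are pooled before the class
    means.  Returns NaN if either class is empty or has no finite values.
    """
    normalized = np.asarray(normalized, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if normalized.shape != labels.shape:
        raise ValueError("normalized and labels must share shape")
    flat = normalized[labels == FLATTENING]
    lag = normalized[labels == LAGGING]
    if flat.size == 0 or lag.size == 0:
        return float("nan")
    mf = np.nanmean(flat) if np.isfinite(flat).any() else np.nan
    ml = np.nanmean(lag) if np.isfinite(lag).any() else np.nan
    if not np.isfinite(mf) or not np.isfinite(ml) or ml == 0:
        return float("nan")
    return float(mf / ml)


# ---------------------------------------------------------------------------
# rotation null
# ---------------------------------------------------------------------------

@dataclass
class RotationNullTable:
    """Per-offset fold enrichments of a TEM cohort under circular rotation.

    Attributes
    ----------
    folds:
        Array (n_offsets, n_tems) of per-TEM fold enrichment at each offset.
    table:
        Tidy summary, one row per offset: offset (bins), offset_deg, mean,
        sd, n (valid TEMs), t, p (two-tailed one-sample t test vs 1).
    n_bins:
        Angular bin count the offsets index into.
    """

    folds: np.ndarray
    table: pd.DataFrame
    n_bins: int = 0
    offsets: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def rotation_scan(
    normalized_per_tem: list[np.ndarray],
    labels_per_tem: list[np.ndarray],
    n_rotations: int | None = None,
) -> RotationNullTable:
    """Rotation null for the flattening/lagging fold enrichment.

    For each integer offset k (0 .. n_rotations-1), every TEM's normalized
    fluorescence bins are circularly shifted by k bins while the
    flattening/lagging labels stay fixed, and the pooled fold enrichment is
    recomputed.  At each offset the per-TEM scores are tested against the
    null value 1 with a two-tailed one-sample t test; no multiple-testing
    correction is applied.  Offset 0 reproduces the unrotated score exactly,
    and a full turn (k = n_bins) would reproduce offset 0.

    Parameters
    ----------
    normalized_per_tem:
        One (n_frames, n_bins) array of normalized probe bin means per TEM.
    labels_per_tem:
        Matching label arrays from :func:`classify_regions`.
    n_rotations:
        Number of offsets to evaluate (default: the full turn, n_bins).
    """
    if len(normalized_per_tem) != len(labels_per_tem):
        raise ValueError("need one label array per TEM")
    if len(normalized_per_tem) < 2:
        raise ValueError("rotation scan needs >= 2 TEMs for the test")
    n_bins = normalized_per_tem[0].shape[-1]
    for arr, lab in zip(normalized_per_tem, labels_per_tem):
        if arr.shape != lab.shape:
            raise ValueError("normalized and labels must share shape per TEM")
        if arr.shape[-1] != n_bins:
            raise ValueError("bin counts must be equal across TEMs")
    if n_rotations is None:
        n_rotations = n_bins
    offsets = np.arange(n_rotations)
    folds = np.full((n_rotations, len(normalized_per_tem)), np.nan)
    for i, (norm, lab) in enumerate(zip(normalized_per_tem, labels_per_tem)):
        norm = np.asarray(norm, dtype=float)
        for j, k in enumerate(offsets):
            shifted = np.roll(norm, int(k), axis=-1)
            folds[j, i] = fold_enrichment(shifted, lab)
    rows = []
    bin_width_deg = 360.0 / n_bins
    for j, k in enumerate(offsets):
        vals = folds[j][np.isfinite(folds[j])]
        n = vals.size
        mean = float(vals.mean()) if n else float("nan")
        sd = float(vals.std(ddof=1)) if n > 1 else float("nan")
        if n >= 2 and sd > 0:
            t_stat, p = stats.ttest_1samp(vals, popmean=1.0)
            t_stat, p = float(t_stat), float(p)
        else:
            t_stat, p = float("nan"), float("nan")
        rows.append(
            {
                "offset": int(k),
                "offset_deg": float(k * bin_width_deg),
                "mean": mean,
                "sd": sd,
                "n": n,
                "t": t_stat,
                "p": p,
            }
        )
    return RotationNullTable(
        folds=folds, table=pd.DataFrame(rows), n_bins=n_bins, offsets=offsets
    )


# ---------------------------------------------------------------------------
# trends and correlations
# ---------------------------------------------------------------------------

def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with mid-ranked ties; NaN when undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(x, y).statistic
    return float(rho)


def perimeter_trend(
    intensity_per_perimeter: np.ndarray, x: np.ndarray | None = None
) -> float:
    """Spearman rho of per-perimeter intensity against frame index.

    ``x`` defaults to the frame index; pass perimeter values to correlate
    against perimeter instead.  Needs >= 3 frames; a constant series is
    undefined (NaN).
    """
    y = np.asarray(intensity_per_perimeter, dtype=float)
    if y.size < 3:
        raise ValueError("perimeter trend needs >= 3 frames")
    if x is None:
        x = np.arange(y.size, dtype=float)
    return _spearman(np.asarray(x, dtype=float), y)


def velocity_signal_correlation(edge_profile: pd.DataFrame) -> float:
    """Spearman rho of normalized probe vs edge velocity, pooled over bins.

    Expects an EdgeProfile-style tidy table with columns ``v`` and
    ``normalized``; all (frame, bin) samples of one cell or TEM are pooled.
    Needs >= 10 paired nonmissing samples; constant velocity is undefined.
    """
    if not {"v", "normalized"} <= set(edge_profile.columns):
        raise ValueError("edge profile needs `v` and `normalized` columns")
    v = edge_profile["v"].to_numpy(dtype=float)
    s = edge_profile["normalized"].to_numpy(dtype=float)
    ok = np.isfinite(v) & np.isfinite(s)
    if ok.sum() < 10:
        raise ValueError("need >= 10 paired nonmissing samples")
    return _spearman(v[ok], s[ok])


# ---------------------------------------------------------------------------
# compartments & colocalization
# ---------------------------------------------------------------------------

def compartment_ratio(
    frame: np.ndarray,
    target_mask: np.ndarray,
    reference_mask: np.ndarray,
    cytosol_mask: np.ndarray,
) -> float:
    """Ratio of background-corrected per-area intensities of two compartments.

    For each segment, corrected = sum(segment) - cytosolic-per-area-mean *
    area(segment); the score is (corrected_target / area_target) /
    (corrected_reference / area_reference).  A nonpositive corrected
    reference makes the ratio undefined (NaN).
    """
    frame = np.asarray(frame, dtype=float)
    target = np.asarray(target_mask, dtype=bool)
    reference = np.asarray(reference_mask, dtype=bool)
    cytosol = np.asarray(cytosol_mask, dtype=bool)
    if (target & reference).any() or (target & cytosol).any() or (
        reference & cytosol
    ).any():
        raise ValueError("masks must be pairwise disjoint")
    if not cytosol.any():
        raise ValueError("cytosol mask is empty")
    if not target.any() or not reference.any():
        raise ValueError("target and reference masks must be nonempty")
    cyto_per_area = float(frame[cytosol].mean())

    def corrected_per_area(mask: np.ndarray) -> float:
        area = int(mask.sum())
        return (float(frame[mask].sum()) - cyto_per_area * area) / area

    ref = corrected_per_area(reference)
    if ref <= 0:
        return float("nan")
    return corrected_per_area(target) / ref


def manders_m1(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    roi: np.ndarray,
    b_threshold: float | None = None,
) -> float:
    """Manders M1: fraction of channel-A signal in B-positive pixels.

    M1 = sum of A over {roi, B > threshold} / sum of A over roi, on
    background-subtracted inputs (the caller corrects the channels first).
    ``b_threshold`` defaults to Otsu's threshold of channel B within the roi.
    Undefined (NaN) when channel A carries no signal in the roi.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if a.shape != b.shape or a.shape != roi.shape:
        raise ValueError("channels and roi must share shape")
    if not roi.any():
        raise ValueError("roi is empty")
    if b_threshold is None:
        vals = b[roi]
        if np.all(vals == vals.flat[0]):
            raise ValueError("channel B is constant in roi; pass b_threshold")
        b_threshold = float(filters.threshold_otsu(vals))
    total = float(a[roi].sum())
    if total == 0:
        return float("nan")
    coloc = float(a[roi & (b > b_threshold)].sum())
    return coloc / total


def scramble_control(
    frame: np.ndarray, mask: np.ndarray, seed: int
) -> tuple[float, float]:
    """Mean in-mask intensity of the image and of a scrambled copy.

    The scrambled copy is a seeded uniform random permutation of ALL pixel
    values in the field; the same mask is then applied to both.  A spatially
    uniform image gives identical means; signal concentrated inside the mask
    gives mean_signal > mean_scrambled.
    """
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if frame.shape != mask.shape:
        raise ValueError("frame and mask must share shape")
    if not mask.any():
        raise ValueError("mask is empty")
    rng = np.random.default_rng(seed)
    scrambled = rng.permutation(frame.ravel()).reshape(frame.shape)
    return float(frame[mask].mean()), float(scrambled[mask].mean())


# ---------------------------------------------------------------------------
# protrusion morphometrics
# ---------------------------------------------------------------------------

def protrusion_metrics(
    mask_t0: np.ndarray,
    mask_t1: np.ndarray,
    elapsed: float,
    *,
    pixel_size: float | None = None,
    min_area: int = 4,
) -> pd.DataFrame:
    """Morphometrics of protrusion events between two aligned masks.

    Each connected component of ``mask_t1`` minus ``mask_t0`` (at least
    ``min_area`` px) is a protrusion.  Its length is the maximum
    distance-transform value inside the component measured from the t0
    region; its width is the chord of the component perpendicular to the
    extension axis at half the length; speed = length / elapsed.

    Parameters
    ----------
    elapsed:
        Time between the two masks, in seconds.
    pixel_size:
        If given (nm/px), micrometre columns are added and speed is reported
        in um/min as well as px/min.

    Returns
    -------
    DataFrame with one row per protrusion: label, area_px2, length_px,
    width_px, speed_px_per_min (and length_um, width_um, speed_um_per_min
    when calibrated).  No protrusions -> empty table.
    """
    m0 = np.asarray(mask_t0, dtype=bool)
    m1 = np.asarray(mask_t1, dtype=bool)
    if m0.shape != m1.shape:
        raise ValueError("masks must share shape")
    if elapsed <= 0:
        raise ValueError("elapsed must be positive")
    new = m1 & ~m0
    cols = ["label", "area_px2", "length_px", "width_px", "speed_px_per_min"]
    if pixel_size is not None:
        cols += ["length_um", "width_um", "speed_um_per_min"]
    if not new.any() or not m0.any():
        return pd.DataFrame(columns=cols)
    # distance of every pixel from the t0 region (0 inside t0)
    dist_from_t0 = ndimage.distance_transform_edt(~m0)
    labels, n_comp = ndimage.label(new)
    rows = []
    for lab in range(1, n_comp + 1):
        comp = labels == lab
        area = int(comp.sum())
        if area < min_area:
            continue
        d = dist_from_t0[comp]
        length = float(d.max())
        if length <= 0:
            continue
        yy, xx = np.nonzero(comp)
        # extension axis: from the component's root (pixels touching t0) to
        # its tip (farthest pixel)
        tip_i = int(np.argmax(d))
        tip = np.array([xx[tip_i], yy[tip_i]], dtype=float)
        root_sel = d <= max(1.0, 0.1 * length)
        root = np.array([xx[root_sel].mean(), yy[root_sel].mean()])
        axis = tip - root
        norm = np.hypot(*axis)
        axis = axis / norm if norm > 0 else np.array([0.0, 1.0])
        perp = np.array([-axis[1], axis[0]])
        # chord at half the length: pixels within half a pixel of d = L/2,
        # extent along the perpendicular direction
        band = np.abs(d - length / 2.0) <= 0.5
        if not band.any():
            band = np.abs(d - length / 2.0) <= 1.0
        proj = xx[band] * perp[0] + yy[band] * perp[1]
        width = float(proj.max() - proj.min() + 1.0)
        speed = length / elapsed * 60.0
        row = {
            "label": lab,
            "area_px2": area,
            "length_px": length,
            "width_px": width,
            "speed_px_per_min": speed,
        }
        if pixel_size is not None:
            nm = pixel_size
            row["length_um"] = length * nm / 1000.0
            row["width_um"] = width * nm / 1000.0
            row["speed_um_per_min"] = speed * nm / 1000.0
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)
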