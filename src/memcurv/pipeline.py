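"""End-to-end analyses driven by a serializable run configuration.

Each ``run_*`` function is a pure function of (inputs, RunConfig): all
randomness is seeded through the config, every output CSV embeds the config
hash and package version, and a persisted config re-executes to identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage import draw, filters

from . import __version__
from .enrichment import (
    RotationNullTable,
    TemSeries,
    background_correct,
    classify_regions,
    fold_enrichment,
    normalized_probe,
    perimeter_trend,
    protrusion_metrics,
    rotation_scan,
    tem_enrichment,
    velocity_signal_correlation,
)
from .geometry import angular_profile, edge_velocity, ring_table, signed_curvature
from .segmentation import (
    NoRegionFoundError,
    _holes_of,
    _largest_component,
    align_masks,
    boundary_band,
    intensity_boundary,
    segment_region,
    segment_rings,
)
from .stack import ImageStack

__all__ = [
    "ConfigError",
    "EdgeResult",
    "RingResult",
    "RunConfig",
    "TemResult",
    "run_edge_analysis",
    "run_protrusion_analysis",
    "run_ring_analysis",
    "run_tem_analysis",
]

logger = logging.getLogger("memcurv")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Serializable parameters of one analysis run.

    Defaults encode the printed settings of the underlying method:
    N = 1000 boundary points, curvature scale S = 10 for TEMs and S = 44 for
    the migrating-cell edge, 50 angular bins for TEMs and 1000 for the cell
    edge, and 3-px doughnut dilations.
    """

    # inputs / outputs
    inputs: list[str] = field(default_factory=list)
    out_dir: str = "results"
    membrane_channel: str = "membrane"
    probe_channel: str = "probe"

    # segmentation
    seg_sigma: float = 1.0          # mask-level smoothing (segment_region)
    threshold: float | str = "otsu"
    erosion_radius: float = 0.0
    contour_sigma: float = 3.0      # image smoothing before the iso-contour
    arc_smoothing: float = 3.0      # boundary smoothing along arc length (px)

    # geometry
    n_points: int = 1000
    s_tem: int = 10
    s_edge: int = 44
    n_bins_tem: int = 50
    n_bins_edge: int = 1000
    velocity_mode: str = "central"  # or "literal_average"
    derivative: str = "central"     # d kappa/dt: "central" or "forward"

    # enrichment
    d1: int = 3
    d2: int = 3
    band_half_width: float = 3.0
    background_mode: str = "rolling_ball"  # or "constant", "none"
    background_radius: float = 50.0

    # edge analysis
    border_margin: float = 8.0

    # rings
    ring_background_radius: float = 20.0
    ring_min_area: float = 20.0
    ring_max_area: float = 2000.0
    ring_hist_bin_nm: float = 20.0

    # protrusions
    drift_correct: bool = True
    protrusion_min_area: int = 4

    # misc
    seed: int = 0
    pixel_size: float | None = None      # nm/px override
    frame_interval: float | None = None  # s override

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_points < 8:
            raise ConfigError("n_points must be >= 8")
        for name in ("s_tem", "s_edge"):
            s = getattr(self, name)
            if not 1 <= s < self.n_points // 2:
                raise ConfigError(f"{name} must be in [1, n_points/2)")
        if self.n_bins_tem < 2 or self.n_bins_edge < 2:
            raise ConfigError("bin counts must be >= 2")
        if self.d1 < 1 or self.d2 < 1:
            raise ConfigError("doughnut dilations must be >= 1 px")
        if self.background_mode not in ("rolling_ball", "constant", "none"):
            raise ConfigError(f"unknown background mode {self.background_mode!r}")
        if self.velocity_mode not in ("central", "literal_average"):
            raise ConfigError(f"unknown velocity mode {self.velocity_mode!r}")
        if self.derivative not in ("forward", "central"):
            raise ConfigError(f"unknown derivative mode {self.derivative!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    @property
    def hash(self) -> str:
        """Fingerprint of the analysis parameters.

        Input and output locations are excluded so the same parameters hash
        identically wherever the data live and the results are written.
        """
        d = self.to_dict()
        d.pop("inputs", None)
        d.pop("out_dir", None)
        text = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# provenance-stamped CSV I/O
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# memcurv {__version__}\n")
        fh.write(f"# config_sha256: {config.hash}\n")
        df.to_csv(fh, index=False)
    logger.info("wrote %s (%d rows)", path, len(df))


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the provenance header."""
    return pd.read_csv(path, comment="#")


def _load_stacks(config: RunConfig, stacks) -> list[ImageStack]:
    if stacks is not None:
        return list(stacks)
    if not config.inputs:
        raise ConfigError("no inputs given (config.inputs is empty)")
    out = []
    for p in config.inputs:
        if not Path(p).exists():
            raise ConfigError(f"input not found: {p}")
        out.append(ImageStack.from_tiff(p))
    return out


def _calibrate(stack: ImageStack, config: RunConfig) -> tuple[float, float]:
    px = config.pixel_size if config.pixel_size is not None else stack.pixel_size
    dt = (
        config.frame_interval
        if config.frame_interval is not None
        else stack.frame_interval
    )
    return px, dt


def _require_channels(stack: ImageStack, config: RunConfig) -> None:
    for name in (config.membrane_channel, config.probe_channel):
        if name not in stack.channel_names:
            raise ConfigError(
                f"missing channel {name!r}; stack has {stack.channel_names}"
            )


def _background(frame: np.ndarray, config: RunConfig, region=None) -> np.ndarray:
    if config.background_mode == "constant":
        return background_correct(frame, "constant", region=region)
    return background_correct(
        frame, config.background_mode, radius=config.background_radius
    )


def _dkappa_dt(kappa: np.ndarray, mode: str) -> np.ndarray:
    """Per-bin curvature time derivative; rows where undefined are NaN."""
    out = np.full_like(kappa, np.nan)
    if mode == "forward":
        out[:-1] = np.diff(kappa, axis=0)
    else:  # central
        out[1:-1] = (kappa[2:] - kappa[:-2]) / 2.0
    return out


# ---------------------------------------------------------------------------
# TEM analysis
# ---------------------------------------------------------------------------

@dataclass
class TemResult:
    tem_series: list[TemSeries]
    edge_profiles: list[pd.DataFrame]
    rotation: RotationNullTable | None
    summary: pd.DataFrame


def _analyze_one_tem(
    stack: ImageStack, config: RunConfig, tem_id: int
) -> tuple[TemSeries, pd.DataFrame]:
    """Per-frame hole analysis of one TEM stack."""
    membrane = stack.channel(config.membrane_channel)
    probe = stack.channel(config.probe_channel)
    px_nm, _ = _calibrate(stack, config)
    n_bins = config.n_bins_tem
    H, W = stack.shape
    yy, xx = np.mgrid[0:H, 0:W]

    # crisp (lightly smoothed) masks for doughnuts and velocity; the heavier
    # contour_sigma smoothing is reserved for the curvature boundary, where
    # lattice noise matters more than edge placement
    anchor = None
    cell_masks: list[np.ndarray | None] = []
    hole_masks: list[np.ndarray | None] = []
    for t in range(stack.n_frames):
        sm = ndimage.gaussian_filter(membrane[t], config.seg_sigma)
        level = (
            filters.threshold_otsu(sm)
            if config.threshold == "otsu"
            else float(config.threshold)
        )
        try:
            cell = _largest_component(sm >= level)
        except NoRegionFoundError:
            cell = None
        cell_masks.append(cell)
        hole_masks.append(_holes_of(cell) if cell is not None else None)
        if anchor is None and hole_masks[-1] is not None and hole_masks[-1].any():
            hy, hx = np.nonzero(hole_masks[-1])
            anchor = (float(hx.mean()), float(hy.mean()))
    if anchor is None:
        raise NoRegionFoundError(f"TEM {tem_id}: no interior hole found")
    ax, ay = int(round(anchor[0])), int(round(anchor[1]))

    rows, prof_rows = [], []
    profiles: dict[str, list[np.ndarray]] = {"membrane": [], "probe": []}
    kappa_bins = np.full((stack.n_frames, n_bins), np.nan)
    v_bins = np.full((stack.n_frames, n_bins), np.nan)
    valid = np.zeros(stack.n_frames, dtype=bool)
    boundaries: list = [None] * stack.n_frames

    for t in range(stack.n_frames):
        try:
            b = intensity_boundary(
                membrane[t],
                anchor=anchor,
                n_points=config.n_points,
                smoothing_sigma=config.contour_sigma,
                arc_smoothing=config.arc_smoothing,
                threshold=config.threshold,
                frame_index=t,
            )
        except NoRegionFoundError as exc:
            logger.warning("TEM %d frame %d skipped: %s", tem_id, t, exc)
            profiles["membrane"].append(np.full(n_bins, np.nan))
            profiles["probe"].append(np.full(n_bins, np.nan))
            continue
        boundaries[t] = b
        valid[t] = True

        # doughnut mask: the crisply segmented hole containing the anchor
        # (the smoothed polygon would sit too far down the rim flank)
        tem_mask = None
        if hole_masks[t] is not None and hole_masks[t].any():
            lab, _ = ndimage.label(hole_masks[t])
            if lab[ay, ax]:
                tem_mask = lab == lab[ay, ax]
        if tem_mask is None:
            tem_mask = draw.polygon2mask((H, W), b.points[:, ::-1])
        perimeter = b.arc_length
        area = int(tem_mask.sum())
        enr, ipp = tem_enrichment(
            probe[t],
            tem_mask,
            d1=config.d1,
            d2=config.d2,
            cell_mask=cell_masks[t],
            perimeter=perimeter,
        )
        # same estimator on the membrane channel so per-channel trends are
        # directly comparable (band-geometry artifacts cancel in the contrast)
        _, mem_ipp = tem_enrichment(
            membrane[t],
            tem_mask,
            d1=config.d1,
            d2=config.d2,
            cell_mask=cell_masks[t],
            perimeter=perimeter,
        )
        rows.append(
            {
                "frame": t,
                "perimeter_px": perimeter,
                "perimeter_um": perimeter * px_nm / 1000.0,
                "area_px2": area,
                "enrichment_factor": enr,
                "intensity_per_perimeter": ipp,
                "membrane_intensity_per_perimeter": mem_ipp,
            }
        )

        # curvature profile
        kappa = signed_curvature(b, config.s_tem)
        kappa_bins[t] = angular_profile(kappa, b.points, anchor, n_bins)[0]

        # band fluorescence, background corrected; the band is centered on a
        # crisp (lightly smoothed) boundary so it straddles the membrane rim —
        # the heavy curvature smoothing displaces the contour down the rim
        # flank, which does not matter for kappa but would for photometry
        try:
            b_band = intensity_boundary(
                membrane[t],
                anchor=anchor,
                n_points=config.n_points,
                smoothing_sigma=config.seg_sigma,
                arc_smoothing=config.seg_sigma,
                threshold=config.threshold,
                frame_index=t,
            )
        except NoRegionFoundError:
            b_band = b
        hole_interior = ndimage.binary_erosion(tem_mask, iterations=3)
        bg_region = hole_interior if hole_interior.any() else tem_mask
        band = boundary_band(b_band, config.band_half_width, (H, W))
        coords = np.column_stack([xx[band], yy[band]])
        mem_c = _background(membrane[t], config, region=bg_region)
        pro_c = _background(probe[t], config, region=bg_region)
        profiles["membrane"].append(
            angular_profile(mem_c[band], coords, anchor, n_bins)[0]
        )
        profiles["probe"].append(
            angular_profile(pro_c[band], coords, anchor, n_bins)[0]
        )

    if not valid.any():
        raise NoRegionFoundError(f"TEM {tem_id}: no usable frames")

    # edge velocity (central difference needs both neighbors)
    for t in range(stack.n_frames):
        if not valid[t]:
            continue
        tp, tn = t - 1, t + 1
        if tp < 0 or tn >= stack.n_frames:
            continue
        if cell_masks[tp] is None or cell_masks[tn] is None:
            continue
        v = edge_velocity(
            boundaries[t], cell_masks[tp], cell_masks[tn], mode=config.velocity_mode
        )
        v_bins[t] = angular_profile(v, boundaries[t].points, anchor, n_bins)[0]

    mem_prof = np.array(profiles["membrane"])
    pro_prof = np.array(profiles["probe"])
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(mem_prof > 0, pro_prof / mem_prof, np.nan)
    dk = _dkappa_dt(kappa_bins, config.derivative)

    bin_width = 360.0 / n_bins
    for t in range(stack.n_frames):
        for j in range(n_bins):
            prof_rows.append(
                {
                    "tem": tem_id,
                    "frame": t,
                    "bin": j,
                    "theta_deg": j * bin_width,
                    "kappa": kappa_bins[t, j],
                    "dkappa_dt": dk[t, j],
                    "v": v_bins[t, j],
                    "mean_membrane": mem_prof[t, j],
                    "mean_probe": pro_prof[t, j],
                    "normalized": normalized[t, j],
                }
            )
    series = TemSeries(
        table=pd.DataFrame(rows),
        profiles={"membrane": mem_prof, "probe": pro_prof},
    )
    return series, pd.DataFrame(prof_rows)


def run_tem_analysis(
    config: RunConfig, stacks: list[ImageStack] | None = None
) -> TemResult:
    """Full TEM pipeline: segmentation, enrichment, curvature dynamics,
    classification and the rotation null over the cohort.

    Each input stack is treated as one TEM (membrane + probe channels).
    Frames without a detectable hole are skipped with a logged reason.
    """
    config.validate()
    stacks = _load_stacks(config, stacks)
    out = Path(config.out_dir)
    tem_series: list[TemSeries] = []
    edge_profiles: list[pd.DataFrame] = []
    norm_per_tem, labels_per_tem = [], []
    summary_rows = []

    for i, stack in enumerate(stacks):
        _require_channels(stack, config)
        series, profile = _analyze_one_tem(stack, config, i)
        tem_series.append(series)
        edge_profiles.append(profile)
        _write_csv(series.table, out / f"tem_series_{i}.csv", config)
        _write_csv(profile, out / f"edge_profile_{i}.csv", config)

        n_bins = config.n_bins_tem
        kappa = profile["kappa"].to_numpy().reshape(-1, n_bins)
        dk = profile["dkappa_dt"].to_numpy().reshape(-1, n_bins)
        normalized = profile["normalized"].to_numpy().reshape(-1, n_bins)
        labels = classify_regions(kappa, dk)
        ok_rows = np.isfinite(dk).any(axis=1)
        norm_per_tem.append(normalized[ok_rows])
        labels_per_tem.append(labels[ok_rows])
        fold = fold_enrichment(normalized[ok_rows], labels[ok_rows])
        ipp = series.table["intensity_per_perimeter"].to_numpy()
        trend_probe = (
            perimeter_trend(ipp) if len(ipp) >= 3 else float("nan")
        )
        # membrane per-perimeter trend (same doughnut estimator as the probe)
        mem_ipp = series.table["membrane_intensity_per_perimeter"].to_numpy()
        trend_mem = (
            perimeter_trend(mem_ipp) if len(mem_ipp) >= 3 else float("nan")
        )
        summary_rows.append(
            {
                "tem": i,
                "n_frames": len(series.table),
                "fold_enrichment": fold,
                "trend_rho_probe": trend_probe,
                "trend_rho_membrane": trend_mem,
            }
        )

    rotation = None
    if len(norm_per_tem) >= 2:
        rotation = rotation_scan(norm_per_tem, labels_per_tem)
        _write_csv(rotation.table, out / "rotation_null.csv", config)
    summary = pd.DataFrame(summary_rows)
    _write_csv(summary, out / "tem_summary.csv", config)
    config.to_yaml(out / "config.yaml")
    return TemResult(tem_series, edge_profiles, rotation, summary)


# ---------------------------------------------------------------------------
# leading-edge analysis
# ---------------------------------------------------------------------------

@dataclass
class EdgeResult:
    profile: pd.DataFrame
    rho: float
    n_samples: int


def run_edge_analysis(
    config: RunConfig, stacks: list[ImageStack] | None = None
) -> EdgeResult:
    """Migrating-cell edge pipeline: outer-boundary curvature and velocity
    against normalized probe signal (1000-bin mode, S = 44 by default)."""
    config.validate()
    stack = _load_stacks(config, stacks)[0]
    _require_channels(stack, config)
    membrane = stack.channel(config.membrane_channel)
    probe = stack.channel(config.probe_channel)
    n_bins = config.n_bins_edge
    H, W = stack.shape
    yy, xx = np.mgrid[0:H, 0:W]
    out = Path(config.out_dir)

    masks, boundaries = [], []
    for t in range(stack.n_frames):
        mask = segment_region(
            membrane[t],
            smoothing_sigma=config.seg_sigma,
            threshold=config.threshold,
            erosion_radius=config.erosion_radius,
        )
        masks.append(mask)
        boundaries.append(
            intensity_boundary(
                membrane[t],
                anchor=None,
                n_points=config.n_points,
                smoothing_sigma=config.contour_sigma,
                arc_smoothing=config.arc_smoothing,
                threshold=config.threshold,
                frame_index=t,
            )
        )
    center = boundaries[0].centroid()

    kappa_bins = np.full((stack.n_frames, n_bins), np.nan)
    v_bins = np.full((stack.n_frames, n_bins), np.nan)
    mem_prof = np.full((stack.n_frames, n_bins), np.nan)
    pro_prof = np.full((stack.n_frames, n_bins), np.nan)
    border_ok = np.ones((stack.n_frames, n_bins), dtype=bool)
    m = config.border_margin

    for t in range(stack.n_frames):
        b = boundaries[t]
        kappa = signed_curvature(b, config.s_edge)
        kappa_bins[t] = angular_profile(kappa, b.points, center, n_bins)[0]
        # bins whose boundary points hug the image border are unreliable
        near = (
            (b.x < m) | (b.x > W - 1 - m) | (b.y < m) | (b.y > H - 1 - m)
        ).astype(float)
        frac_near = angular_profile(near, b.points, center, n_bins)[0]
        border_ok[t] = ~(np.nan_to_num(frac_near, nan=1.0) > 0)
        if 0 < t < stack.n_frames - 1:
            v = edge_velocity(b, masks[t - 1], masks[t + 1], mode=config.velocity_mode)
            v_bins[t] = angular_profile(v, b.points, center, n_bins)[0]
        band = boundary_band(b, config.band_half_width, (H, W))
        coords = np.column_stack([xx[band], yy[band]])
        mem_c = _background(membrane[t], config, region=~masks[t])
        pro_c = _background(probe[t], config, region=~masks[t])
        mem_prof[t] = angular_profile(mem_c[band], coords, center, n_bins)[0]
        pro_prof[t] = angular_profile(pro_c[band], coords, center, n_bins)[0]

    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(mem_prof > 0, pro_prof / mem_prof, np.nan)
    normalized[~border_ok] = np.nan
    v_bins[~border_ok] = np.nan
    dk = _dkappa_dt(kappa_bins, config.derivative)

    bin_width = 360.0 / n_bins
    frames = np.repeat(np.arange(stack.n_frames), n_bins)
    bins = np.tile(np.arange(n_bins), stack.n_frames)
    profile = pd.DataFrame(
        {
            "frame": frames,
            "bin": bins,
            "theta_deg": bins * bin_width,
            "kappa": kappa_bins.ravel(),
            "dkappa_dt": dk.ravel(),
            "v": v_bins.ravel(),
            "mean_membrane": mem_prof.ravel(),
            "mean_probe": pro_prof.ravel(),
            "normalized": normalized.ravel(),
        }
    )
    rho = velocity_signal_correlation(profile)
    n = int((np.isfinite(v_bins) & np.isfinite(normalized)).sum())
    _write_csv(profile, out / "edge_profile.csv", config)
    _write_csv(
        pd.DataFrame([{"rho": rho, "n_samples": n}]),
        out / "edge_correlation.csv",
        config,
    )
    config.to_yaml(out / "config.yaml")
    return EdgeResult(profile, rho, n)


# ---------------------------------------------------------------------------
# ring analysis
# ---------------------------------------------------------------------------

@dataclass
class RingResult:
    table: pd.DataFrame
    summary: pd.DataFrame
    empty: bool


def run_ring_analysis(
    config: RunConfig, stacks: list[ImageStack] | None = None
) -> RingResult:
    """Ring morphometry: segmentation, center-line perimeter, d = C/pi,
    and a diameter histogram summary (median; mode at a stated bin width)."""
    config.validate()
    stack = _load_stacks(config, stacks)[0]
    px_nm, _ = _calibrate(stack, config)
    frame = stack.frame(0, 0)
    out = Path(config.out_dir)
    labels = segment_rings(
        frame,
        background_radius=config.ring_background_radius,
        min_area=config.ring_min_area,
        max_area=config.ring_max_area,
        smoothing_sigma=config.seg_sigma / 2.0,
        threshold=config.threshold,
    )
    table = ring_table(labels, pixel_size_nm=px_nm)
    empty = len(table) == 0
    if empty:
        summary = pd.DataFrame(
            [{"n_rings": 0, "median_nm": np.nan, "mode_nm": np.nan,
              "mode_bin_nm": config.ring_hist_bin_nm, "empty": True}]
        )
    else:
        d = table["diameter_nm"].to_numpy()
        w = config.ring_hist_bin_nm
        edges = np.arange(0.0, d.max() + w, w)
        counts, edges = np.histogram(d, bins=edges)
        mode_center = float(edges[np.argmax(counts)] + w / 2.0)
        summary = pd.DataFrame(
            [{"n_rings": len(table), "median_nm": float(np.median(d)),
              "mode_nm": mode_center, "mode_bin_nm": w, "empty": False}]
        )
    _write_csv(table, out / "ring_table.csv", config)
    _write_csv(summary, out / "ring_summary.csv", config)
    config.to_yaml(out / "config.yaml")
    return RingResult(table, summary, empty)


# ---------------------------------------------------------------------------
# protrusion analysis
# ---------------------------------------------------------------------------

def run_protrusion_analysis(
    config: RunConfig, stacks: list[ImageStack] | None = None
) -> pd.DataFrame:
    """Protrusion metrics for every consecutive frame pair of the stack."""
    config.validate()
    stack = _load_stacks(config, stacks)[0]
    px_nm, dt = _calibrate(stack, config)
    membrane = stack.channel(config.membrane_channel)
    out = Path(config.out_dir)
    masks = []
    for t in range(stack.n_frames):
        mask = segment_region(
            membrane[t],
            smoothing_sigma=config.seg_sigma,
            threshold=config.threshold,
            erosion_radius=config.erosion_radius,
        )
        masks.append(ndimage.binary_fill_holes(mask))
    tables = []
    for t in range(stack.n_frames - 1):
        m0, m1 = masks[t], masks[t + 1]
        if config.drift_correct:
            m1, _ = align_masks(m0, m1)
        tab = protrusion_metrics(
            m0, m1, elapsed=dt, pixel_size=px_nm,
            min_area=config.protrusion_min_area,
        )
        tab.insert(0, "frame_pair", f"{t}-{t + 1}")
        tables.append(tab)
    result = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=["frame_pair"])
    )
    _write_csv(result, out / "protrusions.csv", config)
    config.to_yaml(out / "config.yaml")
    return result
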