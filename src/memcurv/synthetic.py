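"""Seeded synthetic-microscopy generator with analytic ground truth.

Three scenarios are emulated, each returning an :class:`~memcurv.stack.ImageStack`
plus a :class:`GroundTruth` record of the exact geometry and coupling used:

* a closing transendothelial macroaperture (TEM): a circular hole in a cell
  whose radius shrinks linearly, optionally perturbed by a decaying sinusoidal
  "lag" mode so that both flattening (curvature decreasing) and lagging
  (curvature increasing) boundary regions exist;
* an advancing leading edge whose local speed varies along the front, with a
  probe whose boundary intensity is an affine function of local edge speed;
* a field of annular nanorings of known diameter.

All scenarios share the same imaging model: intensities are deposited either
per pixel (cell body) or per boundary point (membrane rim / probe), blurred by
an isotropic unit-sum Gaussian PSF, then corrupted by a constant background,
Poisson shot noise and additive Gaussian read noise.  Every stack is a pure
function of (parameters, seed): the master seed spawns fixed, named substreams
(placement, Poisson, read noise) so changing one noise source does not shift
the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .stack import ImageStack

__all__ = [
    "NoiseParams",
    "GroundTruth",
    "make_closing_tem",
    "make_leading_edge",
    "make_ring_field",
    "make_tem_cohort",
    "calibrate_flattening_coupling",
    "true_fold_enrichment",
    "save_synthetic",
]

# substream order is part of the reproducibility contract
_STREAMS = ("placement", "poisson", "read")


@dataclass(frozen=True)
class NoiseParams:
    """Fluorescence-detection noise model.

    background : constant offset (counts) added before shot noise
    poisson    : apply Poisson shot noise to (signal + background)
    read_sigma : SD of additive Gaussian read noise (counts)
    """

    background: float = 100.0
    poisson: bool = True
    read_sigma: float = 4.0

    @staticmethod
    def none() -> "NoiseParams":
        return NoiseParams(background=0.0, poisson=False, read_sigma=0.0)


@dataclass
class GroundTruth:
    """Generator-side record of the true geometry and coupling.

    Only the fields relevant to the generating scenario are populated.
    Angles follow the image convention used throughout the package:
    theta = atan2(y - cy, x - cx) with y increasing downward.
    """

    scenario: str
    seed: int
    params: dict
    psf_sigma: float
    noise: NoiseParams
    # closing-TEM scenario
    hole_center: tuple[float, float] | None = None  # (x, y) px
    radius: np.ndarray | None = None                # (T,) mean hole radius px
    theta: np.ndarray | None = None                 # (n_pts,) rad
    kappa_true: np.ndarray | None = None            # (T, n_pts) 1/px, hole positive
    v_true: np.ndarray | None = None                # (T, n_pts) px/frame, closing positive
    probe_deposit: np.ndarray | None = None         # (T, n_pts) deposited probe per point
    membrane_edge_deposit: float | None = None      # per-point membrane rim intensity
    coupling: tuple[float, float, float] | None = None  # (b0, b1, b2)
    cell_masks: np.ndarray | None = None            # (T, Y, X) bool, cell minus hole
    # leading-edge scenario
    front_y: np.ndarray | None = None               # (T, X) px
    v_true_edge: np.ndarray | None = None           # (T, X) px/frame, protruding positive
    probe_deposit_edge: np.ndarray | None = None    # (T, X)
    # ring-field scenario
    rings: pd.DataFrame | None = None               # ring, cx, cy, diameter_px, diameter_nm

    def truth_table(self) -> pd.DataFrame:
        """Tidy (frame, theta_bin, kappa_true, v_true, probe_deposited) table."""
        if self.kappa_true is None:
            raise ValueError("truth table is defined for the closing-TEM scenario")
        T, n = self.kappa_true.shape
        frames = np.repeat(np.arange(T), n)
        bins = np.tile(np.arange(n), T)
        return pd.DataFrame(
            {
                "frame": frames,
                "theta_bin": bins,
                "kappa_true": self.kappa_true.ravel(),
                "v_true": self.v_true.ravel(),
                "probe_deposited": self.probe_deposit.ravel(),
            }
        )


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _splat(image: np.ndarray, x: np.ndarray, y: np.ndarray, amp: np.ndarray) -> None:
    """Deposit point intensities with bilinear weights (sum-preserving)."""
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx = x - x0
    fy = y - y0
    H, W = image.shape
    for dx, dy, w in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        xi = x0 + dx
        yi = y0 + dy
        ok = (xi >= 0) & (xi < W) & (yi >= 0) & (yi < H)
        np.add.at(image, (yi[ok], xi[ok]), amp[ok] * w[ok])


def _blur(image: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return image
    # truncate=8 keeps the discrete kernel unit-sum to ~1e-15 away from borders
    return ndimage.gaussian_filter(image, sigma, mode="constant", truncate=8.0)


def _apply_noise(
    image: np.ndarray, noise: NoiseParams, rng_poisson: np.random.Generator,
    rng_read: np.random.Generator,
) -> np.ndarray:
    out = image + noise.background
    if noise.poisson:
        out = rng_poisson.poisson(np.clip(out, 0, None)).astype(float)
    if noise.read_sigma > 0:
        out = out + rng_read.normal(0.0, noise.read_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# closing TEM
# ---------------------------------------------------------------------------

def _tem_polar_truth(
    theta: np.ndarray,
    r_t: float,
    g_t: float,
    dg_dt: float,
    dr_dt: float,
    lag_mode: int,
    lag_amplitude: float,
    lag_phase: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic (rho, kappa, v_normal) of the perturbed hole boundary.

    The boundary is the polar curve rho(theta) = r (1 + a cos(m theta - phi) g).
    kappa is the plane-curve curvature of that polar curve, taken positive for
    the hole (circle center on the hole side); v is the normal speed of the
    interface, positive when the hole shrinks (cell advances).
    """
    a, m, phi = lag_amplitude, lag_mode, lag_phase
    c = np.cos(m * theta - phi)
    s = np.sin(m * theta - phi)
    rho = r_t * (1 + a * c * g_t)
    rho_th = -r_t * a * m * s * g_t
    rho_thth = -r_t * a * m * m * c * g_t
    denom = (rho**2 + rho_th**2) ** 1.5
    kappa = (rho**2 + 2 * rho_th**2 - rho * rho_thth) / denom
    rho_t = dr_dt * (1 + a * c * g_t) + r_t * a * c * dg_dt
    v = -rho_t * rho / np.sqrt(rho**2 + rho_th**2)
    return rho, kappa, v


def make_closing_tem(
    r0: float = 40.0,
    closure_rate: float = 0.5,
    n_frames: int = 10,
    lag_mode: int = 3,
    lag_amplitude: float = 0.20,
    lag_tau: float = 5.0,
    lag_phase: float = 0.0,
    coupling: tuple[float, float, float] = (300.0, 0.0, 0.0),
    psf_sigma: float = 1.0,
    noise: NoiseParams | None = None,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (256, 256),
    cell_radius: float = 100.0,
    membrane_body: float = 400.0,
    membrane_edge: float = 600.0,
    probe_body: float = 50.0,
    probe_mode: str = "coupled",
    probe_factor: float = 0.5,
    n_boundary_points: int = 1000,
    min_radius: float = 5.0,
    pixel_size: float = 160.0,
    frame_interval: float = 5.0,
) -> tuple[ImageStack, GroundTruth]:
    """Synthesize a cell with a closing circular hole (TEM).

    The hole boundary is rho(theta, t) = r(t) (1 + a cos(m theta - phi) g(t))
    with r(t) = r0 - closure_rate * t and g(t) = exp(-t / lag_tau).  The
    membrane channel is a uniform cell-body fill plus a uniform-intensity rim
    deposited along the hole boundary (and the outer cell edge); the probe
    channel deposits, per boundary point,

        I(theta, t) = b0 + b1 * max(kappa, 0) + b2 * max(-dkappa/dt, 0)

    (``probe_mode="coupled"``), or is exactly ``probe_factor`` times the
    membrane deposits (``probe_mode="proportional"``, a geometry-free probe
    whose normalized boundary profile is constant).

    Returns the image stack (channels "membrane", "probe") and the ground
    truth carrying analytic curvature, normal speed, deposits and the exact
    rasterized cell masks.
    """
    if noise is None:
        noise = NoiseParams()
    if not 0 <= lag_amplitude < 1:
        raise ValueError("lag_amplitude must be in [0, 1)")
    if n_frames < 3:
        raise ValueError("need at least 3 frames")
    if probe_mode not in ("coupled", "proportional"):
        raise ValueError(f"unknown probe_mode {probe_mode!r}")
    r_sched = r0 - closure_rate * np.arange(n_frames)
    if np.any(r_sched * (1 - lag_amplitude) <= min_radius):
        raise ValueError(
            f"radius schedule reaches {r_sched.min():.1f} px "
            f"(min allowed {min_radius}) before frame {n_frames}; "
            "reduce closure_rate or n_frames"
        )
    if r0 * (1 + lag_amplitude) >= cell_radius - 10:
        raise ValueError("initial hole too large for the cell region")

    rngs = _spawn_rngs(seed)
    H, W = shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    yy, xx = np.mgrid[0:H, 0:W]
    pix_theta = np.arctan2(yy - cy, xx - cx)
    pix_dist = np.hypot(yy - cy, xx - cx)
    cell_disk = pix_dist <= cell_radius

    n_pts = n_boundary_points
    theta = 2 * np.pi * np.arange(n_pts) / n_pts
    g = np.exp(-np.arange(n_frames) / lag_tau)
    dg = -g / lag_tau

    kappa_true = np.empty((n_frames, n_pts))
    v_true = np.empty((n_frames, n_pts))
    rho_all = np.empty((n_frames, n_pts))
    cell_masks = np.empty((n_frames, H, W), dtype=bool)
    for t in range(n_frames):
        rho, kap, v = _tem_polar_truth(
            theta, r_sched[t], g[t], dg[t], -closure_rate,
            lag_mode, lag_amplitude, lag_phase,
        )
        rho_all[t] = rho
        kappa_true[t] = kap
        v_true[t] = v
        rho_pix, _, _ = _tem_polar_truth(
            pix_theta.ravel(), r_sched[t], g[t], dg[t], -closure_rate,
            lag_mode, lag_amplitude, lag_phase,
        )
        hole = pix_dist.ravel() < rho_pix
        cell_masks[t] = cell_disk & ~hole.reshape(H, W)

    # curvature rate for the probe coupling: forward difference, last frame
    # falls back to the preceding one (it carries no classification anyway)
    dkdt = np.empty_like(kappa_true)
    dkdt[:-1] = np.diff(kappa_true, axis=0)
    dkdt[-1] = dkdt[-2]

    b0, b1, b2 = coupling
    probe_deposit = b0 + b1 * np.clip(kappa_true, 0, None) + b2 * np.clip(-dkdt, 0, None)

    # outer cell rim (membrane accumulates on every edge)
    out_x = cx + cell_radius * np.cos(theta)
    out_y = cy + cell_radius * np.sin(theta)

    frames = np.zeros((n_frames, 2, H, W))
    for t in range(n_frames):
        bx = cx + rho_all[t] * np.cos(theta)
        by = cy + rho_all[t] * np.sin(theta)
        mem = membrane_body * cell_masks[t].astype(float)
        _splat(mem, bx, by, np.full(n_pts, membrane_edge))
        _splat(mem, out_x, out_y, np.full(n_pts, membrane_edge))
        if probe_mode == "proportional":
            prb = probe_factor * mem
        else:
            prb = probe_body * cell_masks[t].astype(float)
            _splat(prb, bx, by, probe_deposit[t])
        for c_idx, img in ((0, mem), (1, prb)):
            blurred = _blur(img, psf_sigma)
            frames[t, c_idx] = _apply_noise(
                blurred, noise, rngs["poisson"], rngs["read"]
            )

    stack = ImageStack(
        data=frames,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        channel_names=("membrane", "probe"),
    )
    if probe_mode == "proportional":
        probe_deposit = np.full_like(probe_deposit, probe_factor * membrane_edge)
    gt = GroundTruth(
        scenario="closing_tem",
        seed=seed,
        params=dict(
            r0=r0, closure_rate=closure_rate, n_frames=n_frames,
            lag_mode=lag_mode, lag_amplitude=lag_amplitude, lag_tau=lag_tau,
            lag_phase=lag_phase, shape=list(shape), cell_radius=cell_radius,
            membrane_body=membrane_body, membrane_edge=membrane_edge,
            probe_body=probe_body, probe_mode=probe_mode,
            probe_factor=probe_factor, pixel_size=pixel_size,
            frame_interval=frame_interval,
        ),
        psf_sigma=psf_sigma,
        noise=noise,
        hole_center=(cx, cy),
        radius=r_sched,
        theta=theta,
        kappa_true=kappa_true,
        v_true=v_true,
        probe_deposit=probe_deposit,
        membrane_edge_deposit=membrane_edge,
        coupling=(b0, b1, b2),
        cell_masks=cell_masks,
    )
    return stack, gt


# ---------------------------------------------------------------------------
# truth-side enrichment bookkeeping
# ---------------------------------------------------------------------------

def _bin_truth(gt: GroundTruth, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Bin per-point truth (kappa, probe deposit) into n_bins angular bins.

    Returns (kappa_binned, deposit_binned), each (T, n_bins).  The point grid
    is uniform in theta, so binning is a plain reshape-style average.
    """
    idx = np.floor(gt.theta / (2 * np.pi / n_bins)).astype(int) % n_bins
    T = gt.kappa_true.shape[0]
    kap = np.empty((T, n_bins))
    dep = np.empty((T, n_bins))
    counts = np.bincount(idx, minlength=n_bins)
    for t in range(T):
        kap[t] = np.bincount(idx, weights=gt.kappa_true[t], minlength=n_bins) / counts
        dep[t] = np.bincount(idx, weights=gt.probe_deposit[t], minlength=n_bins) / counts
    return kap, dep


def true_fold_enrichment(gt: GroundTruth, n_bins: int = 50) -> float:
    """Analytic flattening-over-lagging fold enrichment of the deposits.

    Classifies bins from the true binned curvature (forward time difference)
    and pools the deposited probe intensities over all classified frames,
    mirroring the estimator's pooling — but on the noiseless, unblurred truth.
    """
    kap, dep = _bin_truth(gt, n_bins)
    dk = np.diff(kap, axis=0)
    k = kap[:-1]
    d = dep[:-1]
    flat = (k > 0) & (dk < 0)
    lag = (k > 0) & (dk > 0)
    if not flat.any() or not lag.any():
        return float("nan")
    return float(d[flat].mean() / d[lag].mean())


def calibrate_flattening_coupling(
    target_fold: float,
    b0: float = 300.0,
    n_bins: int = 50,
    **tem_kwargs,
) -> float:
    """Solve for the flattening coupling b2 giving a stated true fold enrichment.

    Uses the analytic curvature field of the stated TEM geometry (no images):
    with deposits b0 + b2 * max(-dkappa/dt, 0), the pooled fold enrichment is
    (b0 + b2*mF) / (b0 + b2*mL) where mF, mL are the pooled bin means of the
    flattening drive over flattening and lagging bins.  Closed-form inversion.
    """
    _, gt = make_closing_tem(
        coupling=(0.0, 0.0, 1.0), noise=NoiseParams.none(), **tem_kwargs
    )
    kap, dep = _bin_truth(gt, n_bins)  # dep == binned max(-dkdt, 0)
    dk = np.diff(kap, axis=0)
    k = kap[:-1]
    d = dep[:-1]
    flat = (k > 0) & (dk < 0)
    lag = (k > 0) & (dk > 0)
    if not flat.any() or not lag.any():
        raise ValueError("geometry produces no flattening or no lagging bins")
    mF = d[flat].mean()
    mL = d[lag].mean()
    denom = mF - target_fold * mL
    if denom <= 0:
        raise ValueError("target fold not reachable with this geometry")
    return float(b0 * (target_fold - 1.0) / denom)


def make_tem_cohort(
    n_tems: int = 3,
    seed: int = 0,
    modes: Sequence[int] = (3, 4, 5),
    random_phase: bool = True,
    probe_mode: str = "proportional",
    target_fold: float | None = None,
    b0: float = 300.0,
    n_bins: int = 50,
    **tem_kwargs,
) -> list[tuple[ImageStack, GroundTruth]]:
    """Generate a cohort of closing TEMs with distinct lag modes and phases.

    Distinct modes and random phases break the rotational near-symmetry a
    single sinusoidal mode would impose, so a cohort-level rotation scan has a
    unique zero-offset peak.  With ``target_fold`` set, each TEM's flattening
    coupling b2 is solved analytically (per its own geometry) so that the true
    pooled fold enrichment equals the target; otherwise ``probe_mode`` is
    passed through ("proportional" gives geometry-free uniform probes).
    """
    ss = np.random.SeedSequence(seed)
    tem_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_tems)]
    phase_rng = np.random.default_rng(ss.spawn(1)[0]) if random_phase else None
    out = []
    for j in range(n_tems):
        mode = int(modes[j % len(modes)])
        phase = float(phase_rng.uniform(0, 2 * np.pi)) if phase_rng else 0.0
        kw = dict(tem_kwargs)
        kw.update(lag_mode=mode, lag_phase=phase, seed=tem_seeds[j])
        if target_fold is not None:
            b2 = calibrate_flattening_coupling(
                target_fold, b0=b0, n_bins=n_bins,
                **{k: v for k, v in kw.items() if k != "seed"},
            )
            kw.update(coupling=(b0, 0.0, b2), probe_mode="coupled", probe_body=0.0)
        else:
            kw.setdefault("probe_mode", probe_mode)
        out.append(make_closing_tem(**kw))
    return out


# ---------------------------------------------------------------------------
# leading edge
# ---------------------------------------------------------------------------

def make_leading_edge(
    front_speed: float = 1.0,
    lag_wavelength: float = 64.0,
    lag_amplitude: float = 6.0,
    coupling: tuple[float, float] = (300.0, 50.0),
    psf_sigma: float = 2.0,
    noise: NoiseParams | None = None,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (128, 256),
    n_frames: int = 12,
    y0: float = 40.0,
    omega: float = 0.6,
    lag_phase: float = 0.0,
    time_phase: float = 0.0,
    membrane_body: float = 400.0,
    membrane_edge: float = 600.0,
    pixel_size: float = 160.0,
    frame_interval: float = 5.0,
) -> tuple[ImageStack, GroundTruth]:
    """Synthesize an advancing cell front with laterally varying edge speed.

    The cell occupies y <= y_front(x, t) with

        y_front = y0 + front_speed*t + lag_amplitude*sin(2 pi x/lambda + phi)
                  * sin(omega*t + psi),

    so the true local normal-ish speed per column is

        v_true(x, t) = front_speed
                       + lag_amplitude*omega*sin(2 pi x/lambda + phi)*cos(omega*t + psi).

    The probe deposits, per column along the front, c0 + c1 * v_true (clipped
    at zero); the membrane channel is a uniform body fill plus a uniform rim.
    """
    if noise is None:
        noise = NoiseParams()
    if lag_amplitude < 0:
        raise ValueError("lag_amplitude must be nonnegative")
    if lag_amplitude > lag_wavelength / 2:
        raise ValueError("lag_amplitude too large for the wavelength (self-intersecting front)")
    H, W = shape
    t_arr = np.arange(n_frames)
    x = np.arange(W, dtype=float)
    sin_x = np.sin(2 * np.pi * x / lag_wavelength + lag_phase)
    front = (
        y0
        + front_speed * t_arr[:, None]
        + lag_amplitude * sin_x[None, :] * np.sin(omega * t_arr + time_phase)[:, None]
    )
    if front.min() < 5 or front.max() > H - 5:
        raise ValueError("front leaves the field of view; adjust y0/front_speed/n_frames")
    v_true = (
        front_speed
        + lag_amplitude * omega * sin_x[None, :] * np.cos(omega * t_arr + time_phase)[:, None]
    )
    c0, c1 = coupling
    probe_dep = np.clip(c0 + c1 * v_true, 0.0, None)

    rngs = _spawn_rngs(seed)
    yy = np.arange(H, dtype=float)[:, None]
    frames = np.zeros((n_frames, 2, H, W))
    for t in range(n_frames):
        mask = yy <= front[t][None, :]
        mem = membrane_body * mask.astype(float)
        _splat(mem, x, front[t], np.full(W, membrane_edge))
        prb = np.zeros((H, W))
        _splat(prb, x, front[t], probe_dep[t])
        for c_idx, img in ((0, mem), (1, prb)):
            blurred = _blur(img, psf_sigma)
            frames[t, c_idx] = _apply_noise(
                blurred, noise, rngs["poisson"], rngs["read"]
            )

    stack = ImageStack(
        data=frames, pixel_size=pixel_size, frame_interval=frame_interval,
        channel_names=("membrane", "probe"),
    )
    gt = GroundTruth(
        scenario="leading_edge",
        seed=seed,
        params=dict(
            front_speed=front_speed, lag_wavelength=lag_wavelength,
            lag_amplitude=lag_amplitude, coupling=list(coupling),
            shape=list(shape), n_frames=n_frames, y0=y0, omega=omega,
            membrane_body=membrane_body, membrane_edge=membrane_edge,
            pixel_size=pixel_size, frame_interval=frame_interval,
        ),
        psf_sigma=psf_sigma,
        noise=noise,
        front_y=front,
        v_true_edge=v_true,
        probe_deposit_edge=probe_dep,
    )
    return stack, gt


# ---------------------------------------------------------------------------
# ring field
# ---------------------------------------------------------------------------

def make_ring_field(
    n_rings: int = 30,
    diameter_dist: tuple[float, float] = (230.0, 40.0),
    thickness: float = 2.0,
    psf_sigma: float = 1.0,
    noise: NoiseParams | None = None,
    pixel_size: float = 23.0,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (512, 512),
    amplitude: float = 100.0,
    margin: float = 4.0,
    max_attempts: int = 20000,
) -> tuple[ImageStack, GroundTruth]:
    """Synthesize a field of non-overlapping fluorescent annuli ("rings").

    Center-line diameters are drawn from a normal distribution (mean, SD in
    nanometres), clipped at 4 pixels.  Each ring is rasterized as a hard
    annulus of the stated center-line diameter and radial thickness, then the
    whole field is PSF-blurred and noised.  Placement uses seeded rejection
    sampling; a field too small to host ``n_rings`` without overlap raises.
    """
    if noise is None:
        noise = NoiseParams(background=5.0, poisson=True, read_sigma=1.5)
    rngs = _spawn_rngs(seed)
    rng = rngs["placement"]
    H, W = shape
    mean_nm, sd_nm = diameter_dist
    d_nm = np.clip(rng.normal(mean_nm, sd_nm, size=n_rings), 4 * pixel_size, None)
    d_px = d_nm / pixel_size
    # largest first eases packing but keep the seeded draw order deterministic
    order = np.argsort(-d_px, kind="stable")

    centers = np.full((n_rings, 2), np.nan)  # (x, y)
    bound = d_px / 2 + thickness / 2 + margin
    attempts = 0
    for i in order:
        b = bound[i]
        placed = False
        while attempts < max_attempts:
            attempts += 1
            cx = rng.uniform(b, W - 1 - b)
            cy = rng.uniform(b, H - 1 - b)
            ok = True
            for j in range(n_rings):
                if np.isnan(centers[j, 0]):
                    continue
                if np.hypot(cx - centers[j, 0], cy - centers[j, 1]) < b + bound[j]:
                    ok = False
                    break
            if ok:
                centers[i] = (cx, cy)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place {n_rings} rings in a {H}x{W} field without overlap"
            )

    img = np.zeros((H, W))
    yy, xx = np.mgrid[0:H, 0:W]
    for i in range(n_rings):
        cx, cy = centers[i]
        r = d_px[i] / 2
        dist = np.hypot(yy - cy, xx - cx)
        img[np.abs(dist - r) <= thickness / 2] += amplitude
    blurred = _blur(img, psf_sigma)
    noisy = _apply_noise(blurred, noise, rngs["poisson"], rngs["read"])

    stack = ImageStack(
        data=noisy[None, None],
        pixel_size=pixel_size,
        frame_interval=1.0,
        channel_names=("rings",),
    )
    rings = pd.DataFrame(
        {
            "ring": np.arange(n_rings),
            "cx": centers[:, 0],
            "cy": centers[:, 1],
            "diameter_px": d_px,
            "diameter_nm": d_nm,
        }
    )
    gt = GroundTruth(
        scenario="ring_field",
        seed=seed,
        params=dict(
            n_rings=n_rings, diameter_mean_nm=mean_nm, diameter_sd_nm=sd_nm,
            thickness=thickness, pixel_size=pixel_size, shape=list(shape),
            amplitude=amplitude,
        ),
        psf_sigma=psf_sigma,
        noise=noise,
        rings=rings,
    )
    return stack, gt


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_synthetic(
    stack: ImageStack, gt: GroundTruth, out_dir: str | Path, stem: str = "synthetic"
) -> dict[str, Path]:
    """Write the stack (16-bit TIFF), a parameter sidecar YAML and — for the
    closing-TEM scenario — the tidy ground-truth CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    tiff = out_dir / f"{stem}.tif"
    stack.to_tiff(tiff)
    paths["tiff"] = tiff
    side = out_dir / f"{stem}.yaml"
    meta = {
        "scenario": gt.scenario,
        "seed": gt.seed,
        "psf_sigma": gt.psf_sigma,
        "noise": {
            "background": gt.noise.background,
            "poisson": gt.noise.poisson,
            "read_sigma": gt.noise.read_sigma,
        },
        "params": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in gt.params.items()
        },
    }
    side.write_text(yaml.safe_dump(meta, sort_keys=False))
    paths["yaml"] = side
    if gt.kappa_true is not None:
        csv = out_dir / f"{stem}_truth.csv"
        gt.truth_table().to_csv(csv, index=False)
        paths["truth"] = csv
    if gt.rings is not None:
        csv = out_dir / f"{stem}_rings.csv"
        gt.rings.to_csv(csv, index=False)
        paths["truth"] = csv
    return paths
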