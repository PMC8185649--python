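# Methods notes

This note records the estimator conventions, default parameter choices and
known limitations of `memcurv`, in enough detail to reproduce or audit any
number the package reports. All defaults below were fixed from first
principles or from feasibility studies on the synthetic generator **before**
the validation suite was frozen; none were adjusted afterwards.

## Synthetic imaging model

All estimators are validated against `memcurv.synthetic`, which renders
scenes with analytic ground truth and a simple but realistic camera model:

- **Scene**: intensities are deposited in a floating-point buffer —
  a cell body level, a brighter membrane-edge line density along the
  boundary (deposited per unit arc length with sub-pixel bilinear splatting),
  and a probe channel (see below).
- **PSF**: Gaussian blur, normalized to unit sum (photon-conserving).
- **Noise**: constant background offset, Poisson shot noise on the expected
  counts, and additive Gaussian read noise; 16-bit quantization on export.

Default study conditions (chosen to mimic a bright super-resolution
live-imaging regime, e.g. TIRF-SIM at ~160 nm pixels):

| parameter | default | rationale |
| --- | --- | --- |
| `membrane_body` / `membrane_edge` | 400 / 600 counts | bright, realistic SNR |
| `probe` coupling `b0` | 300 counts | comparable to membrane |
| background / read noise | 100 counts / σ = 4 | camera offset + read floor |
| `psf_sigma` (TEM/cell scenes) | 1.0 px (σ = 160 nm) | rim resolved at 160 nm/px sampling |
| `psf_sigma` (ring fields) | 1.0 px at 23 nm/px | STORM-like ~54 nm FWHM |
| lag amplitude / τ | 0.2 / 5 frames | visible shape dynamics |

The closing-hole scenario is parametric: ρ(θ, t) = r(t)·(1 + a·cos(mθ − φ)·g(t))
with r(t) = r₀ − c·t and g(t) = exp(−t/τ). Curvature and edge-velocity truth
come from the closed-form parametric expressions, so oracle tests compare
against exact values, not against another numeric pipeline.

The probe channel has two modes:

- `proportional`: the probe buffer is exactly `probe_factor ×` the membrane
  buffer, so the normalized profile (probe/membrane) is constant — the null
  case for fold-enrichment tests.
- `coupled`: line density `b0 + b1·max(κ, 0) + b2·max(−dκ/dt, 0)` — a probe
  that reads curvature and/or flattening. For a requested true fold
  enrichment F, `b2` has the closed form `b2 = b0(F − 1)/(m_F − F·m_L)`
  where `m_F`, `m_L` are the mean flattening/lagging deposit weights of the
  noiseless geometry; `calibrate_flattening_coupling` evaluates it, and
  `true_fold_enrichment` verifies it to machine precision.

## Boundary extraction: two contours per frame

The TEM pipeline deliberately uses **two different boundaries** per frame:

- a **curvature boundary** from a heavily smoothed intensity iso-contour
  (Gaussian σ = 3 on the image, σ = 3 arc-length smoothing on the contour).
  Osculating-circle curvature at S ≈ 10 is exquisitely sensitive to
  pixel-lattice staircase noise; heavy smoothing suppresses it while leaving
  shape at the 50-bin angular scale intact.
- a **photometry boundary** from a crisp iso-contour (σ = 1): the band of
  half-width 3 px used to read membrane and probe fluorescence is centered on
  it. Heavy smoothing displaces a contour down the rim flank — harmless for
  κ, but a band centered there misses the intensity peak, which at low rim
  width destroys the fluorescence estimate.

Boundaries are closed polylines resampled to N = 1000 equal-arc points,
oriented with the region interior on the left; the outward normal is
(t_y, −t_x). Masks come from Otsu (or fixed) thresholding of a σ = 1
smoothed frame; the TEM mask is the labeled hole containing the anchor.

## Curvature, time derivative, velocity

- κ from three-point circumcircles at index offset S (S = 10 for TEM rims
  with 50 angular bins; S = 44 for whole cells with 1000 bins); collinear
  triples give κ = 0.
- dκ/dt per angular bin defaults to the **central** difference
  (κ[t+1] − κ[t−1])/2. A forward difference is available
  (`derivative: forward`) but is *not* the default for a statistical reason:
  forward differences make the frame-t flattening/lagging labels share the
  frame-t image noise with the frame-t fluorescence sample, which biases the
  null fold enrichment upward (measured +0.5% with ~3× inflated
  false-positive rate). The central difference decouples labels from the
  sampled frame and calibrates the null exactly (fold 1.000 ± 0.003; FPR
  8/200 at α = 0.05, within binomial bounds).
- Edge velocity: signed EDT (positive inside the region, half-pixel
  interface-corrected), central difference between frames t−1 and t+1,
  bilinearly sampled at the boundary points; positive = advancing.
  A `literal_average` mode — (sdt(t+1) + sdt(t−1))/2, the literal average of
  the two distance maps — is retained for comparison; for steady motion it
  measures the residual distance offset, not a speed.

## Background correction

Fluorescence quantification subtracts background before any per-area or
per-perimeter quantity:

- `rolling_ball` (default): the ball background is estimated on a Gaussian
  pre-smoothed copy (σ = 2) of the frame and subtracted from the original;
  without pre-smoothing the ball sinks into the pixel-noise floor and leaves
  a systematic positive residual. For speed the estimate runs on a 4×
  downscaled image (ball radius scaled accordingly) and is upsampled — the
  background is smooth at the ball scale, so the approximation error is
  negligible.
- `constant`: subtracts the **mean** (not the median) intensity of a
  reference region (for TEMs, the eroded hole interior). The mean of Poisson
  counts is unbiased; the median of a Poisson variate is biased low by about
  one-third of a count, which measurably shifts per-area ratios at low
  backgrounds.

The doughnut **enrichment factor** itself is the raw per-area ratio of the
signal and background bands (so a uniform frame scores exactly 1, with no
estimated quantities involved); background correction enters the
per-perimeter intensity and the compartment ratios.

## Fold enrichment and the rotation null

Per TEM, angular bins with κ > 0 are labeled flattening (dκ/dt < 0) or
lagging (dκ/dt > 0); bins with κ ≤ 0, zero derivative, or missing data are
`neither`. The normalized probe (probe/membrane band means; non-positive
membrane bins are missing) is pooled over all frames, and the fold
enrichment is mean(flattening)/mean(lagging).

The rotation scan shifts each TEM's normalized bins circularly by k bins
(labels fixed) for k = 0 … n_bins−1 and tests the per-TEM folds against 1
with a two-tailed one-sample t test at each offset (no multiple-testing
correction; the scan is a diagnostic curve, and a real signal must peak at
k = 0). Offset 0 reproduces the unrotated fold exactly.

Null calibration: over 200 independent 3-TEM cohorts with proportional
probes, the offset-0 test at α = 0.05 rejected 8/200 times (binomial 95%
bounds [4, 16]), with an unbiased fold (mean 1.0001, SD 0.003).

## Per-channel trends (direction recovery)

The per-TEM trend statistic is the Spearman ρ of the background-corrected
band intensity **per unit rim perimeter** against frame index, computed with
the *identical* doughnut estimator for the probe and the membrane channel.
Symmetry matters: the thresholded hole mask sits ~2–3 px inside the true rim
(the iso-level crosses on the inner flank of the bright rim), so as a hole
shrinks the background band rides up the rim peak and the corrected
per-perimeter intensity acquires a shared negative drift in *both* channels.
The two-channel contrast — mean ρ(probe) − mean ρ(membrane) — cancels this
shared artifact and recovers the direction of a genuinely increasing probe
signal; the absolute per-channel ρ values should not be interpreted alone.

## Ring morphometry

Rings are segmented from a rolling-ball background-subtracted, lightly
smoothed (σ = 0.5) frame by thresholding, connected components, and an area
filter. The reported diameter is that of the perfect circle with the same
perimeter, d = C/π, where C is the **center-line** perimeter: the mean of
the outer and inner (hole) sub-pixel contour lengths of the particle
(particles without a resolved hole use the outer contour). Contours are
measured on a lightly pre-smoothed binary (σ = 0.8) so polygon length is not
inflated by the rasterization staircase. The summary reports the median and
the histogram mode at a stated bin width (default 20 nm), since a mode is
meaningless without its binning.

**Known bias**: a Gaussian-blurred thin ring's radial intensity peak sits
*inward* of the true radius by ≈ σ²/(2r), so the thresholded band mid-line —
and hence d = C/π — underestimates small-ring diameters by roughly σ²/r in
absolute terms (≈ 2.5% for 230-nm rings at σ = 23 nm + σ = 11.5 nm
segmentation smoothing; verified against ground truth). Real sub-diffraction
rings measured this way carry the same bias for the instrument's effective σ.

## Protrusions

Connected components of mask(t+1) \ mask(t) (after optional integer-pixel
drift alignment maximizing overlap) of at least 4 px are protrusion events.
Length is the maximum distance-transform value inside the component measured
from the t0 region; width is the extent of the component perpendicular to
the root→tip axis at half the length; speed = length/elapsed, reported in
px/min and µm/min.

## Limitations and open questions

- Per-point curvature on **rasterized** masks is dominated by lattice noise
  at small S; the oracle tolerance (1%) is met on analytically sampled
  boundaries and on heavily smoothed iso-contours, not on raw mask contours.
- The doughnut bands inherit the threshold offset of the hole mask (above);
  absolute per-perimeter intensities drift as holes shrink, and only
  band-symmetric contrasts are bias-free.
- The ring diameter estimator carries the inward blur bias above; it is not
  deconvolved because the instrument σ is generally unknown.
- `literal_average` velocity reproduces a plausible reading of
  distance-transform averaging but is not a speed for steady motion; the
  central-difference mode is the default and the only mode used by the
  pipelines.
- The rotation scan's per-offset p-values are not corrected for multiple
  comparisons; only the offset-0 test is used confirmatorily.
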