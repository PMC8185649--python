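# memcurv

Membrane-geometry and fluorescence-enrichment morphometry for time-lapse
fluorescence microscopy.

`memcurv` quantifies how proteins distribute along curved cell membranes. It
was built around three recurring measurement problems in membrane biology:

1. **Closing transcellular holes (TEMs).** A transendothelial macroaperture is
   a micron-scale hole through a thin cell that reseals over minutes. Its rim
   presents strong positive in-plane curvature that grows as the hole closes,
   making it a natural assay for curvature-sensing machinery: is a probe
   enriched at the rim relative to the surrounding membrane, does the
   enrichment track rim curvature over time, and is it concentrated where the
   rim is *flattening* (curvature decreasing) rather than *lagging*
   (curvature increasing)?
2. **Migrating cell edges.** At a lamellipodium, protrusion machinery is
   predicted to correlate with local edge velocity. Given a movie of a
   segmentable cell, `memcurv` measures per-boundary-point curvature,
   edge velocity, and band fluorescence, and correlates them.
3. **Nanoscale rings.** Curvature-generating complexes often assemble into
   ring-shaped structures at sub-diffraction scales. Given a super-resolution
   image, `memcurv` segments candidate rings and reports the diameter of the
   perfect circle with the same perimeter (d = C/π).

All estimators are validated against a seeded synthetic-microscopy generator
(`memcurv.synthetic`) with analytic ground truth: parametric closing holes
with sinusoidal lag modes, advancing fronts, and annular ring fields, rendered
with a Gaussian PSF, Poisson shot noise, and Gaussian read noise.

## The core measurements

- **Signed curvature** — each segmented boundary is resampled to N = 1000
  equal-arc-length points; the curvature at a point is the inverse radius of
  the circumcircle through the points S indices away on either side
  (osculating circle). S sets the spatial scale: S = 10 for TEM rims
  (50 angular bins), S = 44 for whole-cell outlines (1000 bins). Sign
  convention: positive when the circle center lies on the non-region side, so
  a circular hole in a cell has κ = +1/r and a convex cell bulge κ = −1/r.
- **Edge velocity** — central difference of the signed Euclidean distance
  transform (positive inside the region, interface-corrected by half a pixel)
  between the previous and next frames, sampled at sub-pixel boundary points.
  Positive = advancing edge (protruding cell, closing hole), in px/frame with
  µm/min conversions.
- **Doughnut enrichment factor** — the TEM mask is dilated by 3 px to form a
  signal band and by another 3 px to form a background band; the enrichment
  factor is the ratio of per-area band intensities (1 = no enrichment). The
  corrected band intensity per unit rim perimeter is tracked over closure.
- **Flattening/lagging fold enrichment** — boundary bins with κ > 0 are
  classified by the sign of dκ/dt; the fold enrichment is the mean normalized
  probe signal (probe/membrane) over flattening bins divided by lagging bins.
  Significance comes from a rotation scan: fluorescence bins are circularly
  rotated against the fixed geometric labels, and each offset is tested
  against the null value 1 across TEMs. A real curvature-coupled signal peaks
  at zero rotation.
- **Colocalization and controls** — Manders M1, compartment intensity ratios,
  a seeded scrambled-pixel control, and protrusion length/width/speed from
  frame-difference maps.

## Worked example: a curvature-coupled probe at a closing TEM

Generate a cohort of three synthetic closing TEMs whose probe channel is
calibrated so that the true flattening/lagging fold enrichment is exactly 1.5,
then recover it:

```python
from memcurv.pipeline import RunConfig, run_tem_analysis
from memcurv.synthetic import make_tem_cohort

cohort = make_tem_cohort(n_tems=3, seed=42, target_fold=1.5)
res = run_tem_analysis(
    RunConfig(out_dir="results/demo"), stacks=[s for s, _ in cohort]
)

print(res.summary)
#    tem  n_frames  fold_enrichment  ...
# recovered fold ~1.5 per TEM

rot = res.rotation.table          # rotation scan: 50 offsets x (mean, t, p)
print(rot.loc[rot["mean"].idxmax(), "offset"])   # -> 0 (peak at zero rotation)
```

`results/demo/` now contains, per TEM, a tidy per-frame series
(`tem_series_*.csv`: perimeter, area, enrichment factor, intensity per
perimeter) and a per-bin profile (`edge_profile_*.csv`: κ, dκ/dt, velocity,
band fluorescence, normalized probe), plus the cohort-level rotation null
(`rotation_null.csv`) and the exact configuration (`config.yaml`, with its
hash stamped into every CSV header).

The same workflow is available from the command line:

```sh
memcurv synth-tem --out data --seed 42 --n-tems 3 --target-fold 1.5 --probe-mode coupled
memcurv analyze-tem data/tem0.tif data/tem1.tif data/tem2.tif --out-dir results/demo

memcurv synth-rings --out data --seed 1
memcurv analyze-rings data/rings.tif --out-dir results/rings

memcurv synth-edge --out data --seed 5
memcurv analyze-edge data/edge.tif --out-dir results/edge
```

Exit codes: 0 success, 2 configuration error, 3 empty result.

## Validation

`tests/test_acceptance.py` holds the headline checks, one test per criterion:

1. Uniform fluorescence → doughnut enrichment factor exactly 1.
2. Probe proportional to membrane → mean fold enrichment 1 ± 0.05.
3. Curvature oracle: κ = ±1/r within 1% for r ∈ {15, 25, 50, 100} px at
   S ∈ {5, 10, 44}.
4. Velocity oracle: analytic disk speeds within 0.5 px/frame.
5. Rotation-null calibration: false-positive rate at α = 0.05 within binomial
   95% bounds over 200 null cohorts.
6. A cohort generated with true fold 1.5 is recovered within 10%, with the
   rotation-scan maximum at offset 0.
7. 230-nm rings: median diameter within 5% through the full pipeline.
8. Direction recovery: a curvature-coupled probe's per-TEM intensity trend
   exceeds the membrane channel's.

Run everything with `pytest`, or compute the two analytic acceptance targets
directly:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Estimator conventions, parameter choices and known limitations are documented
in [docs/methods.md](docs/methods.md).
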