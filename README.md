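# fairycircles

Spatial-pattern, remote-sensing and soil statistics for arid-grassland
vegetation gaps ("fairy circles"): barren, roughly circular patches a few
meters across that recur in Namib-region short-grass matrices, are often
over-dispersed, and track narrow climate envelopes. The package is aimed
at ecologists and image analysts who want the full analysis chain —
simulate → detect → dispersion statistics → occupancy envelopes → niche
model → soil statistics — as tested, seeded, scriptable code that runs
entirely offline on synthetic landscapes with known ground truth, and
accepts real circle tables, rasters and site CSVs through the same
interfaces.

## What it computes

* **Point-process generators** spanning the dispersion continuum —
  Matérn cluster (clumped), CSR (random), sequential hard-core
  (over-dispersed), jittered triangular lattice (maximal) — plus
  lognormal circle diameters calibrated to field percentiles
  (median 4.8 m, 5–95% range 3.2–7.9 m).
* **Clark–Evans dispersion index** R = r̄_obs/r_exp with
  r_exp = 1/(2√ρ) and normal Z-test (SE = 0.26136/√(nρ)): R = 1 under
  randomness, < 1 clumped, 2.15 at the hexagonal ceiling. Landscape
  summaries: density, occupancy (% surface in circles), periphery gaps,
  cumulative circumference per hectare.
* **Morphological circle detection** in grayscale rasters: Otsu
  threshold, disk-structuring-element opening, connected components,
  area/circularity/border filters; scored against ground truth by
  precision, recall and area bias.
* **90th-quantile piecewise envelopes**: continuous two-segment quantile
  regression (pinball loss, grid-searched breakpoint) for upper limits of
  occupancy along environmental gradients.
* **Boosted regression trees** (from scratch): stagewise logistic
  boosting with Newton leaf steps, bagging, stratified CV AUC, relative
  influence, 1-SE backward simplification, partial dependence, pairwise
  interaction sizes, grid prediction.
* **Soil statistics**: depth weight-summed areal totals (bulk density
  1738 kg m⁻³), Welch t tests from printed (mean, SE, n) summaries, fold
  ratios, OLS fits, and the interior soil-moisture/organic-carbon
  correlation.

See `docs/methods.md` for models, assumptions and parameter rationale.

## Worked example

```python
import numpy as np
from fairycircles import (
    SpatialWindow, gen_hardcore, assign_radii, render_landscape,
    detect_circles, evaluate_detection, clark_evans, landscape_occupancy,
)

# an over-dispersed landscape: hard-core centers, lognormal diameters
window = SpatialWindow(0, 200, 0, 200)
centers = gen_hardcore(intensity=25e-4, min_distance=9.0,
                       window=window.inset(6.0), seed=0)
pattern = assign_radii(centers, seed=1, forbid_overlap=True).with_window(window)

ce = clark_evans(pattern.centers, window)
print(f"R = {ce.R:.2f}, Z = {ce.Z:.1f}, p = {ce.p_two_sided:.1e}")
print(f"occupancy = {landscape_occupancy(pattern):.2f}%")

image = render_landscape(pattern, pixel_scale=0.5,
                         speckle_sd=0.06, noise_sd=0.04, seed=2)
detected = detect_circles(image)
score = evaluate_detection(detected, pattern)
print(f"precision {score['precision']:.2f}, recall {score['recall']:.2f}, "
      f"area bias {score['area_bias_pct']:+.1f}%")
```

prints

```
R = 1.27, Z = 4.9, p = 8.8e-07
occupancy = 4.24%
precision 1.00, recall 1.00, area bias -4.3%
```

R = 1.27 with a strongly significant Z marks the pattern as over-dispersed
(more regular than random), as hard-core inhibition should produce; the
detector recovers every circle from the noisy render and underestimates
circle area by ~4% — the same direction and order as aerial-photograph
analysis scored against ground survey.

## Analysis scripts

The numbered drivers under `analysis/` run the stages end-to-end and write
tables under `results/`:

```bash
python analysis/01_simulate_landscapes.py   # seeded inputs + manifest
python analysis/02_detect_circles.py        # detections + evaluation
python analysis/03_spatial_dispersion.py    # R by process, site summary
python analysis/04_occupancy_envelope.py    # 90th-quantile envelope fit
python analysis/05_niche_model.py           # BRT: CV AUC, influence, PD
python analysis/06_soil_statistics.py       # t tests, folds, correlation
```

The same stages are available as a CLI (`fairycircles simulate|detect|
stats|envelope|niche|fieldstats|run-all`) for use on your own CSVs and
rasters.

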