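# handkin

Kinematic analysis of rodent food-handling from markerless pose tracking.

Mice (and squirrels) eating a seed alternate rapidly between an **oromanual
phase** — active bimanual manipulation with the hands at the mouth — and a
**holding phase** — a static grip below the mouth while chewing.  Given
DeepLabCut-style tracking tables (snout tip and the bilateral D3 knuckles)
and per-video ethogram annotations, this package reconstructs the kinematic
description of that behaviour:

* the two coordinates spanning the postural space, **D** (inter-D3 distance,
  the grip aperture) and **L** (snout to D3-midpoint distance, the
  hand-to-mouth distance), plus the inter-D3 angle **θ** and view-specific
  distances L_side / L_ventral;
* phase statistics (switch rate, oromanual duty cycle, bout durations) and
  unsupervised recovery of the two postural modes by k-means over (L, D)
  with L-method knee selection, with kernel-smoothed density maps and
  10 %-of-maximum contours;
* detection and measurement of the two fast maneuvers: **regrips**
  (~20 ms spikes in D; prominence ≥ 0.75 mm, flank slope > 88 mm·s⁻¹) and
  **sniffs** (dips in L_ventral to ≤ 2.5 mm, prominence ≥ 1 mm — 2.5 mm with
  a 600 ms width cap for head-fixed recordings — and 250 ms separation),
  each measured as amplitude against pre/post baseline windows
  (−300..−100 ms, +100..+300 ms) and FWHM at half of peak-minus-baseline;
* regrip microstructure: burst periodicity from mean autocorrelograms,
  the signed bimanual path-integral asymmetry index
  (right − left)/(right + left) over the 40 ms peri-peak window, rolling
  coefficient of variation, and grip-angle changes;
* head pitch from tracked eye positions via Pratt's algebraic circle fit;
* the field's aggregation conventions: median ± m.a.d. (unscaled), first
  within and then between animals, exact Wilcoxon signed-rank and
  Mann-Whitney U tests, Spearman correlations, BH/Bonferroni flags.

A synthetic-session generator (`handkin.synthetic_data`) emulates all of this
structure with full ground truth — phase sequence, true event times,
per-event asymmetries, latent L/D/θ series — and writes files in the exact
input dialects, so every pipeline stage is verifiable without video data.

## Worked example

```python
import numpy as np
import handkin as hk

params = hk.GeneratorParams(duration_s=60.0)
session = hk.generate_session(params, seed=42)
front = hk.calibrate(hk.mask_low_quality(session.front, 0.5), session.truth.calibration)
feats = hk.compute_features(front)

stats = hk.phase_statistics(session.truth.ethogram, params.fps)
modes = hk.cluster_phases(feats, rng_seed=0)
events = hk.measure_events(feats.D, hk.detect_regrips(feats.D, params.fps), params.fps)
correlogram = hk.regrip_autocorrelogram(feats.D, events, params.fps)
```

prints (via the obvious formatting):

```
switch rate : 3.45 Hz
duty cycle  : 0.45
k selected  : 2
oromanual centroid (L, D): (2.85, 5.49) mm
holding centroid   (L, D): (4.98, 4.86) mm
regrips     : 23 (0.4 Hz)
median FWHM : 19.8 ms
periodicity : 16.3 Hz (6 burst groups)
```

The switch rate and duty cycle match the generator's analytic values
(3.36 Hz, 0.455); the clustering recovers two modes whose L centroids sit at
the generating state means (5.1 and 2.7 mm); the regrip FWHM reflects the
2.3548 σ width of the generated 7.2 ms pulses plus baseline-window effects;
and the burst periodicity recovers the 65 ms intra-burst interval (15.4 Hz).

A thin CLI wraps the two shell-friendly entry points:

```sh
handkin simulate --seed 3 --out session_dir
handkin detect --kind regrip --input session_dir/front.csv \
    --mm-per-px 0.05 --likelihood-floor 0.5 --out regrips.csv
```

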