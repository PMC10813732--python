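# sipsense

Fluid-intake assessment from inertial sensors, for researchers in wearable
digital health. `sipsense` implements a hierarchical pipeline that (1)
recognizes the five gestures of a drinking activity — *grasp*, *pre-sip*,
*sip*, *post-sip*, *release* — from tri-axial accelerometer/gyroscope
streams, and (2) estimates the ingested volume of each sip from the
recognized *sip* segment. Two sensor placements are analyzed side by side on
the same events: a **wrist-worn** sensor (sees all five gestures, with high
inter-subject variability) and a **smart-container** sensor on the cup
bottom (moves only from *pre-sip* to *post-sip*).

Because the original human recordings are not publicly available, the
package ships a seeded synthetic generator that reproduces the study
protocol — 12 participants × 7 fill levels (100–400 g) × 3 sip sizes × 4
repetitions = 1008 labeled events at 128 Hz — together with the physical
couplings the analysis exploits: emptier cups require larger sip tilt,
larger sips take longer, sip amounts follow per-category truncated normals
(large 53.82 ± 8.58 g, medium 27.23 ± 6.20 g, small 10.71 ± 5.56 g), and the
wrist signal carries markedly more variability than the container signal.

## Method

**Gesture recognition.** Sliding windows (16–56 samples, 25–87.5 % overlap)
over 12 channels (tri-axial acceleration *a*, angular velocity *ω*, angular
acceleration *ω̇* by central difference, and per-axis inclination
θᵢ = arccos(aᵢ/‖a‖)) are summarized by 8 statistics (mean, SD, variance,
max, min, range, skewness, kurtosis) → 96 features, classified by an
RBF-kernel SVM, then postprocessed: an interior run of ≤ 2 windows whose
flanking fragments agree is rewritten to the preceding fragment's label.

**Volume estimation.** From the recognized sip interval: duration, average /
maximum / integral of inclination per direction, counts of samples with
inclination over k° (k = 10…90) and over p % of the interval maximum
(p = 10…90), optionally the fill level → 64/65 features; support-vector
regression (linear or Gaussian kernel), either one *general* model or three
*sip-size-dependent* models routed by category. Fill level is itself
estimated by SVR on the same 64 features over the pre-sip…post-sip span.

**Evaluation.** Leave-one-subject-out (LOSO) throughout. Classification:
sensitivity TP/(TP+FN), precision TP/(TP+FP), F1 = 2SP/(S+P), accuracy,
macro-averaged one-vs-rest. Regression: MAPE = mean(|â−a|/a)·100 %,
MAD = mean|â−a| (g), RMSE (g), R².

## Worked example

```python
from sipsense import ProtocolConfig, WindowingConfig, generate_dataset
from sipsense.evaluation import run_gesture_loso, segment_features, \
    fill_level_loso, volume_loso, regression_metrics

events = generate_dataset(ProtocolConfig(seed=1))        # 1008 events
res = run_gesture_loso(events, "container", WindowingConfig(40, 50.0), seed=1)
print(f"container accuracy: raw {res.report_raw.accuracy:.4f} "
      f"postprocessed {res.report_post.accuracy:.4f}")

sf = segment_features(events, "container", res.segmentations)
fill = regression_metrics(sf.fills, fill_level_loso(sf))
print(f"fill level: MAD {fill.mad_g:.1f} g, R2 {fill.r2:.2f}")

sf_true = segment_features(events, "container")
for dep in (False, True):
    rep = regression_metrics(sf_true.amounts,
                             volume_loso(sf_true, size_dependent=dep))
    print(f"{'size-dependent' if dep else 'general':>14}: "
          f"MAD {rep.mad_g:.2f} g  RMSE {rep.rmse_g:.2f} g")
```

prints (seed 1):

```
container accuracy: raw 0.9905 postprocessed 0.9922
fill level: MAD 32.8 g, R2 0.83
       general: MAD 3.18 g  RMSE 4.11 g
size-dependent: MAD 2.45 g  RMSE 3.33 g
```

i.e. ~99 % of container windows are labeled correctly (postprocessing
repairs isolated errors), the fill level is recovered to ±33 g of 100–400 g,
and per-sip-size regressors beat the single general model.

The same study is available from the shell:

```bash
sipsense generate --seed 1 --out scratch/data       # write the session bundle
sipsense run --seed 1 --out scratch/report          # full study -> CSV/JSON
sipsense grid --arm wrist --out scratch/grid        # window/overlap sweep
```

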