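# ethotrace

Automated behavioral coding of pose-tracked zoo-animal night footage.

Behavioral studies of captive animals — here the motivating case is two
African elephants observed over 7-hour nights (22:00–05:00) on 25 FPS
CCTV — traditionally rely on manual second-by-second scoring against an
ethogram. Machine-learning front ends can replace the scoring step: a
pose-estimation model emits per-frame keypoint coordinates with
likelihoods, and an object-detection model emits per-frame behavior
labels with confidences. `ethotrace` implements everything downstream of
those models:

* **Zone-rule classification** — condition keypoints on a likelihood
  p-cutoff (default 0.5), then code each frame by coordinate limits: the
  lowest-priority axis-aligned pixel box whose constrained body parts
  all fall inside assigns the behavior; unmatched in-view frames get the
  default behavior (`Standing`); frames with no valid anchor keypoint
  are `Out of view`. Frame labels are aggregated to seconds by majority
  vote and minimum-duration rules (sway must last ≥ 5 s) are enforced.
* **Sway detection** — stereotypic swaying is rhythmic side-to-side
  motion of head and trunk that no fixed image zone captures. The
  per-frame Euclidean step of the trunk-root keypoint between
  consecutive valid samples is summed into a cumulative displacement
  trace, and bouts are segmented where the windowed mean displacement
  rate stays at or above a threshold (px/s) for at least 5 s.
* **Agreement statistics** — time budgets (percent of observation time
  per behavior, out-of-view included), cumulative activity curves,
  observer-referenced confusion matrices (columns = manual scoring,
  rows = model prediction, column-normalized), Kendall's coefficient of
  concordance *W* with its χ² approximation
  `χ² = m(n−1)W` on `n−1` degrees of freedom, and Spearman rank
  correlations of nightly lying-down curves.
* **A synthetic-night simulator** — scripts of behavior bouts rendered
  into pose tracks (zone-dependent keypoint placements, Gaussian jitter,
  dropout, low-likelihood samples, sinusoidal sway) and detection
  streams (label confusion, missed frames), with exact ground truth, so
  the whole pipeline is testable without footage.

## Worked example

```sh
# simulate a noise-free 10-minute night, then classify it back
ethotrace simulate --seed 7 --duration 600 --coord-sd 0 --dropout-p 0 --out-dir night/
ethotrace classify --pose night/pose.csv --out night/labels.csv
ethotrace evaluate --predicted night/labels.csv --observed night/truth_labels.csv --out-dir night/eval
```

prints (stderr):

```
wrote night/pose.csv, night/detections.csv, night/truth_labels.csv
Foraging: 284 s
Standing: 230 s
Drinking: 86 s
per-second agreement: 100.0%
```

With zero noise, zone classification recovers the scripted behaviors
for every second — the 600 s split here into 284 s foraging, 230 s
standing and 86 s drinking — and `evaluate` confirms 100% per-second
agreement against the ground-truth labels (the confusion matrix written
to `night/eval/` is purely diagonal).

The same works from Python:

```python
import ethotrace as et

cfg = et.default_config()
script = et.random_script(cfg, seed=7, total_duration_s=600)
track, stream, truth = et.simulate_night(script, cfg, et.noiseless(), seed=8)
seq = et.aggregate_to_seconds(et.classify_track(track, cfg), cfg)
print((seq.labels == truth.labels).mean())   # 1.0
print(et.time_budget(seq, cfg).percents.round(1).to_dict())
```

Concordance between coding methods, as printed by `ethotrace concord`
on three label files, uses time-budget sums over the n = 6 categories
(five behaviors + out of view); for example three identical files give
`W = 1.000 (m = 3, n = 6), chi2 = 15.00, p = 0.0104`.

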