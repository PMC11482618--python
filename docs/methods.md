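# Methods

## The coding model

`ethotrace` treats automated behavioral coding as a deterministic
post-processing problem. Upstream models are assumed to emit either

* a **pose track**: per frame and body part, an (x, y) pixel position
  and a likelihood in [0, 1], with some samples missing entirely
  (the network produced no label — distinct from a low likelihood), or
* a **detection stream**: per frame, at most one behavior label with a
  confidence.

Pixel coordinates use the image convention: origin top-left, y
increasing downward; the bundled configuration assumes a 1920×1080
frame. Frame indices are 0-based; time intervals are half-open, and
second *s* covers frames ⌊s·fps⌋ … ⌊(s+1)·fps⌋−1.

### Zone rules

Each non-default behavior may carry a zone rule: a set of axis-aligned
pixel boxes, one per constrained body part. A rule matches a frame iff
all its constrained parts are valid — labeled and with likelihood **at
or above** the p-cutoff (a closed lower bound; the common convention
when a threshold is quoted without strictness) — and inside their
boxes. When several rules match, the lowest priority integer wins; the
bundled fixture orders Lying down < Foraging < Hay-net < Drinking so
specific zones beat each other deterministically. Unmatched frames are
the default behavior (`Standing`) when at least one *anchor* body part
(head or trunk root) is valid, and `Out of view` when every anchor is
invalid. Requiring **all** anchors to fail before declaring out-of-view
keeps partial tracking dropout from masquerading as absence: with one
anchor surviving, the animal is demonstrably in frame.

Swaying deliberately has no zone rule: it can occur anywhere in the
frame, so zone classification codes it as its underlying posture
(standing) and detection is delegated to the displacement statistic
below. Consequently the noiseless-identity property (classification
recovers a scripted night exactly) holds for scripts over zone-codable
behaviors, which is how it is tested.

### Second aggregation and minimum durations

Manual scoring operates at 1-s resolution, so frame labels are reduced
to seconds by majority vote. Ties break toward the better tie rank:
zone-ruled behaviors by rule priority, then unruled behaviors in
declaration order, with `Out of view` losing every tie (it should never
displace an equally supported positive observation). Whether any
majority step is the "right" bridge from 25 FPS output to 1-s scoring
is underdetermined; majority vote is this package's documented choice.
After aggregation, maximal runs of a duration-constrained behavior
shorter than its minimum (sway: 5 s) are relabeled to the default.
Enforcing the rule after aggregation, in whole seconds, matches the
resolution at which the rule is stated.

## Sway detection

The statistic is the per-frame Euclidean step of one keypoint (default
`trunk_root`) between consecutive valid samples; its running sum is the
cumulative-displacement trace whose steep increases visually mark sway.
Steps across tracking gaps are charged zero: label dropout is common,
and charging the jump across a gap would fabricate motion.

Bouts are segmented by a rate rule rather than a spectral one: per
second the displacement sum (px/s) is smoothed with a centered moving
average (`window_s`, default 10 s); seconds at or above
`rate_threshold` are active; active runs separated by gaps ≤
`merge_gap_s` (default 2 s) merge; merged runs ≥ `min_duration_s`
(default 5 s) are bouts. The rate rule reproduces exactly the evidence
used in practice — the slope of the cumulative trace — with one
interpretable threshold. A sinusoid x(t) = A·sin(2πt/T) travels 4A per
period, so its mean rate is 4A/T px/s (helper `sinusoid_mean_rate`);
setting the threshold to half that value separates a sway bout from
background jitter whenever the bout rate is comfortably above the
jitter rate. Stationary Gaussian jitter of SD σ per coordinate
produces a mean background step of σ√π px/frame (≈ 25σ√π px/s at
25 FPS), which is the number to compare a candidate threshold against.
Frequency-domain stereotypy detection is out of scope.

## Agreement statistics

* **Time budgets** — per-behavior seconds as percentages of total
  observation time; out-of-view is a category, so budgets always sum to
  100%.
* **Confusion matrices** — observer-referenced: columns are the
  manually observed behavior, rows the model prediction; the normalized
  view divides each column by its sum (empty columns stay zero).
* **Kendall's W** — computed from an m×n value table (m raters — coding
  methods or nights — ranking n items, typically per-behavior
  time-budget sums over the six codable categories: five behaviors plus
  out-of-view). Ties get average ranks with the standard correction
  W = 12·Σ(Rᵢ − m(n+1)/2)² / (m²(n³−n) − m·ΣT), T = Σ(t³−t) per rater.
  The p-value uses the large-sample approximation χ² = m(n−1)W on n−1
  degrees of freedom. This is the field-standard test and reproduces
  published W→p pairs at m = 3 and m = 7 to two significant figures,
  but the approximation is *coarse for small m*: at m = 3, n = 6 its
  tail probabilities differ from the exact permutation null by an
  order of magnitude at high W (the permutation null is discrete and
  much lighter-tailed there). The package keeps the χ² approximation
  as the reported p-value because that is what the statistic's users
  print; treat small-m p-values as approximate.
* **Spearman** — average-rank Spearman via `scipy.stats.spearmanr`,
  with constant input rejected explicitly (the coefficient is
  undefined). Night-to-night sleep comparisons correlate per-minute
  cumulative 'Lying down' series by default (`--resolution-s 60`); the
  sampling resolution of such comparisons is rarely stated in field
  reports, so it is exposed as a parameter.

## The synthetic night

The generator's job is statistical structure, not photorealism. A
*script* is an alternating-renewal bout sequence: behaviors switch
uniformly among the others, bout durations are exponential with
per-behavior means (clamped to ≥ 1 s, integer seconds), truncated at
the night's end. Defaults emulate one 7-h night (25,200 s) at 25 FPS
with mean bout lengths of 1150/1200/500/260/70 s for
Standing/Lying down/Foraging/Hay-net/Drinking — long-run shares of
roughly 36/38/16/8/2%, the ballpark of captive-elephant night budgets
in which recumbent rest occupies a third or more of the night. Real
nights are not renewal processes (lying is consolidated into a few
long early-night bouts, foraging follows feeder timers), so passing
tests demonstrate correctness of the pipeline's arithmetic, not
realism of elephant behavior.

Rendering places each body part at its behavior's geometry point
(inside its zone box, outside all others), adds sway oscillation to
head and trunk root during Swaying bouts (defaults A = 40 px,
T = 4 s — no published kinematics exist; parameters, not constants),
then applies, in order: Gaussian jitter (`coord_sd`, default 1 px, the
order of a well-trained pose model's training error), low-likelihood
draws (`low_conf_p` = 0.05, likelihood below the p-cutoff), and dropout
(`dropout_p` = 0.05, sample missing). The detection stream draws each
frame's label from a row-stochastic confusion matrix indexed by the
true behavior (sway maps to standing first, since box-based detectors
do not code it), then blanks frames with probability `det_miss_p`
(default 0.10, the order of the out-of-view excess that detection
models show against near-zero manual values). The default confusion
concentrates errors on the two documented failure modes: drinking read
as standing, and hay-net reaching read as foraging. One
`numpy.random.default_rng(seed)` drives every draw, so fixed seeds give
bit-identical outputs.

Because detection corruption is i.i.d. per frame, the column-normalized
confusion estimate converges to the generator matrix at *frame*
resolution with `det_miss_p = 0`; majority-vote aggregation to seconds
sharpens per-frame error rates, so recovery checks are done at frame
level.

## Numerical and design notes

* Likelihood exactly equal to the p-cutoff is retained.
* Empty sequences: classification of an empty track yields an empty
  sequence; time budgets reject empty input.
* `detect_sway_bouts` with threshold 0 returns one bout spanning the
  record (any rate ≥ 0); with threshold ∞, none. Output is invariant
  under uniform translation of all coordinates.
* Degenerate Kendall tables (m < 2 or n < 2) are rejected; reversed
  two-rater rankings give W = 0 and p = 1.
* Pose CSV floats are written at full precision and parsed with
  pandas' round-trip parser, so write→read is the identity.
* Problem sizes in the test and acceptance suites: noiseless identity
  runs 20 full 7-h nights; confusion recovery one 7-h night; sway
  recovery ten 7-h nights with three planted bouts each at jitter
  SD 0.3 px (chosen so the planted 40 px/s bout rate is ≥ 2× the
  ≈ 13 px/s background rate, the regime in which a rate detector is
  expected to work); statistic oracles use 100 random small tables and
  a 10,000-draw permutation null.

## Known limitations

* Zone boxes are static and per-camera; no support for moving cameras,
  multi-animal disambiguation, or learned zone boundaries.
* The χ² p-value for W is anticonservative/inaccurate for small m (see
  above); an exact permutation p-value is straightforward to compute
  from `kendalls_w` on permuted tables if small-m inference matters.
* The sway detector is rate-based: slow drifting locomotion at
  sway-like displacement rates would false-positive; oscillation
  frequency is not checked.
* The simulator does not model autocorrelated detection errors,
  lighting changes, or occlusion geometry; agreement numbers on
  synthetic nights are upper bounds on what real footage yields.
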