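# Methods

## The classification model

The pipeline estimates, for each 0.5-second window of a consultation
recording, which of four doctor–patient–computer interaction classes is
taking place: screen gaze with dialogue (SG+D), dialogue only (D), screen
gaze only (SG), or neither (Other). Two independent binary classifiers are
fused:

### Screen gaze (per video frame)

Input is a stream of five facial keypoints per frame — nose, left/right
eye, left/right ear, each `(x, y, confidence)` — from any body-pose
estimator. A keypoint is *estimated* iff its confidence exceeds
`presence_threshold` (default 0: any positive confidence; pose backends
calibrate confidences differently, so this is configuration). A frame is
*screen gaze* iff

1. both ears are estimated, and
2. nose, left eye and right eye are estimated and
   `|x_n − (x_l + x_r)/2| ≤ tolerance_factor · |x_l − x_r|`
   with `tolerance_factor = 0.5`.

Numerical conventions, chosen once and asserted by tests:

* **Axis.** Offsets and the inter-eye distance are measured on the x axis
  only (`axis="horizontal"`), since head yaw is the motion that carries the
  signal; a Euclidean variant (planar nose-to-midpoint distance against
  planar inter-eye distance) is available through configuration.
* **Boundary.** Offset exactly equal to the tolerance counts as screen
  gaze (≤, matching the reading of a "tolerance").
* **Undetected person.** A frame with no detected person classifies as no
  screen gaze rather than being dropped, so the window grid never shifts
  relative to the audio.

In multi-person streams the doctor is selected as the person with the
largest mean inter-eye pixel distance over frames where both eyes are
estimated (the face closest to the doctor's own camera); exact ties break
to the lower person id.

### Dialogue (per audio segment)

Mono audio is cut into consecutive non-overlapping segments of
`segment_ms = 5` ms (a trailing remainder shorter than one segment is
dropped). Each segment receives a binary voice decision. The built-in
reference detector is a short-time energy gate:

* per-segment level = `20·log10(RMS)` dBFS, clamped at −96 dB for silence;
* adaptive noise floor = the `noise_floor_percentile` (default 10th)
  percentile of the per-segment levels of the whole recording;
* decision: voice iff level **strictly** exceeds floor + `delta_db`.

`delta_db` defaults to a map from the detector `aggressiveness` (0→3, 1→6,
2→9, 3→12 dB; default aggressiveness 3, i.e. the strictest filtering of
non-speech). These two fields overlap: an explicitly set `delta_db`
overrides the aggressiveness map. The detector is deliberately simple —
scale-covariant, fully deterministic, dependency-free — so the windowing
and fusion layers can be tested without an external engine; any external
per-segment VAD can be registered as a backend, and requesting an
unregistered backend is a configuration error, never a silent fallback.
Stereo input is rejected rather than silently down-mixed.

### Windowing and fusion

Frame/segment decisions are majority-voted onto the window grid
(`window_seconds = 0.5`, half-open windows `[t, t+0.5)`):

* majority label per window;
* a tie takes the previous window's label (temporal continuity); a tie in
  the first window resolves to 0;
* a trailing partial window is kept iff it holds at least half a window of
  items, else dropped.

The (gaze, voice) pair then maps bijectively onto {SG+D, D, SG, Other} —
no fallback class, so the pair is recoverable from every timeline label.
Series of unequal length (video and audio tails rarely coincide) are
truncated to the shorter with an explicit warning; series on different
grids raise an alignment error. No smoothing is applied to the fused
timeline.

## Evaluation machinery

Confusion matrices are 4×4 with rows = ground truth and columns =
prediction, in fixed class order (SG+D, D, SG, Other). Per-class
precision, recall and F1 use the zero-denominator convention that an
undefined metric is 0. Support-weighted scores weight each class by its
ground-truth window count; weighted recall is identically the accuracy
(asserted to 12 decimals in tests). Reported metrics round to 2 decimals
and percentages to 1 decimal, half away from zero.

Accuracy comparisons between raters use a two-sided two-sample t test with
pooled variance (Student), so ten videos per rater give 18 degrees of
freedom and five give 8; Welch's form is available behind a flag. Constant
equal lists return t = 0, p = 1; zero pooled variance with unequal means
returns a signed infinite t.

**Transitions.** A transition is any window where the timeline's class
changes; it *qualifies* for timing analysis iff it is preceded and followed
by at least 1.5 s (3 windows) of a single continuous class, bounds
inclusive. A prediction error is *attributable to a transition timing
shift* iff a qualifying ground-truth boundary `b` exists such that the
error window `w` lies within the shift radius (2 windows = 0.5–1 s by
default) and the predicted label equals the truth on the *other* side of
the boundary: early marking (`b−2 ≤ w < b`, prediction shows the
post-transition class) or late marking (`b ≤ w ≤ b+1`, prediction shows the
pre-transition class). Each boundary can therefore absorb at most 2 early
+ 2 late windows. The per-window attribution test and its radius are a
design choice of this package (the shift definition fixes only the 0.5–1-s
range); the radius is configurable for sensitivity analysis.

## The session simulator

The simulator exists to make every pipeline stage testable without
clinical recordings. It renders a scripted sequence of interaction states
(a `ScenarioScript`: ordered (state, duration) segments plus layout and
seed) into the three artefacts the pipeline consumes and one it is scored
against: a keypoint stream, audio (or per-segment voice decisions directly,
for fast tests), and the ground-truth timeline (the script discretised to
the window grid by majority overlap, ties to the earlier segment, with the
same trailing-partial rule as the classifiers).

### Head geometry

Eyes sit at azimuths ±α (default 30°) on a head circle of radius r = 1,
the nose protrudes at azimuth 0 with radius r_n = 1.8 > r·cos α, and the
camera projects `x = radius · sin(azimuth + yaw) · pixel_scale`. The gaze
rule then flips analytically at

    θ* = atan( r·sin α / (r_n − r·cos α) ) ≈ 28.16°,

and the ear on the far side of the turn is occluded (confidence 0) beyond
`ear_occlusion_yaw = 30°`. These constants are self-consistent stand-ins,
not anatomy; what the tests assert is the boundary the projection equations
imply, matched empirically to within the sweep step. Per state, the yaw is
drawn once per segment: N(0°, 5°) when facing the screen, N(±away_mean,
away_sd) otherwise, with away_mean = 45° (semi-inclusive layout) or 90°
(fully inclusive) and away_sd = 10° by default. An optional linear yaw
ramp (`yaw_ramp_seconds`) sweeps the head between segments instead of
jumping, producing genuine transition timing shifts; the default is an
instantaneous turn. Gaussian pixel jitter and independent per-keypoint
dropout model detector noise.

### Speech

Dialogue states carry alternating speech bursts (lognormal durations,
median 4 s) and turn-taking gaps (uniform 0.2–0.4 s). Within a burst,
voiced word groups (0.35–0.7 s) alternate with intra-utterance micro-pauses
(0.05–0.15 s); a pause never ends a burst. Micro-pauses serve two
purposes: they are realistic, and they guarantee a silent-segment
population larger than the floor percentile even in dialogue-saturated
sessions — without them the adaptive noise floor can land inside the
voiced level cluster and the energy detector collapses. Voiced samples sit
30 dB above a −50 dBFS Gaussian background; non-dialogue states carry only
background plus rare 50-ms clicks (door, keyboard) that are far below half
a window and never flip a label. `sample_script` draws layout-appropriate
state mixes (dialogue-dominated, screen-only and idle states brief) with
dwell times of 2–12 s.

### What the simulator does and does not establish

A 0.5-s window flips to silence only if more than half of its 100 segments
are silent, i.e. ≥ 0.255 s; a turn gap can contribute at most its own
length plus two partially voiced boundary segments (< 0.01 s). Hence gaps
up to 0.24 s provably never flip a window, while the default 0.2–0.4-s
gaps occasionally flip a mid-dialogue window to Other — exactly the
dialogue-to-Other confusion mode observed with real recordings, and the
reason human coders and windowed VADs disagree about short silences. The
package therefore distinguishes two regimes:

* **exact-recovery regime** (`low_noise_head` / `low_noise_speech`: jitter
  0.5 px, no dropout, yaw sds 5°, gaps 0.15–0.23 s): every window farther
  than 1 s from a scripted transition is classified correctly, and
  aggregate accuracy over ten 3-minute sessions exceeds 0.95 — this
  validates the rule, the detector, the vote and the fusion, end to end;
* **default regime** (gaps up to 0.4 s, yaw sd 10°): aggregate accuracy
  stays ≥ 0.95 but mid-state dialogue dropouts appear, and lengthening
  gaps beyond half a window strictly increases D→Other confusions.

Passing these tests shows the pipeline implements its stated rules
faithfully and recovers planted structure under controlled noise. It does
not show field accuracy on clinical video: real pose estimators produce
correlated, pose-dependent errors rather than i.i.d. jitter and dropout;
real speech levels vary and overlap with noise far more than a 30-dB
two-level model; real head motion is continuous and anticipatory. The
layout-effect comparison (fully inclusive easier than semi-inclusive) is
asserted on matched scripts under both geometries — it mirrors the
field observation directionally but is a property of the simulator's
geometry, not clinical evidence.

## Problem sizes and tolerances

The test suite and the acceptance script run the simulator at ten sessions
of 180 s (3600 windows, 54 000 frames, 48 s of unit-test budget in total)
and property checks on randomized inputs of up to 1000 windows; the yaw
sweep uses a 0.05° step against a 1° acceptance band. Published-table
arithmetic is asserted at the tables' printed precision (2 decimals for
scores, 1 for percentages), except two weighted cells that were evidently
computed from unrounded per-class scores before printing; recomputation
from the printed two-decimal scores reproduces them only within the input
rounding propagation bound (~0.01), and they are asserted at that bound
with the cause noted in the test.

## Known limitations

* The gaze rule captures yaw only; pitch and roll are outside its design,
  and fully exclusive clinic layouts (doctor's back to the patient) are out
  of scope.
* Speaker identity and speech content are not modelled: no diarization, no
  recognition, no doctor-vs-patient attribution of speech.
* The reference VAD is an energy gate: it will count any sufficiently loud
  noise as voice and is meant as a well-specified default and test anchor,
  not a replacement for a production VAD in noisy clinics.
* Interval ground truth must be non-overlapping and ordered; overlapping
  annotations are rejected rather than resolved.
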