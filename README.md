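# gazedialogue

Unobtrusive, automatic classification of **screen gaze and dialogue
combinations in doctor–patient–computer interactions**.

With electronic medical records on every clinic desk, the doctor–patient
relationship has become a triad of doctor, patient and computer. Researchers
who study these interactions — health-communication researchers, medical
informaticians, educators — traditionally videotape consultations and code
them by hand, which is slow, costly and obtrusive. `gazedialogue`
implements a computational-ethnography alternative: the only required
hardware is the computer's own camera and microphone, and every 0.5-second
window of a consultation is classified into one of four interaction
classes:

| screen gaze | dialogue | class  |
|-------------|----------|--------|
| yes         | yes      | SG+D   |
| no          | yes      | D      |
| yes         | no       | SG     |
| no          | no       | Other  |

## The two classifiers

**Screen gaze** is detected per video frame from five facial keypoints
produced by any body-pose estimator (nose, eyes, ears, each with a detector
confidence). A doctor facing the screen presents a frontal pose to the
camera above it, so a frame is classified *screen gaze* iff

1. both ears are estimated (confidence above the presence threshold), and
2. the nose is horizontally centred between the eyes, with a tolerance of
   half the inter-eye distance:

   |x_nose − (x_left_eye + x_right_eye)/2| ≤ ½ · |x_left_eye − x_right_eye|

Head yaw away from the screen breaks both conditions: the far ear is
occluded and the nose projection drifts toward the near eye.

**Dialogue** is detected from mono audio cut into 5-ms segments. Each
segment gets a binary voice decision — by default a self-contained
energy detector that thresholds the segment's RMS level against an adaptive
noise floor (a low percentile of the per-segment level distribution) plus
an aggressiveness-dependent margin; an external VAD engine can be plugged
in instead.

Frame and segment decisions are majority-voted onto a common 0.5-second
window grid and fused into the four classes. Evaluation utilities score a
predicted timeline against interval ground truth: confusion matrices,
per-class precision/recall/F1 with supports, support-weighted scores,
accuracy t tests, transition tables, and an analysis separating errors that
are mere 0.5–1-s timing shifts of a class transition from substantive
misclassifications.

Because clinical recordings cannot be shipped, the package includes a
session simulator (`gazedialogue.simulate`): scripted interaction states
are rendered into keypoint streams through a head-yaw geometry model
(under which the gaze rule flips analytically at
θ\* = atan(r·sin α / (r_n − r·cos α)) ≈ 28.2°), and into audio with
turn-taking speech bursts, so the whole pipeline is testable end to end.
The two clinic seating layouts are modelled by the away-gaze yaw: ~45° when
the patient sits beside the computer desk (semi-inclusive), ~90° when the
patient sits beside the doctor (fully inclusive).

## Worked example

Simulate a one-minute fully inclusive consultation, classify it, and score
the result against the simulated ground truth:

```sh
gazedialogue simulate demo --layout fully-inclusive --seed 7 --duration 60
gazedialogue classify demo/keypoints.jsonl demo/audio.wav demo/pred.csv
gazedialogue evaluate demo/pred.csv demo/truth.csv
```

which prints

```text
simulated 60s fully-inclusive session (1800 frames, 120 windows) in demo
wrote 120 interaction windows to demo/pred.csv
{
  "accuracy": 0.98,
  "classes": [
    {"class": "SG+D",     "precision": 1.0,  "recall": 0.97, "f1": 0.99, "support": 39},
    {"class": "D",        "precision": 1.0,  "recall": 0.97, "f1": 0.99, "support": 75},
    {"class": "SG",       "precision": 0.86, "recall": 1.0,  "f1": 0.92, "support": 6},
    {"class": "Other",    "precision": 0.0,  "recall": 0.0,  "f1": 0.0,  "support": 0},
    {"class": "weighted", "precision": 0.99, "recall": 0.98, "f1": 0.98, "support": 120}
  ],
  ...
}
```

Of the 120 half-second windows, 117 are classified exactly as scripted
(accuracy 0.98); the three errors sit at scripted state changes, where a
window straddling the boundary can legitimately take either side's label.
The `weighted` row averages the per-class scores with weights proportional
to each class's support (its window count in the ground truth); weighted
recall always equals the accuracy. `gazedialogue transitions demo/pred.csv
demo/truth.csv` additionally tabulates the ground-truth transitions and
reports how many errors are attributable to 0.5–1-s transition shifts.

The same `evaluate`/`transitions` commands accept real data: keypoint
streams in the per-frame JSON dialect of common pose estimators, mono WAV
audio, and interval ground-truth CSV (`start_s,end_s,label`).

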