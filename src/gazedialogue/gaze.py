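"""Screen-gaze classification from face keypoints.

A doctor facing their computer's camera presents a frontal head pose: both
ears are visible to the pose estimator, and the nose sits roughly midway
between the eyes.  Head yaw away from the screen breaks both cues — the far
ear disappears and the nose projection drifts toward the near eye.  The
per-frame rule is therefore:

    screen_gaze  iff  both ears estimated
                  and both eyes and the nose estimated
                  and |x_nose - (x_left_eye + x_right_eye) / 2|
                        <= tolerance_factor * |x_left_eye - x_right_eye|

with ``tolerance_factor`` defaulting to 0.5 (half the inter-eye distance).
A keypoint counts as estimated when its detector confidence exceeds the
presence threshold.  The boundary case (offset exactly equal to the
tolerance) counts as screen gaze.  Frame decisions are then majority-voted
onto the 0.5-second window grid by :mod:`gazedialogue.windowing`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .windowing import BinaryLabelSeries, aggregate_frame_labels

__all__ = [
    "Keypoint",
    "FaceKeypointFrame",
    "GazeRuleConfig",
    "classify_frame_gaze",
    "select_primary_person",
    "classify_gaze_stream",
    "KEYPOINT_NAMES",
]

KEYPOINT_NAMES = ("nose", "left_eye", "right_eye", "left_ear", "right_ear")


@dataclass(frozen=True)
class Keypoint:
    """One detected facial landmark: pixel coordinates plus detector
    confidence in [0, 1].  Confidence 0 means "not estimated"."""

    x: float = 0.0
    y: float = 0.0
    confidence: float = 0.0


# A keypoint slot that the detector did not fill.
MISSING = Keypoint(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class FaceKeypointFrame:
    """The five facial keypoints of one person in one video frame."""

    timestamp: float = 0.0
    person_id: int = 0
    nose: Keypoint = MISSING
    left_eye: Keypoint = MISSING
    right_eye: Keypoint = MISSING
    left_ear: Keypoint = MISSING
    right_ear: Keypoint = MISSING

    def keypoints(self) -> dict[str, Keypoint]:
        return {name: getattr(self, name) for name in KEYPOINT_NAMES}

    def validate(self) -> None:
        """Raise :class:`ValidationError` naming this frame if any keypoint
        is malformed (confidence outside [0, 1], non-finite coordinate)."""
        for name, kp in self.keypoints().items():
            if not (0.0 <= kp.confidence <= 1.0):
                raise ValidationError(
                    f"frame t={self.timestamp:g}s person={self.person_id}: "
                    f"{name} confidence {kp.confidence!r} outside [0, 1]"
                )
            if not (math.isfinite(kp.x) and math.isfinite(kp.y)):
                raise ValidationError(
                    f"frame t={self.timestamp:g}s person={self.person_id}: "
                    f"{name} has non-finite coordinates ({kp.x!r}, {kp.y!r})"
                )


@dataclass(frozen=True)
class GazeRuleConfig:
    """Tunables of the frame-level gaze rule.

    presence_threshold
        A keypoint is "estimated" iff confidence > this (default 0.0, i.e.
        any positive confidence; pose backends differ in calibration).
    tolerance_factor
        Allowed nose offset from the eye midpoint, as a fraction of the
        inter-eye distance.  Default 0.5: half the distance between the eyes.
    axis
        ``"horizontal"`` (default) measures offset and inter-eye distance on
        the x axis only — head yaw is the motion of interest.  ``"euclidean"``
        uses planar distances instead.
    """

    presence_threshold: float = 0.0
    tolerance_factor: float = 0.5
    axis: str = "horizontal"

    def __post_init__(self) -> None:
        if not (0.0 <= self.presence_threshold < 1.0):
            raise ValidationError("presence_threshold must lie in [0, 1)")
        if self.tolerance_factor <= 0:
            raise ValidationError("tolerance_factor must be positive")
        if self.axis not in ("horizontal", "euclidean"):
            raise ValidationError(f"unknown axis convention: {self.axis!r}")

    def present(self, kp: Keypoint) -> bool:
        return kp.confidence > self.presence_threshold


def classify_frame_gaze(frame: FaceKeypointFrame, cfg: GazeRuleConfig | None = None) -> bool:
    """Apply the frame-level screen-gaze rule; True means screen gaze."""
    cfg = cfg or GazeRuleConfig()
    frame.validate()
    if not (cfg.present(frame.left_ear) and cfg.present(frame.right_ear)):
        return False
    if not (cfg.present(frame.left_eye) and cfg.present(frame.right_eye) and cfg.present(frame.nose)):
        return False
    le, re, nose = frame.left_eye, frame.right_eye, frame.nose
    if cfg.axis == "horizontal":
        offset = abs(nose.x - (le.x + re.x) / 2.0)
        spread = abs(le.x - re.x)
    else:
        mx, my = (le.x + re.x) / 2.0, (le.y + re.y) / 2.0
        offset = math.hypot(nose.x - mx, nose.y - my)
        spread = math.hypot(le.x - re.x, le.y - re.y)
    return offset <= cfg.tolerance_factor * spread


def select_primary_person(
    records: Sequence[Mapping[int, FaceKeypointFrame]],
    cfg: GazeRuleConfig | None = None,
) -> int:
    """Pick the person closest to the camera in a multi-person stream.

    The doctor is the person facing the computer's own camera, hence the
    largest face: the person with the greatest mean inter-eye pixel distance
    over frames where both eyes are estimated.  Ties break to the lower
    person id.
    """
    cfg = cfg or GazeRuleConfig()
    dists: dict[int, list[float]] = {}
    for record in records:
        for pid, frame in record.items():
            if cfg.present(frame.left_eye) and cfg.present(frame.right_eye):
                d = math.hypot(
                    frame.left_eye.x - frame.right_eye.x,
                    frame.left_eye.y - frame.right_eye.y,
                )
                dists.setdefault(pid, []).append(d)
    if not dists:
        raise ValidationError("no classifiable person: no frame has both eyes estimated")
    # max mean distance, ties to the lower person_id
    return min(dists, key=lambda pid: (-float(np.mean(dists[pid])), pid))


def classify_gaze_stream(
    frames: Iterable[FaceKeypointFrame],
    cfg: GazeRuleConfig | None = None,
    fps: float = 30.0,
    window_seconds: float = 0.5,
    *,
    start_time: float = 0.0,
) -> BinaryLabelSeries:
    """Per-frame gaze rule followed by majority voting onto the window grid.

    Frames where the person is undetected (all confidences at or below the
    presence threshold) classify as no screen gaze, keeping the window grid
    aligned with the audio stream rather than shifting it.
    """
    cfg = cfg or GazeRuleConfig()
    labels: list[int] = []
    for i, frame in enumerate(frames):
        try:
            labels.append(1 if classify_frame_gaze(frame, cfg) else 0)
        except ValidationError as exc:
            raise ValidationError(f"frame index {i}: {exc}") from exc
    if not labels:
        raise ValidationError("empty keypoint stream")
    return aggregate_frame_labels(
        labels, fps=fps, window_seconds=window_seconds, kind="gaze", start_time=start_time
    )
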