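import numpy as np
import pytest

from gazedialogue import (
    FaceKeypointFrame,
    InteractionTimeline,
    Keypoint,
)
from gazedialogue.fusion import CLASSES


def make_frame(
    nose_x=120.0,
    left_eye_x=140.0,
    right_eye_x=100.0,
    *,
    conf=0.9,
    left_ear_conf=None,
    right_ear_conf=None,
    nose_conf=None,
    y=0.0,
    timestamp=0.0,
    person_id=0,
) -> FaceKeypointFrame:
    """Frontal-ish face frame with overridable x positions and confidences."""
    return FaceKeypointFrame(
        timestamp=timestamp,
        person_id=person_id,
        nose=Keypoint(nose_x, y + 10, conf if nose_conf is None else nose_conf),
        left_eye=Keypoint(left_eye_x, y, conf),
        right_eye=Keypoint(right_eye_x, y, conf),
        left_ear=Keypoint(left_eye_x + 40, y, conf if left_ear_conf is None else left_ear_conf),
        right_ear=Keypoint(right_eye_x - 40, y, conf if right_ear_conf is None else right_ear_conf),
    )


def timeline_of(labels, window_seconds=0.5, start_time=0.0) -> InteractionTimeline:
    return InteractionTimeline(tuple(labels), window_seconds=window_seconds, start_time=start_time)


def random_timeline(rng: np.random.Generator, n: int, persistence=0.8) -> InteractionTimeline:
    """Sticky random 4-class timeline (runs of a few windows, like real coding)."""
    labels = [rng.choice(CLASSES)]
    for _ in range(n - 1):
        if rng.random() < persistence:
            labels.append(labels[-1])
        else:
            labels.append(rng.choice([c for c in CLASSES if c != labels[-1]]))
    return timeline_of(labels)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
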