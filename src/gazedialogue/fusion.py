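"""Fusion of gaze and voice window series into the four interaction classes.

Each 0.5-second window is assigned one of four doctor-patient-computer
interaction classes from the (screen gaze, dialogue) pair:

    ==========  ========  =======
    screen gaze dialogue  class
    ==========  ========  =======
    yes         yes       SG+D
    no          yes       D
    yes         no        SG
    no          no        Other
    ==========  ========  =======

The mapping is a bijection — there is no fallback class — so the original
pair is exactly recoverable from every timeline label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, ValidationError
from .windowing import BinaryLabelSeries

__all__ = ["CLASSES", "InteractionTimeline", "fuse_streams", "pair_to_class", "class_to_pair"]

#: Canonical class order used everywhere (timelines, confusion matrices, reports).
CLASSES = ("SG+D", "D", "SG", "Other")

_PAIR_TO_CLASS = {(1, 1): "SG+D", (0, 1): "D", (1, 0): "SG", (0, 0): "Other"}
_CLASS_TO_PAIR = {v: k for k, v in _PAIR_TO_CLASS.items()}


def pair_to_class(gaze: int, voice: int) -> str:
    return _PAIR_TO_CLASS[(int(gaze), int(voice))]


def class_to_pair(label: str) -> tuple[int, int]:
    try:
        return _CLASS_TO_PAIR[label]
    except KeyError:
        raise ValidationError(f"unknown interaction class: {label!r}") from None


@dataclass(frozen=True)
class InteractionTimeline:
    """Four-class interaction labels on the 0.5-second window grid."""

    labels: tuple[str, ...]
    window_seconds: float = 0.5
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise ValidationError("window_seconds must be positive")
        labels = tuple(self.labels)
        bad = sorted({l for l in labels if l not in CLASSES})
        if bad:
            raise ValidationError(f"unknown interaction classes: {bad}")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    def as_indices(self) -> np.ndarray:
        """Labels as integer indices into :data:`CLASSES`."""
        lut = {c: i for i, c in enumerate(CLASSES)}
        return np.array([lut[l] for l in self.labels], dtype=np.int64)

    def window_bounds(self) -> np.ndarray:
        starts = self.start_time + self.window_seconds * np.arange(len(self))
        return np.column_stack([starts, starts + self.window_seconds])


def fuse_streams(gaze: BinaryLabelSeries, voice: BinaryLabelSeries) -> InteractionTimeline:
    """Combine aligned gaze and voice series window-by-window.

    Both series must share the window length and start time; resampling is
    never done silently.  If their lengths differ (video and audio tails
    rarely end together), the fusion truncates to the shorter series and
    emits a warning recording how many windows were dropped.
    """
    if gaze.window_seconds != voice.window_seconds or gaze.start_time != voice.start_time:
        raise AlignmentError(
            "gaze and voice series are on different grids "
            f"(window {gaze.window_seconds} vs {voice.window_seconds} s, "
            f"start {gaze.start_time} vs {voice.start_time} s)"
        )
    n = min(len(gaze), len(voice))
    dropped = max(len(gaze), len(voice)) - n
    if dropped:
        warnings.warn(
            f"gaze and voice series differ in length; truncated to {n} windows "
            f"({dropped} dropped)",
            stacklevel=2,
        )
    labels = tuple(
        pair_to_class(g, v) for g, v in zip(gaze.labels[:n], voice.labels[:n])
    )
    return InteractionTimeline(
        labels, window_seconds=gaze.window_seconds, start_time=gaze.start_time
    )
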