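"""Majority-vote aggregation of per-frame / per-segment labels onto a fixed
window grid.

Every label stream in the pipeline — per-frame gaze decisions, per-segment
voice decisions, interval ground truth — is reduced to the same 0.5-second
grid before anything is fused or scored.  Windows are half-open
``[start, start + window_seconds)``.  The vote rules live here so the gaze
and dialogue classifiers cannot drift apart:

* each complete window takes the most frequent label of its frames;
* a tie takes the previous window's label (temporal continuity), and a tie
  in the very first window resolves to 0;
* a trailing partial window is kept iff it holds at least half a window's
  worth of frames, otherwise it is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = ["BinaryLabelSeries", "aggregate_frame_labels", "expected_window_count"]


@dataclass(frozen=True)
class BinaryLabelSeries:
    """Binary labels (0/1) on a fixed window grid.

    Parameters
    ----------
    labels
        Ordered window labels, each 0 or 1.
    window_seconds
        Window duration; 0.5 s throughout the pipeline by default.
    kind
        What the positive label means: ``"gaze"`` (screen gaze) or
        ``"voice"`` (dialogue).
    start_time
        Time of the left edge of the first window, seconds.
    """

    labels: np.ndarray
    window_seconds: float = 0.5
    kind: str = "gaze"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise ValidationError("window_seconds must be positive")
        if self.kind not in ("gaze", "voice"):
            raise ValidationError(f"unknown series kind: {self.kind!r}")
        arr = np.asarray(self.labels, dtype=np.int64)
        if arr.ndim != 1:
            raise ValidationError("labels must be a 1-D sequence")
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValidationError("labels must be 0 or 1")
        object.__setattr__(self, "labels", arr)

    def __len__(self) -> int:
        return int(self.labels.size)

    def window_bounds(self) -> np.ndarray:
        """(n, 2) array of [start_s, end_s) per window."""
        n = len(self)
        starts = self.start_time + self.window_seconds * np.arange(n)
        return np.column_stack([starts, starts + self.window_seconds])


def expected_window_count(n_items: int, items_per_second: float, window_seconds: float) -> int:
    """Number of windows produced for ``n_items`` uniformly spaced items,
    including a kept trailing partial (>= half-full) window."""
    per_window = items_per_second * window_seconds
    full = int(n_items // per_window)
    remainder = n_items - full * per_window
    return full + (1 if remainder >= per_window / 2 else 0)


def aggregate_frame_labels(
    per_frame_labels: Sequence[int] | np.ndarray,
    fps: float,
    window_seconds: float = 0.5,
    *,
    kind: str = "gaze",
    start_time: float = 0.0,
) -> BinaryLabelSeries:
    """Majority-vote per-item binary labels onto the window grid.

    ``fps`` is the item rate (video frames or audio segments per second).
    Requires ``fps * window_seconds >= 1`` so each window holds at least one
    item.  See the module docstring for tie and partial-window rules.
    """
    labels = np.asarray(per_frame_labels, dtype=np.int64)
    if labels.size == 0:
        raise ValidationError("cannot aggregate an empty label sequence")
    if fps <= 0 or window_seconds <= 0:
        raise ValidationError("fps and window_seconds must be positive")
    per_window = fps * window_seconds
    if per_window < 1:
        raise ValidationError("a window must span at least one frame")
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError("per-frame labels must be 0 or 1")

    # Frame i belongs to the window containing time i / fps.
    window_of = np.floor(np.arange(labels.size) / per_window).astype(np.int64)
    n_windows = int(window_of[-1]) + 1

    counts_1 = np.bincount(window_of, weights=labels, minlength=n_windows)
    counts = np.bincount(window_of, minlength=n_windows)

    # Trailing partial window: kept iff >= half-full.
    full = int(labels.size // per_window)
    if n_windows > full:
        if counts[-1] < per_window / 2:
            counts_1 = counts_1[:full]
            counts = counts[:full]
            n_windows = full
    if n_windows == 0:
        raise ValidationError("input shorter than half a window; nothing to aggregate")

    out = np.empty(n_windows, dtype=np.int64)
    prev = 0  # ties in the first window resolve to 0
    for w in range(n_windows):
        ones = counts_1[w]
        zeros = counts[w] - ones
        if ones > zeros:
            prev = 1
        elif ones < zeros:
            prev = 0
        out[w] = prev
    return BinaryLabelSeries(out, window_seconds=window_seconds, kind=kind, start_time=start_time)
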