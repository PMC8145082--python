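"""End-to-end convenience wrappers: session/streams in, timeline out."""

from __future__ import annotations

import warnings

import numpy as np

from .fusion import InteractionTimeline, fuse_streams
from .gaze import GazeRuleConfig, classify_gaze_stream
from .simulate import Session
from .vad import VadConfig, classify_dialogue
from .windowing import BinaryLabelSeries, aggregate_frame_labels

__all__ = ["classify_session", "align_timelines"]


def classify_session(
    session: Session,
    gaze_cfg: GazeRuleConfig | None = None,
    vad_cfg: VadConfig | None = None,
    window_seconds: float = 0.5,
) -> InteractionTimeline:
    """Run the full gaze + dialogue + fusion pipeline on a simulated session.

    Sessions carrying a waveform go through the configured VAD; sessions
    generated in decision-only mode feed their per-segment voice decisions
    straight into the window vote.
    """
    gaze = classify_gaze_stream(
        session.frames, gaze_cfg, fps=session.fps, window_seconds=window_seconds
    )
    if session.audio is not None:
        voice = classify_dialogue(session.audio, vad_cfg, window_seconds)
    else:
        voice = aggregate_frame_labels(
            session.voice_decisions,
            fps=1000.0 / session.segment_ms,
            window_seconds=window_seconds,
            kind="voice",
        )
    with warnings.catch_warnings():
        # video and audio tails may differ by one window; truncation is expected here
        warnings.simplefilter("ignore")
        return fuse_streams(gaze, voice)


def align_timelines(
    truth: InteractionTimeline, pred: InteractionTimeline
) -> tuple[InteractionTimeline, InteractionTimeline]:
    """Truncate two timelines on the same grid to their common length."""
    n = min(len(truth), len(pred))
    return (
        InteractionTimeline(truth.labels[:n], truth.window_seconds, truth.start_time),
        InteractionTimeline(pred.labels[:n], pred.window_seconds, pred.start_time),
    )
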