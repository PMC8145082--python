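"""Voice-activity detection and 0.5-second dialogue windowing.

Audio is cut into short fixed-length segments (5 ms by default), each
segment gets a binary voice / no-voice decision, and segment decisions are
majority-voted onto the same 0.5-second grid as the gaze labels.

The per-segment decision is pluggable.  The built-in reference detector is
a short-time energy gate against an adaptive noise floor: a segment is
voiced iff its RMS level in dBFS strictly exceeds ``noise floor + delta``,
where the floor is a low percentile of the per-segment RMS distribution and
delta encodes the detector's aggressiveness (how strictly non-speech is
filtered out).  An external engine (e.g. a WebRTC-style VAD) can be
registered as a backend; its absence is a configuration error, never a
silent fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .windowing import BinaryLabelSeries, aggregate_frame_labels

__all__ = [
    "AudioBuffer",
    "VadConfig",
    "segment_audio",
    "rms_dbfs",
    "estimate_noise_floor",
    "reference_vad",
    "classify_dialogue",
    "register_vad_backend",
]

#: Silence clamp for dB levels (16-bit quantisation floor).
DB_FLOOR = -96.0

#: delta_db implied by each aggressiveness level of the reference detector.
AGGRESSIVENESS_DELTA_DB = {0: 3.0, 1: 6.0, 2: 9.0, 3: 12.0}


@dataclass(frozen=True)
class AudioBuffer:
    """Mono PCM audio with samples normalised to [-1, 1]."""

    samples: np.ndarray
    sample_rate: int = 16000

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim == 2 and arr.shape[1] > 1:
            raise ValidationError(
                "multichannel audio: down-mix to mono explicitly before classification"
            )
        arr = arr.reshape(-1)
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError("audio contains non-finite samples")
        if arr.size and np.abs(arr).max() > 1.0 + 1e-9:
            raise ValidationError("samples must be normalised to [-1, 1]")
        object.__setattr__(self, "samples", arr)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class VadConfig:
    """Voice-activity detector settings.

    segment_ms
        Segment length in milliseconds (default 5).
    aggressiveness
        Ordinal 0-3; 3 (the default, and the strictest non-speech filter)
        maps to a 12 dB activation margin for the reference detector.
    delta_db
        Explicit activation margin in dB above the noise floor; None means
        "derive from aggressiveness".
    noise_floor_percentile
        Percentile of per-segment RMS used as the adaptive floor.
    backend
        ``"reference-energy"`` (built in) or ``"external"`` (must be
        registered via :func:`register_vad_backend`).
    """

    segment_ms: float = 5.0
    aggressiveness: int = 3
    delta_db: float | None = None
    noise_floor_percentile: float = 10.0
    backend: str = "reference-energy"

    def __post_init__(self) -> None:
        if self.segment_ms <= 0:
            raise ValidationError("segment_ms must be positive")
        if self.aggressiveness not in (0, 1, 2, 3):
            raise ValidationError("aggressiveness must be one of 0, 1, 2, 3")
        if not (0.0 <= self.noise_floor_percentile <= 100.0):
            raise ValidationError("noise_floor_percentile must lie in [0, 100]")

    @property
    def effective_delta_db(self) -> float:
        if self.delta_db is not None:
            return float(self.delta_db)
        return AGGRESSIVENESS_DELTA_DB[self.aggressiveness]


def segment_audio(audio: AudioBuffer, segment_ms: float = 5.0) -> np.ndarray:
    """Cut audio into consecutive equal-length segments.

    Returns a (n_segments, samples_per_segment) view; a trailing remainder
    shorter than one segment is dropped.
    """
    if len(audio) == 0:
        raise ValidationError("cannot segment empty audio")
    seg_len = int(round(audio.sample_rate * segment_ms / 1000.0))
    if seg_len < 1:
        raise ValidationError("segment_ms too short for this sample rate")
    n = len(audio) // seg_len
    if n == 0:
        raise ValidationError("audio shorter than one segment")
    return audio.samples[: n * seg_len].reshape(n, seg_len)


def rms_dbfs(segments: np.ndarray) -> np.ndarray:
    """Per-segment RMS level in dBFS, clamped at -96 dB for silence."""
    segments = np.atleast_2d(np.asarray(segments, dtype=np.float64))
    rms = np.sqrt(np.mean(segments**2, axis=-1))
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(rms)
    return np.maximum(db, DB_FLOOR)


def estimate_noise_floor(
    audio: AudioBuffer, percentile: float = 10.0, segment_ms: float = 5.0
) -> float:
    """Adaptive noise floor: the given percentile of per-segment RMS levels
    (dBFS).  Requires at least 10 segments of audio."""
    segments = segment_audio(audio, segment_ms)
    if segments.shape[0] < 10:
        raise ValidationError("audio too short to estimate a noise floor (need >= 10 segments)")
    return float(np.percentile(rms_dbfs(segments), percentile))


def reference_vad(
    segment: np.ndarray, noise_floor_db: float, delta_db: float = 12.0
) -> bool:
    """Energy-gate voice decision for one segment.

    True (voice) iff the segment's dBFS level strictly exceeds
    ``noise_floor_db + delta_db``.
    """
    if not np.isfinite(noise_floor_db):
        raise ValidationError("noise_floor_db must be finite")
    level = float(rms_dbfs(np.asarray(segment, dtype=np.float64))[0])
    return level > noise_floor_db + delta_db


# Registry for external per-segment VAD engines.  An engine receives the
# (n_segments, seg_len) float array and the sample rate and returns a binary
# decision per segment.
_VAD_BACKENDS: dict[str, Callable[[np.ndarray, int], np.ndarray]] = {}


def register_vad_backend(name: str, fn: Callable[[np.ndarray, int], np.ndarray]) -> None:
    _VAD_BACKENDS[name] = fn


def _segment_decisions(audio: AudioBuffer, cfg: VadConfig) -> np.ndarray:
    segments = segment_audio(audio, cfg.segment_ms)
    if cfg.backend == "reference-energy":
        floor = estimate_noise_floor(audio, cfg.noise_floor_percentile, cfg.segment_ms)
        levels = rms_dbfs(segments)
        return (levels > floor + cfg.effective_delta_db).astype(np.int64)
    if cfg.backend in _VAD_BACKENDS:
        out = np.asarray(_VAD_BACKENDS[cfg.backend](segments, audio.sample_rate), dtype=np.int64)
        if out.shape != (segments.shape[0],):
            raise ConfigurationError(f"backend {cfg.backend!r} returned a malformed decision array")
        return out
    raise ConfigurationError(
        f"VAD backend {cfg.backend!r} is not available; register it with "
        "register_vad_backend() or use 'reference-energy'"
    )


def classify_dialogue(
    audio: AudioBuffer,
    cfg: VadConfig | None = None,
    window_seconds: float = 0.5,
    *,
    start_time: float = 0.0,
) -> BinaryLabelSeries:
    """Per-segment voice decisions majority-voted onto the window grid.

    Uses the same tie-break (previous window's label; 0 at the start) and
    trailing-partial-window rules as the gaze classifier, so both label
    series live on an identical grid.
    """
    cfg = cfg or VadConfig()
    if audio.duration < window_seconds:
        raise ValidationError("audio spans less than one window")
    decisions = _segment_decisions(audio, cfg)
    segments_per_second = 1000.0 / cfg.segment_ms
    return aggregate_frame_labels(
        decisions,
        fps=segments_per_second,
        window_seconds=window_seconds,
        kind="voice",
        start_time=start_time,
    )
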