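"""Synthetic consultation sessions for end-to-end testing.

No clinical recordings ship with the package, so every pipeline stage is
exercised against simulated sessions: a scripted sequence of interaction
states is rendered into (a) a face-keypoint stream through a head-yaw
geometry model, (b) mono audio (or, for fast tests, per-segment voice
decisions directly), and (c) the ground-truth interaction timeline on the
0.5-second window grid.

Head geometry
-------------
Eyes sit at azimuths +/-alpha on a head-centred circle of radius r, the nose
protrudes at azimuth 0 on radius r_n > r cos(alpha), and the camera projects
x = radius * sin(azimuth + yaw) * pixel_scale.  Under this projection the
nose offset from the eye midpoint is (r_n - r cos a) sin(yaw) and the
inter-eye distance is 2 r sin(a) cos(yaw), so the half-inter-eye gaze rule
flips exactly at the yaw

    theta* = atan( r sin(a) / (r_n - r cos(a)) )

(about 28.2 degrees at the defaults).  The ear on the far side of the turn
is occluded beyond ``ear_occlusion_yaw``.  The two clinic layouts differ
only in how far the head must turn away from the screen to face the
patient: roughly 45 degrees when the patient sits beside the computer desk
(semi-inclusive) versus a full 90 degrees when the patient sits beside the
doctor (fully inclusive) — which is what makes the two layouts differently
easy to classify.

These geometry constants are stand-ins chosen for self-consistency, not
anatomical fidelity; tests assert the analytic boundary, not human anatomy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .fusion import InteractionTimeline, CLASSES
from .gaze import FaceKeypointFrame, Keypoint
from .vad import AudioBuffer

__all__ = [
    "HeadModelConfig",
    "SpeechModelConfig",
    "ScenarioScript",
    "Session",
    "yaw_boundary_deg",
    "boundary_margin_deg",
    "project_keypoints",
    "perturb_stream",
    "generate_session",
    "sample_script",
    "script_to_timeline",
]

DIALOGUE_STATES = ("SG+D", "D")
SCREEN_STATES = ("SG+D", "SG")


@dataclass(frozen=True)
class HeadModelConfig:
    """Geometry and noise of the synthetic head / pose detector.

    Angles in degrees, radii in arbitrary head units, pixel_scale in px per
    head unit.  ``away_yaw_mean`` is the mean head yaw when facing the
    patient: 45 for a semi-inclusive layout, 90 for a fully inclusive one.
    ``yaw_ramp_seconds`` optionally sweeps the head linearly between
    successive per-state yaws instead of jumping, which produces genuine
    transition timing shifts; the default is an instantaneous turn.
    """

    eye_azimuth_deg: float = 30.0
    eye_radius: float = 1.0
    nose_radius: float = 1.8
    ear_occlusion_yaw_deg: float = 30.0
    screen_yaw_sd_deg: float = 5.0
    away_yaw_mean_deg: float = 45.0
    away_yaw_sd_deg: float = 10.0
    yaw_ramp_seconds: float = 0.0
    pixel_scale: float = 100.0
    center_x: float = 320.0
    center_y: float = 240.0
    jitter_px: float = 0.0
    dropout_rate: float = 0.0
    keypoint_confidence: float = 0.9

    def __post_init__(self) -> None:
        a = math.radians(self.eye_azimuth_deg)
        if not (0.0 < self.eye_azimuth_deg < 90.0):
            raise ValidationError("eye_azimuth_deg must lie in (0, 90)")
        if self.nose_radius <= self.eye_radius * math.cos(a):
            raise ValidationError("nose must protrude: nose_radius > eye_radius * cos(alpha)")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValidationError("dropout_rate must lie in [0, 1]")
        if self.jitter_px < 0:
            raise ValidationError("jitter_px must be nonnegative")

    @classmethod
    def for_layout(cls, layout: str, **overrides) -> "HeadModelConfig":
        if layout == "semi-inclusive":
            return cls(away_yaw_mean_deg=45.0, **overrides)
        if layout == "fully-inclusive":
            return cls(away_yaw_mean_deg=90.0, **overrides)
        raise ValidationError(f"unknown layout: {layout!r}")


def yaw_boundary_deg(cfg: HeadModelConfig) -> float:
    """Analytic yaw at which the half-inter-eye gaze rule flips."""
    a = math.radians(cfg.eye_azimuth_deg)
    return math.degrees(
        math.atan2(cfg.eye_radius * math.sin(a), cfg.nose_radius - cfg.eye_radius * math.cos(a))
    )


def boundary_margin_deg(cfg: HeadModelConfig) -> float:
    """Separation between the away-gaze yaw and the rule boundary."""
    return abs(cfg.away_yaw_mean_deg - yaw_boundary_deg(cfg))


@dataclass(frozen=True)
class SpeechModelConfig:
    """Turn-taking speech model inside dialogue states.

    Speech alternates bursts and short turn-taking gaps; burst durations are
    lognormal (median ``burst_median_s``, log-sd ``burst_log_sd``), gaps are
    uniform in ``turn_gap_range_s``.  Within a burst, voiced word groups
    (uniform in ``word_group_range_s``) alternate with intra-utterance
    micro-pauses (uniform in ``micro_pause_range_s``) — far shorter than
    half a window, so they never flip a window label, but they keep a silent
    segment population present even in dialogue-saturated sessions, which is
    what makes an adaptive percentile noise floor estimable.  Voiced samples
    sit ``voiced_delta_db`` above the background level ``noise_floor_dbfs``.
    Non-dialogue states carry background noise plus rare short clicks
    (``click_rate_hz`` per second, ``click_duration_s`` each) that are far
    shorter than half a window and so never flip a window label.
    """

    burst_median_s: float = 4.0
    burst_log_sd: float = 0.4
    turn_gap_range_s: tuple[float, float] = (0.2, 0.4)
    word_group_range_s: tuple[float, float] = (0.35, 0.7)
    micro_pause_range_s: tuple[float, float] = (0.05, 0.15)
    noise_floor_dbfs: float = -50.0
    voiced_delta_db: float = 30.0
    click_rate_hz: float = 0.02
    click_duration_s: float = 0.05

    def __post_init__(self) -> None:
        for name in ("turn_gap_range_s", "word_group_range_s", "micro_pause_range_s"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} must be an increasing positive range")
        if self.burst_median_s <= 0 or self.burst_log_sd < 0:
            raise ValidationError("burst duration parameters must be positive")


@dataclass(frozen=True)
class ScenarioScript:
    """Ordered (state, duration_seconds) segments plus layout and seed."""

    segments: tuple[tuple[str, float], ...]
    layout: str = "semi-inclusive"
    seed: int = 0

    def __post_init__(self) -> None:
        segs = tuple((str(s), float(d)) for s, d in self.segments)
        if not segs:
            raise ValidationError("script has no segments")
        for s, d in segs:
            if s not in CLASSES:
                raise ValidationError(f"unknown interaction state: {s!r}")
            if d <= 0:
                raise ValidationError("segment durations must be positive")
        if self.layout not in ("semi-inclusive", "fully-inclusive"):
            raise ValidationError(f"unknown layout: {self.layout!r}")
        object.__setattr__(self, "segments", segs)

    @property
    def total_seconds(self) -> float:
        return sum(d for _, d in self.segments)

    def intervals(self) -> list[tuple[float, float, str]]:
        out, t = [], 0.0
        for s, d in self.segments:
            out.append((t, t + d, s))
            t += d
        return out

    def state_at(self, t: float) -> str:
        acc = 0.0
        for s, d in self.segments:
            acc += d
            if t < acc:
                return s
        return self.segments[-1][0]


def script_to_timeline(script: ScenarioScript, window_seconds: float = 0.5) -> InteractionTimeline:
    """Ground truth: the script discretised to the window grid by majority
    overlap (ties to the earlier segment), with the same trailing-partial
    rule as the classifiers."""
    from .io import intervals_to_timeline  # local import to avoid a cycle

    timeline = intervals_to_timeline(script.intervals(), window_seconds=window_seconds)
    if len(timeline) < 1:
        raise ValidationError("script shorter than one window")
    return timeline


def project_keypoints(
    yaw_deg: float,
    cfg: HeadModelConfig | None = None,
    *,
    timestamp: float = 0.0,
    person_id: int = 0,
) -> FaceKeypointFrame:
    """Project the five facial keypoints of a head at the given yaw.

    Positive yaw turns the head toward its left; beyond the occlusion yaw
    the far ear's confidence drops to 0.  No jitter or dropout is applied
    here — see :func:`perturb_stream`.
    """
    cfg = cfg or HeadModelConfig()
    if abs(yaw_deg) > 180.0:
        raise ValidationError("yaw must lie in [-180, 180] degrees")
    yaw = math.radians(yaw_deg)
    a = math.radians(cfg.eye_azimuth_deg)
    conf = cfg.keypoint_confidence

    def x_at(radius: float, azimuth: float) -> float:
        return cfg.center_x + radius * math.sin(azimuth + yaw) * cfg.pixel_scale

    eye_y = cfg.center_y - 0.20 * cfg.pixel_scale
    ear_y = cfg.center_y - 0.15 * cfg.pixel_scale
    nose_y = cfg.center_y + 0.10 * cfg.pixel_scale

    left_ear_conf = conf
    right_ear_conf = conf
    if abs(yaw_deg) > cfg.ear_occlusion_yaw_deg:
        # the ear rotating away from the camera disappears
        if yaw_deg > 0:
            right_ear_conf = 0.0
        else:
            left_ear_conf = 0.0

    return FaceKeypointFrame(
        timestamp=timestamp,
        person_id=person_id,
        nose=Keypoint(x_at(cfg.nose_radius, 0.0), nose_y, conf),
        left_eye=Keypoint(x_at(cfg.eye_radius, +a), eye_y, conf),
        right_eye=Keypoint(x_at(cfg.eye_radius, -a), eye_y, conf),
        left_ear=Keypoint(x_at(cfg.eye_radius, +math.pi / 2), ear_y, left_ear_conf),
        right_ear=Keypoint(x_at(cfg.eye_radius, -math.pi / 2), ear_y, right_ear_conf),
    )


def perturb_stream(
    frames: Sequence[FaceKeypointFrame],
    jitter_px: float,
    dropout_rate: float,
    seed: int | np.random.Generator = 0,
) -> list[FaceKeypointFrame]:
    """Add Gaussian pixel jitter and independent per-keypoint dropout
    (confidence -> 0).  Reproducible under a fixed seed; a zero-noise
    perturbation is the identity."""
    if not (0.0 <= dropout_rate <= 1.0):
        raise ValidationError("dropout_rate must lie in [0, 1]")
    if jitter_px < 0:
        raise ValidationError("jitter_px must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if jitter_px == 0 and dropout_rate == 0:
        return list(frames)
    out = []
    names = ("nose", "left_eye", "right_eye", "left_ear", "right_ear")
    for frame in frames:
        updates = {}
        for name in names:
            kp: Keypoint = getattr(frame, name)
            x, y, c = kp.x, kp.y, kp.confidence
            if jitter_px > 0:
                dx, dy = rng.normal(0.0, jitter_px, 2)
                x, y = x + dx, y + dy
            if dropout_rate > 0 and rng.random() < dropout_rate:
                c = 0.0
            updates[name] = Keypoint(x, y, c)
        out.append(replace(frame, **updates))
    return out


@dataclass(frozen=True)
class Session:
    """One simulated consultation: keypoints, audio (or direct per-segment
    voice decisions), and the ground-truth timeline."""

    script: ScenarioScript
    frames: list[FaceKeypointFrame]
    audio: AudioBuffer | None
    voice_decisions: np.ndarray | None
    truth: InteractionTimeline
    fps: float
    segment_ms: float


def _segment_base_yaws(script: ScenarioScript, cfg: HeadModelConfig, rng: np.random.Generator) -> list[float]:
    yaws = []
    for state, _ in script.segments:
        if state in SCREEN_STATES:
            yaws.append(float(rng.normal(0.0, cfg.screen_yaw_sd_deg)))
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            yaws.append(sign * float(rng.normal(cfg.away_yaw_mean_deg, cfg.away_yaw_sd_deg)))
    return yaws


def _yaw_trajectory(
    script: ScenarioScript, cfg: HeadModelConfig, fps: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-frame yaw: piecewise-constant per segment with a linear ramp of
    ``yaw_ramp_seconds`` at each state change (heads sweep, they do not jump)."""
    n_frames = int(round(script.total_seconds * fps))
    times = np.arange(n_frames) / fps
    bases = _segment_base_yaws(script, cfg, rng)
    starts = np.cumsum([0.0] + [d for _, d in script.segments])  # segment start times
    yaw = np.empty(n_frames)
    seg_idx = np.searchsorted(starts[1:], times, side="right")
    for i, t in enumerate(times):
        k = int(seg_idx[i])
        y = bases[k]
        if k > 0 and cfg.yaw_ramp_seconds > 0:
            dt = t - starts[k]
            if dt < cfg.yaw_ramp_seconds:
                frac = dt / cfg.yaw_ramp_seconds
                y = bases[k - 1] + (bases[k] - bases[k - 1]) * frac
        yaw[i] = y
    return yaw


def _voice_mask(
    script: ScenarioScript,
    cfg: SpeechModelConfig,
    sample_rate: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean per-sample mask of voiced audio: bursts with turn-taking gaps
    inside dialogue states, silence (plus rare clicks) elsewhere."""
    n = int(round(script.total_seconds * sample_rate))
    mask = np.zeros(n, dtype=bool)
    mu = math.log(cfg.burst_median_s)
    for start, end, state in script.intervals():
        i0, i1 = int(round(start * sample_rate)), min(int(round(end * sample_rate)), n)
        if state in DIALOGUE_STATES:
            t = i0
            speaking = True  # dialogue states open mid-utterance
            while t < i1:
                if speaking:
                    dur = float(rng.lognormal(mu, cfg.burst_log_sd))
                    j = min(i1, t + max(1, int(round(dur * sample_rate))))
                    # word groups separated by intra-utterance micro-pauses
                    u, voiced = t, True
                    min_group = int(round(cfg.word_group_range_s[0] * sample_rate))
                    while u < j:
                        rng_range = cfg.word_group_range_s if voiced else cfg.micro_pause_range_s
                        d = float(rng.uniform(*rng_range))
                        v = min(j, u + max(1, int(round(d * sample_rate))))
                        # a pause is inserted only if a full word group still
                        # fits after it: a truncated group between a pause and
                        # the turn gap would cluster into a longer silence
                        if voiced or v + min_group > j:
                            mask[u:v] = True
                        u, voiced = v, not voiced
                else:
                    dur = float(rng.uniform(*cfg.turn_gap_range_s))
                    j = min(i1, t + max(1, int(round(dur * sample_rate))))
                t = j
                speaking = not speaking
        else:
            # rare stray clicks (door, keyboard), far shorter than half a window
            span = (i1 - i0) / sample_rate
            for _ in range(rng.poisson(cfg.click_rate_hz * span)):
                c0 = i0 + int(rng.integers(0, max(1, i1 - i0)))
                c1 = min(i1, c0 + int(round(cfg.click_duration_s * sample_rate)))
                mask[c0:c1] = True
    return mask


def _synthesize_audio(
    mask: np.ndarray, cfg: SpeechModelConfig, sample_rate: int, rng: np.random.Generator
) -> AudioBuffer:
    sigma_bg = 10.0 ** (cfg.noise_floor_dbfs / 20.0)
    sigma_voice = 10.0 ** ((cfg.noise_floor_dbfs + cfg.voiced_delta_db) / 20.0)
    samples = rng.normal(0.0, sigma_bg, mask.size)
    n_voiced = int(mask.sum())
    if n_voiced:
        samples[mask] += rng.normal(0.0, sigma_voice, n_voiced)
    np.clip(samples, -1.0, 1.0, out=samples)
    return AudioBuffer(samples, sample_rate=sample_rate)


def generate_session(
    script: ScenarioScript,
    head_cfg: HeadModelConfig | None = None,
    speech_cfg: SpeechModelConfig | None = None,
    *,
    fps: float = 30.0,
    sample_rate: int = 16000,
    window_seconds: float = 0.5,
    segment_ms: float = 5.0,
    audio: bool = True,
    rng: np.random.Generator | None = None,
) -> Session:
    """Render a scripted consultation into keypoints, audio and ground truth.

    With ``audio=False`` the waveform synthesis is skipped and per-segment
    voice decisions are emitted directly (the voiced-sample majority within
    each segment), which is much faster for tests.  Deterministic under a
    fixed script seed / generator.
    """
    head_cfg = head_cfg or HeadModelConfig.for_layout(script.layout)
    speech_cfg = speech_cfg or SpeechModelConfig()
    if script.total_seconds < window_seconds:
        raise ValidationError("script shorter than one window")
    if fps <= 0 or sample_rate <= 0:
        raise ValidationError("fps and sample_rate must be positive")
    rng = rng or np.random.default_rng(script.seed)

    truth = script_to_timeline(script, window_seconds)

    yaw = _yaw_trajectory(script, head_cfg, fps, rng)
    frames = [
        project_keypoints(float(y), head_cfg, timestamp=i / fps) for i, y in enumerate(yaw)
    ]
    if head_cfg.jitter_px > 0 or head_cfg.dropout_rate > 0:
        frames = perturb_stream(frames, head_cfg.jitter_px, head_cfg.dropout_rate, rng)

    if audio:
        mask = _voice_mask(script, speech_cfg, sample_rate, rng)
        buf = _synthesize_audio(mask, speech_cfg, sample_rate, rng)
        return Session(script, frames, buf, None, truth, fps, segment_ms)

    # decision-only mode: voiced majority per VAD segment on a coarse grid
    seg_rate = int(round(1000.0 / segment_ms))
    mask = _voice_mask(script, speech_cfg, seg_rate * 2, rng)
    n_seg = mask.size // 2
    decisions = mask[: n_seg * 2].reshape(n_seg, 2).mean(axis=1) > 0.5
    return Session(script, frames, None, decisions.astype(np.int64), truth, fps, segment_ms)


# Plausible dwell-time ranges (seconds) per interaction state, and layout-
# specific state mixes approximating observed consultation class shares
# (dialogue-dominated; screen-only and idle states brief and infrequent).
_DWELL_RANGE = {"SG+D": (3.0, 10.0), "D": (4.0, 12.0), "SG": (2.0, 5.0), "Other": (2.0, 4.0)}
_LAYOUT_MIX = {
    "semi-inclusive": {"SG+D": 0.36, "D": 0.56, "SG": 0.045, "Other": 0.035},
    "fully-inclusive": {"SG+D": 0.25, "D": 0.62, "SG": 0.085, "Other": 0.045},
}


def low_noise_head(layout: str) -> HeadModelConfig:
    """Head model for the exact-recovery regime: sub-pixel jitter, no
    dropout, tight yaw spread so every away-gaze segment sits well beyond
    the rule boundary."""
    return HeadModelConfig.for_layout(
        layout, jitter_px=0.5, dropout_rate=0.0, screen_yaw_sd_deg=5.0, away_yaw_sd_deg=5.0
    )


def low_noise_speech() -> SpeechModelConfig:
    """Speech model for the exact-recovery regime.

    Turn gaps are capped at 0.24 s: a silent stretch can flip a 0.5-s window
    only if it silences a strict majority of the window's 5-ms segments
    (>= 0.255 s), and a gap can contribute at most its own length plus two
    partially voiced boundary segments (< 0.01 s), so gaps up to 0.24 s can
    never flip a window.  Longer gaps probe the dialogue-to-Other confusion
    mode instead of recovery.
    """
    return SpeechModelConfig(turn_gap_range_s=(0.15, 0.23))


def sample_script(
    layout: str,
    seed: int = 0,
    total_seconds: float = 180.0,
    *,
    min_duration: float = 2.0,
) -> ScenarioScript:
    """Draw a realistic consultation script: alternating interaction states
    with layout-appropriate frequencies and dwell times of a few seconds,
    totalling ``total_seconds`` (about a 3-minute simulated consultation)."""
    if layout not in _LAYOUT_MIX:
        raise ValidationError(f"unknown layout: {layout!r}")
    rng = np.random.default_rng(seed)
    mix = _LAYOUT_MIX[layout]
    states = list(mix)
    segments: list[tuple[str, float]] = []
    t, prev = 0.0, None
    while t < total_seconds:
        weights = np.array([0.0 if s == prev else mix[s] for s in states])
        state = str(rng.choice(states, p=weights / weights.sum()))
        lo, hi = _DWELL_RANGE[state]
        dur = max(min_duration, float(rng.uniform(lo, hi)))
        dur = min(dur, total_seconds - t)
        if dur < min_duration:  # absorb a too-short tail into the last segment
            segments[-1] = (segments[-1][0], segments[-1][1] + dur)
            t = total_seconds
            break
        segments.append((state, dur))
        t += dur
        prev = state
    return ScenarioScript(tuple(segments), layout=layout, seed=seed)
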