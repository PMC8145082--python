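"""Readers and writers for the pipeline's on-disk formats.

* face-keypoint streams in the per-frame JSON dialect of body-pose
  estimators (one JSON object per frame, people as flat
  ``[x, y, confidence, ...]`` arrays indexed by a configurable keypoint
  index map), either as a directory of per-frame files or one JSON-lines
  file;
* mono WAV audio (PCM16 / PCM32 / float);
* interval label CSV (``start_s, end_s, label``) and windowed label CSV
  (``window_index, start_s, end_s, label``);
* JSON / CSV evaluation reports;
* the YAML run configuration.

All writes are deterministic byte-for-byte under a fixed configuration.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.io import wavfile

from .errors import ConfigurationError, ValidationError
from .evaluation import (
    ClassMetrics,
    ConfusionMatrix,
    TransitionErrorReport,
    TransitionRecord,
    round_half_away,
)
from .fusion import CLASSES, InteractionTimeline
from .gaze import FaceKeypointFrame, GazeRuleConfig, Keypoint, KEYPOINT_NAMES
from .vad import AudioBuffer, VadConfig
from .windowing import BinaryLabelSeries

__all__ = [
    "DEFAULT_INDEX_MAP",
    "RunConfig",
    "read_keypoint_stream",
    "write_keypoint_stream",
    "extract_person",
    "read_audio",
    "write_audio",
    "read_interval_labels",
    "write_interval_labels",
    "intervals_to_timeline",
    "write_windowed_series",
    "write_windowed_timeline",
    "read_windowed_series",
    "read_windowed_timeline",
    "write_report",
]

#: Default mapping of named facial keypoints to indices of the 25-point
#: body-model keypoint array emitted by common pose estimators.
DEFAULT_INDEX_MAP: dict[str, int] = {
    "nose": 0,
    "right_eye": 15,
    "left_eye": 16,
    "right_ear": 17,
    "left_ear": 18,
}


# ---------------------------------------------------------------------------
# keypoint streams

def _frame_from_flat(
    flat: Sequence[float], index_map: Mapping[str, int], timestamp: float, person_id: int
) -> FaceKeypointFrame:
    kps = {}
    for name in KEYPOINT_NAMES:
        idx = index_map[name]
        base = 3 * idx
        if base + 3 > len(flat):
            raise ValidationError(
                f"keypoint array too short for index map entry {name}={idx}"
            )
        kps[name] = Keypoint(float(flat[base]), float(flat[base + 1]), float(flat[base + 2]))
    return FaceKeypointFrame(timestamp=timestamp, person_id=person_id, **kps)


def _validate_index_map(index_map: Mapping[str, int]) -> Mapping[str, int]:
    missing = [n for n in KEYPOINT_NAMES if n not in index_map]
    if missing:
        raise ConfigurationError(f"keypoint index map is missing entries: {missing}")
    return index_map


def read_keypoint_stream(
    path: str | Path,
    index_map: Mapping[str, int] | None = None,
    fps: float = 30.0,
) -> list[dict[int, FaceKeypointFrame]]:
    """Read a keypoint stream: one record per frame, possibly several people.

    ``path`` is either a directory of per-frame ``*.json`` files (ordered by
    filename) or a single ``.jsonl`` file with one frame record per line.
    Each record holds ``{"people": [{"person_id": ..., "pose_keypoints_2d":
    [x, y, c, ...]}, ...]}``.  Frames with an empty people list yield an
    empty record.  Timestamps are ``frame_index / fps`` seconds.
    """
    index_map = _validate_index_map(index_map or DEFAULT_INDEX_MAP)
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.json"))
        if not files:
            raise ValidationError(f"no *.json frame files under {path}")
        raw = []
        for f in files:
            try:
                raw.append(json.loads(f.read_text()))
            except json.JSONDecodeError as exc:
                raise ValidationError(f"malformed JSON in {f.name}: {exc}") from exc
    else:
        raw = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    raw.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise ValidationError(
                        f"malformed JSON on line {lineno} of {path.name}: {exc}"
                    ) from exc

    records: list[dict[int, FaceKeypointFrame]] = []
    for i, rec in enumerate(raw):
        people = rec.get("people", [])
        frame_record: dict[int, FaceKeypointFrame] = {}
        for j, person in enumerate(people):
            pid = person.get("person_id", j)
            if isinstance(pid, list):  # some estimators emit [-1]
                pid = pid[0] if pid and pid[0] >= 0 else j
            flat = person.get("pose_keypoints_2d", [])
            frame_record[int(pid)] = _frame_from_flat(flat, index_map, i / fps, int(pid))
        records.append(frame_record)
    return records


def write_keypoint_stream(
    frames: Iterable[FaceKeypointFrame] | Iterable[Mapping[int, FaceKeypointFrame]],
    path: str | Path,
    index_map: Mapping[str, int] | None = None,
    n_points: int = 25,
) -> None:
    """Write frames (single-person) or records (multi-person) as JSON lines
    in the pose-estimator dialect that :func:`read_keypoint_stream` reads."""
    index_map = _validate_index_map(index_map or DEFAULT_INDEX_MAP)
    path = Path(path)
    with open(path, "w") as fh:
        for item in frames:
            record = item if isinstance(item, Mapping) else {item.person_id: item}
            people = []
            for pid in sorted(record):
                frame = record[pid]
                flat = [0.0] * (3 * n_points)
                for name in KEYPOINT_NAMES:
                    kp: Keypoint = getattr(frame, name)
                    base = 3 * index_map[name]
                    flat[base : base + 3] = [kp.x, kp.y, kp.confidence]
                people.append({"person_id": int(pid), "pose_keypoints_2d": flat})
            fh.write(json.dumps({"people": people}) + "\n")


def extract_person(
    records: Sequence[Mapping[int, FaceKeypointFrame]], person_id: int
) -> list[FaceKeypointFrame]:
    """Single-person frame stream for one person id; frames where the person
    is undetected become empty frames (all confidences zero), preserving the
    time base."""
    out = []
    for i, record in enumerate(records):
        if person_id in record:
            out.append(record[person_id])
        else:
            ts = next(iter(record.values())).timestamp if record else 0.0
            out.append(FaceKeypointFrame(timestamp=ts, person_id=person_id))
    return out


# ---------------------------------------------------------------------------
# audio

def read_audio(path: str | Path) -> AudioBuffer:
    """Read a mono WAV file (PCM16/PCM32 or float) into a normalised buffer."""
    rate, data = wavfile.read(path)
    if data.ndim > 1 and data.shape[1] > 1:
        raise ValidationError(
            f"{Path(path).name} has {data.shape[1]} channels; convert to mono first"
        )
    data = np.asarray(data).reshape(-1)
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        raise ValidationError(f"unsupported WAV sample format: {data.dtype}")
    return AudioBuffer(np.clip(samples, -1.0, 1.0), sample_rate=int(rate))


def write_audio(path: str | Path, audio: AudioBuffer) -> None:
    """Write a buffer as 16-bit PCM WAV."""
    pcm = np.clip(np.round(audio.samples * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, audio.sample_rate, pcm)


# ---------------------------------------------------------------------------
# interval labels and the window grid

def read_interval_labels(path: str | Path) -> list[tuple[float, float, str]]:
    """Read interval ground truth (CSV: start_s, end_s, label), validating
    that intervals are well-formed, ordered and non-overlapping."""
    intervals: list[tuple[float, float, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"start_s", "end_s", "label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(
                f"{Path(path).name}: expected columns start_s, end_s, label"
            )
        for row in reader:
            intervals.append((float(row["start_s"]), float(row["end_s"]), row["label"]))
    _validate_intervals(intervals, str(path))
    return intervals


def _validate_intervals(intervals: Sequence[tuple[float, float, str]], where: str) -> None:
    offenders = []
    for i, (s, e, _) in enumerate(intervals):
        if e <= s:
            offenders.append(f"row {i}: end {e} <= start {s}")
        if i and s < intervals[i - 1][1] - 1e-9:
            offenders.append(f"row {i}: starts at {s} before previous end {intervals[i - 1][1]}")
    if offenders:
        raise ValidationError(f"{where}: bad intervals: " + "; ".join(offenders))


def write_interval_labels(
    intervals: Sequence[tuple[float, float, str]], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start_s", "end_s", "label"])
        for s, e, lab in intervals:
            w.writerow([f"{s:g}", f"{e:g}", lab])


def intervals_to_timeline(
    intervals: Sequence[tuple[float, float, str]],
    window_seconds: float = 0.5,
    start_time: float = 0.0,
) -> InteractionTimeline:
    """Convert interval labels to the window grid by majority overlap.

    Each window takes the label covering the most of it; ties go to the
    earlier interval.  The trailing partial window is kept iff at least half
    a window of labelled time remains, matching the classifiers' rule.
    """
    _validate_intervals(intervals, "intervals")
    if not intervals:
        raise ValidationError("no intervals")
    span = intervals[-1][1] - start_time
    n_full = int(span // window_seconds)
    remainder = span - n_full * window_seconds
    n_windows = n_full + (1 if remainder >= window_seconds / 2 else 0)
    if n_windows == 0:
        raise ValidationError("intervals span less than half a window")

    labels = []
    for w in range(n_windows):
        w0 = start_time + w * window_seconds
        w1 = w0 + window_seconds
        best_label, best_overlap = None, -1.0
        for s, e, lab in intervals:
            if e <= w0 or s >= w1:
                continue
            overlap = min(e, w1) - max(s, w0)
            if overlap > best_overlap + 1e-12:  # strict: ties keep the earlier interval
                best_label, best_overlap = lab, overlap
        labels.append(best_label if best_label is not None else intervals[-1][2])
    return InteractionTimeline(tuple(labels), window_seconds=window_seconds, start_time=start_time)


# ---------------------------------------------------------------------------
# windowed label CSV

def _write_windowed(path: str | Path, bounds: np.ndarray, labels: Sequence) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["window_index", "start_s", "end_s", "label"])
        for i, ((s, e), lab) in enumerate(zip(bounds, labels)):
            w.writerow([i, f"{s:g}", f"{e:g}", lab])


def write_windowed_series(series: BinaryLabelSeries, path: str | Path) -> None:
    _write_windowed(path, series.window_bounds(), [int(x) for x in series.labels])


def write_windowed_timeline(timeline: InteractionTimeline, path: str | Path) -> None:
    _write_windowed(path, timeline.window_bounds(), timeline.labels)


def _read_windowed(path: str | Path) -> tuple[list[str], float, float]:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"window_index", "start_s", "end_s", "label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(
                f"{Path(path).name}: expected columns window_index, start_s, end_s, label"
            )
        for row in reader:
            rows.append(row)
    if not rows:
        raise ValidationError(f"{Path(path).name}: no windows")
    window = float(rows[0]["end_s"]) - float(rows[0]["start_s"])
    start = float(rows[0]["start_s"])
    return [r["label"] for r in rows], window, start


def read_windowed_series(path: str | Path, kind: str = "gaze") -> BinaryLabelSeries:
    labels, window, start = _read_windowed(path)
    return BinaryLabelSeries(
        np.array([int(l) for l in labels]), window_seconds=window, kind=kind, start_time=start
    )


def read_windowed_timeline(path: str | Path) -> InteractionTimeline:
    labels, window, start = _read_windowed(path)
    return InteractionTimeline(tuple(labels), window_seconds=window, start_time=start)


# ---------------------------------------------------------------------------
# reports

def _metrics_rows(metrics: ClassMetrics) -> list[dict[str, object]]:
    rows: list[dict[str, object]] = []
    for c in metrics.class_order:
        rows.append(
            {
                "class": c,
                "precision": round_half_away(metrics.precision[c], 2),
                "recall": round_half_away(metrics.recall[c], 2),
                "f1": round_half_away(metrics.f1[c], 2),
                "support": metrics.support[c],
            }
        )
    rows.append(
        {
            "class": "weighted",
            "precision": round_half_away(metrics.weighted_precision, 2),
            "recall": round_half_away(metrics.weighted_recall, 2),
            "f1": round_half_away(metrics.weighted_f1, 2),
            "support": metrics.total_support,
        }
    )
    return rows


def report_dict(
    metrics: ClassMetrics,
    cm: ConfusionMatrix | None = None,
    transitions: Mapping[tuple[str, str], int] | None = None,
    transition_errors: TransitionErrorReport | None = None,
) -> dict:
    """Assemble the evaluation report structure serialised by write_report."""
    out: dict = {
        "accuracy": round_half_away(metrics.accuracy, 2),
        "classes": _metrics_rows(metrics),
    }
    if cm is not None:
        out["confusion_matrix"] = {
            "class_order": list(cm.class_order),
            "counts": cm.counts.tolist(),
        }
    if transitions is not None:
        out["transitions"] = [
            {"from": f, "to": t, "count": n} for (f, t), n in sorted(transitions.items())
        ]
    if transition_errors is not None:
        out["transition_errors"] = {
            "total_errors": transition_errors.total_errors,
            "transition_errors": transition_errors.transition_errors,
            "percentage": transition_errors.percentage,
        }
    return out


def write_report(report: dict, path: str | Path, fmt: str = "json") -> None:
    """Serialise a report as JSON, or as a CSV mirror of the per-class table."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["class", "precision", "recall", "f1", "support"])
            for row in report.get("classes", []):
                w.writerow([row["class"], row["precision"], row["recall"], row["f1"], row["support"]])
            w.writerow([])
            w.writerow(["accuracy", report.get("accuracy", "")])
    else:
        raise ConfigurationError(f"unknown report format: {fmt!r}")


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Full pipeline configuration; defaults reproduce the reference
    settings (0.5-s windows, 5-ms VAD segments at the highest
    aggressiveness, gaze tolerance of half the inter-eye distance)."""

    window_seconds: float = 0.5
    fps: float = 30.0
    gaze: GazeRuleConfig = field(default_factory=GazeRuleConfig)
    vad: VadConfig = field(default_factory=VadConfig)
    index_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_INDEX_MAP))
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "window_seconds": self.window_seconds,
            "fps": self.fps,
            "gaze": dataclasses.asdict(self.gaze),
            "vad": dataclasses.asdict(self.vad),
            "index_map": dict(self.index_map),
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ConfigurationError(f"{Path(path).name}: not a mapping")
        try:
            return cls(
                window_seconds=float(payload.get("window_seconds", 0.5)),
                fps=float(payload.get("fps", 30.0)),
                gaze=GazeRuleConfig(**payload.get("gaze", {})),
                vad=VadConfig(**payload.get("vad", {})),
                index_map=_validate_index_map(
                    payload.get("index_map", dict(DEFAULT_INDEX_MAP))
                ),
                seed=int(payload.get("seed", 0)),
            )
        except TypeError as exc:
            raise ConfigurationError(f"bad run configuration: {exc}") from exc
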