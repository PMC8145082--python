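"""Scoring of predicted interaction timelines against ground truth.

Covers the full evaluation machinery for 4-class behavioural coding on the
0.5-second grid:

* confusion matrices (rows = ground truth, columns = prediction);
* per-class precision / recall / F1 with supports, overall accuracy, and
  support-weighted scores (weighted recall is identically the accuracy);
* two-sample t tests on per-video accuracies (pooled-variance Student by
  default, so ten videos per condition give the conventional 18 degrees of
  freedom; Welch available behind a flag);
* transition detection on categorical timelines, the >= 1.5-second
  flanking-run qualification filter, and attribution of prediction errors
  to transition timing shifts of 0.5-1 s.

A transition timing error is a misclassified window close to a ground-truth
class change whose predicted label matches the truth on the *other* side of
the change — i.e. the transition was marked early or late rather than the
behaviour being misread.  Such errors are usually harmless in practice and
are reported separately from substantive errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .fusion import CLASSES, InteractionTimeline

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "TransitionRecord",
    "TransitionErrorReport",
    "TtestResult",
    "confusion_matrix",
    "classification_report",
    "support_weighted",
    "accuracy_ttest",
    "find_transitions",
    "transition_table",
    "qualifying_transitions",
    "transition_error_analysis",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1, -0.5 -> -1).

    Python's builtin rounds half to even; reports here follow the
    round-half-away convention common in tabulated percentages.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)) * (
        -1.0 if x < 0 else 1.0
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    """4x4 contingency table over the interaction classes.

    ``counts[i, j]`` is the number of windows with true class
    ``class_order[i]`` predicted as ``class_order[j]``.
    """

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_order)
        if arr.shape != (k, k):
            raise ValidationError(f"confusion matrix must be {k}x{k}")
        if (arr < 0).any():
            raise ValidationError("confusion matrix counts must be nonnegative")
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        """Ground-truth windows per class (row sums)."""
        return self.counts.sum(axis=1)


def confusion_matrix(truth: InteractionTimeline, pred: InteractionTimeline) -> ConfusionMatrix:
    """Tally truth/prediction pairs window by window; never truncates."""
    _check_same_grid(truth, pred)
    k = len(CLASSES)
    t = truth.as_indices()
    p = pred.as_indices()
    counts = np.bincount(t * k + p, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts)


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class and support-weighted scores for one confusion matrix."""

    class_order: tuple[str, ...]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float

    @property
    def total_support(self) -> int:
        return sum(self.support.values())


def support_weighted(values: Sequence[float], supports: Sequence[float]) -> float:
    """Support-weighted average of per-class scores: sum(s_c * v_c) / sum(s_c)."""
    values = np.asarray(values, dtype=np.float64)
    supports = np.asarray(supports, dtype=np.float64)
    if values.shape != supports.shape or values.size == 0:
        raise ValidationError("values and supports must be equal-length and nonempty")
    total = supports.sum()
    if total <= 0:
        raise ValidationError("total support must be positive")
    return float((values * supports).sum() / total)


def classification_report(cm: ConfusionMatrix) -> ClassMetrics:
    """Precision, recall, F1 and support per class, plus accuracy and
    support-weighted scores.

    Zero-denominator conventions: a metric whose denominator is zero is 0
    (a class never predicted has precision 0; a class absent from the truth
    has recall 0; F1 is 0 when precision + recall is 0).
    """
    if cm.total == 0:
        raise ValidationError("cannot score an empty confusion matrix")
    counts = cm.counts.astype(np.float64)
    diag = np.diag(counts)
    colsum = counts.sum(axis=0)
    rowsum = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(colsum > 0, diag / np.where(colsum > 0, colsum, 1), 0.0)
        recall = np.where(rowsum > 0, diag / np.where(rowsum > 0, rowsum, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    accuracy = float(diag.sum() / cm.total)
    order = cm.class_order
    return ClassMetrics(
        class_order=order,
        precision={c: float(precision[i]) for i, c in enumerate(order)},
        recall={c: float(recall[i]) for i, c in enumerate(order)},
        f1={c: float(f1[i]) for i, c in enumerate(order)},
        support={c: int(rowsum[i]) for i, c in enumerate(order)},
        accuracy=accuracy,
        weighted_precision=support_weighted(precision, rowsum),
        weighted_recall=support_weighted(recall, rowsum),
        weighted_f1=support_weighted(f1, rowsum),
    )


class TtestResult(NamedTuple):
    statistic: float
    pvalue: float
    df: float


def accuracy_ttest(
    acc_a: Sequence[float], acc_b: Sequence[float], *, welch: bool = False
) -> TtestResult:
    """Two-sided two-sample t test on per-video accuracy lists.

    Pooled-variance Student t by default (df = n_a + n_b - 2); Welch with
    ``welch=True``.  Degenerate cases: two identical-mean lists with zero
    pooled variance give t = 0, p = 1; zero pooled variance with unequal
    means gives a signed infinite t and p = 0.
    """
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each accuracy list needs at least 2 values")
    df = (a.size + b.size - 2) if not welch else _welch_df(a, b)
    if not welch and np.ptp(a) == 0 and np.ptp(b) == 0:
        # constant lists: zero pooled variance
        if a[0] == b[0]:
            return TtestResult(0.0, 1.0, float(df))
        return TtestResult(math.copysign(math.inf, a[0] - b[0]), 0.0, float(df))
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TtestResult(float(res.statistic), float(res.pvalue), float(df))


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        return float(a.size + b.size - 2)
    return float((va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1)))


@dataclass(frozen=True)
class TransitionRecord:
    """One class change in a timeline.

    ``boundary_index`` is the window index where the new class starts;
    ``pre_run`` / ``post_run`` are the lengths (windows) of the uninterrupted
    runs of ``from_class`` before and ``to_class`` after the boundary.
    """

    boundary_index: int
    from_class: str
    to_class: str
    pre_run: int
    post_run: int


def find_transitions(timeline: InteractionTimeline) -> list[TransitionRecord]:
    """All class changes in the timeline, with flanking run lengths."""
    if len(timeline) == 0:
        raise ValidationError("empty timeline")
    labels = timeline.labels
    # run-length encode
    runs: list[tuple[str, int]] = []
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1] = (lab, runs[-1][1] + 1)
        else:
            runs.append((lab, 1))
    records: list[TransitionRecord] = []
    idx = 0
    for (c_from, n_from), (c_to, n_to) in zip(runs, runs[1:]):
        idx += n_from
        records.append(
            TransitionRecord(
                boundary_index=idx,
                from_class=c_from,
                to_class=c_to,
                pre_run=n_from,
                post_run=n_to,
            )
        )
    return records


def transition_table(records: Sequence[TransitionRecord]) -> dict[tuple[str, str], int]:
    """Frequency of each ordered (from, to) class pair."""
    table: dict[tuple[str, str], int] = {}
    for rec in records:
        key = (rec.from_class, rec.to_class)
        table[key] = table.get(key, 0) + 1
    return table


def qualifying_transitions(
    records: Sequence[TransitionRecord],
    timeline: InteractionTimeline,
    min_run_seconds: float = 1.5,
) -> list[TransitionRecord]:
    """Keep transitions preceded and followed by a continuous single class
    for at least ``min_run_seconds`` (3 windows at the 0.5-s default);
    the bound is inclusive."""
    min_windows = min_run_seconds / timeline.window_seconds
    if abs(min_windows - round(min_windows)) > 1e-9:
        raise ValidationError("min_run_seconds must be a multiple of window_seconds")
    k = int(round(min_windows))
    return [r for r in records if r.pre_run >= k and r.post_run >= k]


@dataclass(frozen=True)
class TransitionErrorReport:
    """Breakdown of prediction errors into transition-timing errors and the rest."""

    total_errors: int
    transition_errors: int

    def __post_init__(self) -> None:
        if not (0 <= self.transition_errors <= self.total_errors):
            raise ValidationError("transition_errors must lie in [0, total_errors]")

    @property
    def percentage(self) -> float:
        """Transition errors as a percentage of all errors, 1 decimal
        (0.0 when there are no errors at all)."""
        if self.total_errors == 0:
            return 0.0
        return round_half_away(100.0 * self.transition_errors / self.total_errors, 1)


def transition_error_analysis(
    truth: InteractionTimeline,
    pred: InteractionTimeline,
    *,
    min_run_seconds: float = 1.5,
    radius_windows: int = 2,
) -> TransitionErrorReport:
    """Count prediction errors attributable to transition timing shifts.

    An error window ``w`` is attributable to a timing shift of up to
    ``radius_windows`` windows (0.5-1 s at the defaults) of some qualifying
    ground-truth transition with boundary ``b`` iff the predicted label
    matches the truth on the other side of that boundary:

    * early marking: ``b - radius_windows <= w < b`` and the prediction
      already shows the post-transition class;
    * late marking: ``b <= w <= b + radius_windows - 1`` and the prediction
      still shows the pre-transition class

    so each boundary can absorb at most ``radius_windows`` early plus
    ``radius_windows`` late windows.
    """
    _check_same_grid(truth, pred)
    t, p = truth.labels, pred.labels
    error_windows = [w for w in range(len(t)) if t[w] != p[w]]
    qualifying = qualifying_transitions(find_transitions(truth), truth, min_run_seconds)
    n_attrib = 0
    for w in error_windows:
        for rec in qualifying:
            b = rec.boundary_index
            if b - radius_windows <= w < b and p[w] == rec.to_class:
                n_attrib += 1
                break
            if b <= w <= b + radius_windows - 1 and p[w] == rec.from_class:
                n_attrib += 1
                break
    return TransitionErrorReport(total_errors=len(error_windows), transition_errors=n_attrib)


def _check_same_grid(a: InteractionTimeline, b: InteractionTimeline) -> None:
    if len(a) != len(b):
        raise ValidationError(f"timeline length mismatch: {len(a)} vs {len(b)}")
    if a.window_seconds != b.window_seconds or a.start_time != b.start_time:
        raise ValidationError("timelines are on different window grids")
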