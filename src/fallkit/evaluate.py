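"""Detection metrics: frame counts, event matching, FP/h.

Sensitivity = 100*TP/(TP+FN), specificity = 100*TN/(TN+FP), accuracy =
100*(TP+TN)/total; a metric with a zero denominator is reported as None
(undefined), never as 0 or 100.  Per-sample classifier output is turned
into alarm events (minimum duration, gap merging) and matched greedily
one-to-one against ground-truth events within a time tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Event",
    "EventLog",
    "EvalReport",
    "frames_to_events",
    "match_events",
    "summarize",
    "per_adl_table",
    "fp_rate",
]


@dataclass(frozen=True)
class Event:
    start_s: float
    end_s: float
    adl_id: int | None = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _check_ordered(events: list[Event], what: str) -> None:
    for a, b in zip(events, events[1:]):
        if b.start_s < a.end_s:
            raise ValueError(f"{what} events overlap or are unordered: {a} / {b}")


@dataclass
class EventLog:
    """Detected and ground-truth events on one continuous timeline."""

    detected: list[Event]
    truth: list[Event]
    tol_s: float = 2.0

    def __post_init__(self) -> None:
        self.detected = sorted(self.detected, key=lambda e: e.start_s)
        self.truth = sorted(self.truth, key=lambda e: e.start_s)
        _check_ordered(self.detected, "detected")
        _check_ordered(self.truth, "truth")


@dataclass
class EvalReport:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    fp_per_hour: float | None = None
    per_adl: list[tuple[int, int, float]] = field(default_factory=list)  # (adl, errors, rate %)

    def __str__(self) -> str:  # human-readable summary
        def fmt(v):
            return "undefined" if v is None else f"{v:.2f}%"

        lines = [
            f"TP={self.tp} TN={self.tn} FP={self.fp} FN={self.fn}",
            f"sensitivity={fmt(self.sensitivity)} "
            f"specificity={fmt(self.specificity)} accuracy={fmt(self.accuracy)}",
        ]
        if self.fp_per_hour is not None:
            lines.append(f"false positives per hour: {self.fp_per_hour:.2f}")
        for adl, errors, rate in self.per_adl:
            lines.append(f"  ADL {adl:2d}: {errors} errors ({rate:.1f}%)")
        return "\n".join(lines)


def frames_to_events(
    labels: np.ndarray,
    fs: float,
    min_on_s: float = 0.05,
    merge_gap_s: float = 2.0,
    t0: float = 0.0,
) -> list[Event]:
    """Aggregate per-sample +/-1 labels into alarm events.

    Maximal runs of +1 lasting at least *min_on_s* become events; events
    whose gap is below *merge_gap_s* are merged.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    on = labels == 1
    edges = np.diff(on.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if on[0]:
        starts.insert(0, 0)
    if on[-1]:
        ends.append(len(on))
    runs = [
        (s, e) for s, e in zip(starts, ends) if (e - s) / fs >= min_on_s - 1e-12
    ]
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and (s - merged[-1][1]) / fs < merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [Event(t0 + s / fs, t0 + e / fs) for s, e in merged]


def match_events(log: EventLog, tol_s: float | None = None) -> tuple[int, int, int]:
    """Greedy one-to-one matching; returns (tp, fn, fp).

    A detected event matches a truth event when their intervals, each
    expanded by *tol_s*, overlap.  Unmatched truth events count as FN,
    unmatched detections as FP.
    """
    tol = log.tol_s if tol_s is None else tol_s
    used = [False] * len(log.detected)
    tp = 0
    for truth in log.truth:
        for i, det in enumerate(log.detected):
            if used[i]:
                continue
            if det.start_s - tol <= truth.end_s and truth.start_s - tol <= det.end_s:
                used[i] = True
                tp += 1
                break
    fn = len(log.truth) - tp
    fp = used.count(False)
    return tp, fn, fp


def summarize(
    tp: int,
    tn: int,
    fp: int,
    fn: int,
    duration_min: float | None = None,
    per_adl_errors: dict[int, tuple[int, int]] | None = None,
) -> EvalReport:
    """Percent metrics from raw counts.

    *per_adl_errors* maps adl_id -> (error count, class total); rates
    are percentages of the class total.
    """
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("no counts to summarize")
    report = EvalReport(tp=tp, tn=tn, fp=fp, fn=fn)
    if tp + fn > 0:
        report.sensitivity = 100.0 * tp / (tp + fn)
    if tn + fp > 0:
        report.specificity = 100.0 * tn / (tn + fp)
    report.accuracy = 100.0 * (tp + tn) / total
    if duration_min is not None:
        report.fp_per_hour = fp_rate(fp, duration_min)
    if per_adl_errors:
        report.per_adl = per_adl_table(per_adl_errors)
    return report


def per_adl_table(errors: dict[int, tuple[int, int]]) -> list[tuple[int, int, float]]:
    """(adl_id, error count, percent error rate) rows, sorted by id."""
    rows = []
    for adl_id in sorted(errors):
        n_err, n_total = errors[adl_id]
        if n_total <= 0:
            raise ValueError(f"ADL {adl_id}: non-positive class total {n_total}")
        rows.append((adl_id, n_err, 100.0 * n_err / n_total))
    return rows


def fp_rate(fp: int, duration_min: float) -> float:
    """False positives per hour of monitoring."""
    if duration_min <= 0:
        raise ValueError(f"duration must be positive, got {duration_min} min")
    return fp / (duration_min / 60.0)
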