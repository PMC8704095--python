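"""Evaluation harness: match detections to ground truth, report rates.

Drop events in the ground truth are the expected detections; a detection
matched to a drop within a spatial radius and time window is a true
positive, unmatched drops are false negatives, and unmatched detections
are false positives.  Sensitivity is TP / (TP + FN) in percent; the
false-positive rate is FP per monitored hour.  Rounding is half-up to
one decimal (sensitivity) and two decimals (rate), matching how such
field results are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "MatchResult",
    "EvalReport",
    "EvaluationError",
    "match_detections",
    "sensitivity",
    "fp_rate",
    "build_report",
]


class EvaluationError(ValueError):
    pass


@dataclass
class MatchResult:
    """Counts and matched pairs for one evaluation stratum."""

    tp: int
    fn: int
    fp: int
    matches: list[dict] = field(default_factory=list)


def _event_pos_time(event) -> tuple[float, float, float]:
    if hasattr(event, "centroid"):
        return float(event.centroid[0]), float(event.centroid[1]), float(event.timestamp)
    return float(event["row"]), float(event["col"]), float(event["timestamp"])


def match_detections(
    events: list,
    truth,
    radius_px: float = 5.0,
    time_window: float = 100.0,
) -> MatchResult:
    """Greedily match detections to ground-truth drop events.

    ``truth`` is a :class:`strikefinder.synth.GroundTruth` or a list of
    record dicts with keys ``type, time, row, col``.  Pairs within
    ``radius_px`` and ``time_window`` are matched nearest-first; each
    truth event is matched at most once.
    """
    if radius_px <= 0 or time_window <= 0:
        raise EvaluationError("radius and time window must be positive")
    records = truth.drops() if hasattr(truth, "drops") else [
        r for r in truth if r.get("type", "drop") == "drop"
    ]

    pairs = []
    for ei, ev in enumerate(events):
        er, ec, et = _event_pos_time(ev)
        for ti, rec in enumerate(records):
            dist = float(np.hypot(er - float(rec["row"]), ec - float(rec["col"])))
            dt = abs(et - float(rec["time"]))
            if dist <= radius_px and dt <= time_window:
                pairs.append((dist, dt, ei, ti))
    pairs.sort()

    used_events: set[int] = set()
    used_truth: set[int] = set()
    matches = []
    for dist, dt, ei, ti in pairs:
        if ei in used_events or ti in used_truth:
            continue
        used_events.add(ei)
        used_truth.add(ti)
        matches.append({"event": ei, "truth": ti, "distance_px": dist, "dt_s": dt})

    return MatchResult(
        tp=len(used_truth),
        fn=len(records) - len(used_truth),
        fp=len(events) - len(used_events),
        matches=matches,
    )


def sensitivity(tp: int, fn: int) -> float:
    """Detection sensitivity 100 * TP / (TP + FN), one decimal, half-up."""
    if tp + fn <= 0:
        raise EvaluationError("sensitivity undefined for tp + fn = 0")
    value = Decimal(100 * tp) / Decimal(tp + fn)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def fp_rate(fp: int, duration_hours: float) -> float:
    """False positives per monitored hour, two decimals, half-up."""
    if duration_hours <= 0:
        raise EvaluationError("duration must be positive")
    value = Decimal(fp) / Decimal(str(duration_hours))
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class EvalReport:
    """Per-stratum result table plus totals (last row, label ``all``)."""

    table: pd.DataFrame

    @property
    def totals(self) -> pd.Series:
        return self.table.iloc[-1]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_report(
    strata: list[tuple[str, MatchResult, float | None]],
    notes: dict[str, str] | None = None,
) -> EvalReport:
    """Build the per-stratum evaluation table with a totals row.

    Each stratum is (label, match result, duration in hours or None).
    Free-text annotations (e.g. false-positive causes) can be attached
    per label via ``notes``; they pass through as a column.
    """
    if not strata:
        raise EvaluationError("no strata")
    notes = notes or {}
    rows = []
    for label, mr, dur in strata:
        rows.append({
            "label": label,
            "duration_h": dur,
            "tp": mr.tp,
            "fn": mr.fn,
            "fp": mr.fp,
            "sensitivity_pct": sensitivity(mr.tp, mr.fn) if mr.tp + mr.fn > 0 else np.nan,
            "fp_per_hour": fp_rate(mr.fp, dur) if dur else np.nan,
            "notes": notes.get(label, ""),
        })
    tp = sum(r["tp"] for r in rows)
    fn = sum(r["fn"] for r in rows)
    fp = sum(r["fp"] for r in rows)
    durations = [r["duration_h"] for r in rows if r["duration_h"]]
    total_dur = float(sum(durations)) if durations else None
    rows.append({
        "label": "all",
        "duration_h": total_dur,
        "tp": tp,
        "fn": fn,
        "fp": fp,
        "sensitivity_pct": sensitivity(tp, fn) if tp + fn > 0 else np.nan,
        "fp_per_hour": fp_rate(fp, total_dur) if total_dur else np.nan,
        "notes": notes.get("all", ""),
    })
    return EvalReport(table=pd.DataFrame(rows))
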