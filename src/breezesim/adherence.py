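"""Align a detected breathing-phase stream with the protocol schedule.

The breathing detector emits timestamped phase intervals (inhale / exhale /
pause / none).  Adherence is scored by same-label overlap between detected
events and each protocol interval: an interval is "fully correct" when the
matching-label coverage reaches ``full_threshold`` of its duration, and
fractionally correct otherwise.  Only inhalations and exhalations drive
biofeedback; pause intervals are scored for reporting only.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .protocol import Phase, PhaseInterval, ProtocolSchedule

__all__ = [
    "BreathEvent",
    "BreathStream",
    "PhaseCorrectness",
    "AdherenceSummary",
    "MalformedStreamError",
    "classify_adherence",
    "adherence_summary",
    "FULL_THRESHOLD",
]

#: Fraction of a phase that must be covered by a matching detection to count
#: as a correct *entire* phase.  Detector latency makes exact 1.0 unattainable.
FULL_THRESHOLD = 0.9


class MalformedStreamError(ValueError):
    """Raised for unsorted or overlapping events in a breath stream."""


@dataclass(frozen=True)
class BreathEvent:
    """One detected phase span ``[start_s, end_s)``."""

    start_s: float
    end_s: float
    label: Phase

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"empty event [{self.start_s}, {self.end_s})")


@dataclass(frozen=True)
class BreathStream:
    """Ordered, non-overlapping detected events; gaps are implicit NONE."""

    events: tuple[BreathEvent, ...]
    origin: str = ""

    def __post_init__(self) -> None:
        prev_end = -float("inf")
        for ev in self.events:
            if ev.start_s < prev_end - 1e-9:
                raise MalformedStreamError(
                    f"event starting at {ev.start_s} overlaps the previous "
                    f"event ending at {prev_end}"
                )
            prev_end = max(prev_end, ev.end_s)

    def __len__(self) -> int:
        return len(self.events)

    def label_at(self, t: float) -> Phase:
        """Detected label at time ``t`` (NONE inside gaps or outside events)."""
        i = bisect.bisect_right(self.events, t, key=lambda ev: ev.start_s) - 1
        if i >= 0 and self.events[i].start_s <= t < self.events[i].end_s:
            return self.events[i].label
        return Phase.NONE

    def labels_at(self, times: "np.ndarray") -> list[Phase]:
        """Vectorized :meth:`label_at` over an array of timestamps."""
        if not self.events:
            return [Phase.NONE] * len(times)
        starts = np.array([ev.start_s for ev in self.events])
        ends = np.array([ev.end_s for ev in self.events])
        labels = [ev.label for ev in self.events]
        idx = np.searchsorted(starts, times, side="right") - 1
        out: list[Phase] = []
        for t, i in zip(times, idx):
            if i >= 0 and t < ends[i]:
                out.append(labels[i])
            else:
                out.append(Phase.NONE)
        return out


@dataclass(frozen=True)
class PhaseCorrectness:
    """Same-label overlap of the detected stream with one protocol interval."""

    interval: PhaseInterval
    correct_overlap_s: float
    coverage: float
    full: bool


@dataclass(frozen=True)
class AdherenceSummary:
    """Session-level adherence aggregates, all fractions in [0, 1]."""

    mean_coverage_by_phase: dict[Phase, float] = field(default_factory=dict)
    full_inhale_fraction: float = 0.0
    full_exhale_fraction: float = 0.0
    overall_correct_fraction: float = 0.0


def classify_adherence(
    stream: BreathStream,
    schedule: ProtocolSchedule,
    full_threshold: float = FULL_THRESHOLD,
) -> list[PhaseCorrectness]:
    """Score every protocol interval by matching-label overlap.

    The stream and schedule must share the session time origin (t = 0).
    Overlap with a differently-labelled event contributes nothing; gaps count
    as NONE and earn no credit.
    """
    records: list[PhaseCorrectness] = []
    events = stream.events  # BreathStream validates ordering on construction
    for iv in schedule.intervals:
        overlap = 0.0
        for ev in events:
            if ev.end_s <= iv.start_s:
                continue
            if ev.start_s >= iv.end_s:
                break
            if ev.label is iv.phase:
                overlap += min(ev.end_s, iv.end_s) - max(ev.start_s, iv.start_s)
        cov = overlap / iv.duration_s
        cov = min(cov, 1.0)
        records.append(
            PhaseCorrectness(
                interval=iv,
                correct_overlap_s=overlap,
                coverage=cov,
                full=cov >= full_threshold,
            )
        )
    return records


def adherence_summary(records: list[PhaseCorrectness]) -> AdherenceSummary:
    """Aggregate per-interval correctness into session-level fractions."""
    if not records:
        raise ValueError("cannot summarize an empty correctness record list")
    by_phase: dict[Phase, list[PhaseCorrectness]] = {}
    for rec in records:
        by_phase.setdefault(rec.interval.phase, []).append(rec)
    mean_cov = {
        phase: sum(r.coverage for r in recs) / len(recs)
        for phase, recs in by_phase.items()
    }

    def _full_fraction(phase: Phase) -> float:
        recs = by_phase.get(phase, [])
        if not recs:
            return 0.0
        return sum(r.full for r in recs) / len(recs)

    total = sum(r.interval.duration_s for r in records)
    correct = sum(r.correct_overlap_s for r in records)
    return AdherenceSummary(
        mean_coverage_by_phase=mean_cov,
        full_inhale_fraction=_full_fraction(Phase.INHALE),
        full_exhale_fraction=_full_fraction(Phase.EXHALE),
        overall_correct_fraction=correct / total if total > 0 else 0.0,
    )
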