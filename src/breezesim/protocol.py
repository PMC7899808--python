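"""Paced-breathing protocol: the phase pattern and its per-session schedule.

A breathing pattern is a fixed inhale / exhale / pause triple in seconds
(default 4-2-4, i.e. a 10-s cycle and a paced rate of 6 cycles/min).  A
session schedule tiles the paced duration (default 6 min) with repeating
half-open phase intervals, starting with an inhalation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "Phase",
    "BreathingPattern",
    "PhaseInterval",
    "ProtocolSchedule",
    "build_schedule",
    "phase_at",
    "pattern_bpm",
]


class Phase(str, Enum):
    """A breathing phase label.

    ``NONE`` marks spans where no breathing activity was detected; it never
    appears in a protocol schedule, only in detected streams.
    """

    INHALE = "inhale"
    EXHALE = "exhale"
    PAUSE = "pause"
    NONE = "none"


#: Phases that make up one protocol cycle, in order.
CYCLE_PHASES = (Phase.INHALE, Phase.EXHALE, Phase.PAUSE)


class InvalidPatternError(ValueError):
    """Raised when a breathing pattern has non-positive inhale/exhale durations."""


@dataclass(frozen=True)
class BreathingPattern:
    """Inhale-exhale-pause durations in seconds; defaults pace 6 cycles/min."""

    inhale_s: float = 4.0
    exhale_s: float = 2.0
    pause_s: float = 4.0

    def __post_init__(self) -> None:
        if not (self.inhale_s > 0 and self.exhale_s > 0):
            raise InvalidPatternError(
                f"inhale_s and exhale_s must be positive, got "
                f"({self.inhale_s}, {self.exhale_s})"
            )
        if self.pause_s < 0:
            raise InvalidPatternError(f"pause_s must be >= 0, got {self.pause_s}")

    @property
    def cycle_s(self) -> float:
        """Length of one full cycle in seconds."""
        return self.inhale_s + self.exhale_s + self.pause_s

    @property
    def phase_durations(self) -> tuple[tuple[Phase, float], ...]:
        return (
            (Phase.INHALE, self.inhale_s),
            (Phase.EXHALE, self.exhale_s),
            (Phase.PAUSE, self.pause_s),
        )


@dataclass(frozen=True)
class PhaseInterval:
    """One half-open [start_s, end_s) span of a single protocol phase."""

    start_s: float
    end_s: float
    phase: Phase
    cycle_index: int

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"empty interval [{self.start_s}, {self.end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class ProtocolSchedule:
    """Contiguous phase intervals exactly tiling ``[0, duration_s)``."""

    pattern: BreathingPattern
    duration_s: float
    intervals: tuple[PhaseInterval, ...] = field(repr=False)

    def __len__(self) -> int:
        return len(self.intervals)


def build_schedule(pattern: BreathingPattern, duration_s: float) -> ProtocolSchedule:
    """Expand a breathing pattern into a session schedule.

    Repeats inhale -> exhale -> pause from t = 0 until ``duration_s``; a
    trailing partial cycle is truncated so the schedule covers the session
    duration exactly.

    Parameters
    ----------
    pattern
        The paced breathing pattern (inhale and exhale must be positive).
    duration_s
        Total paced duration in seconds (>= 0).
    """
    if duration_s < 0:
        raise ValueError(f"duration_s must be >= 0, got {duration_s}")
    intervals: list[PhaseInterval] = []
    cycle = 0
    t = 0.0
    while t < duration_s and not math.isclose(t, duration_s, abs_tol=1e-12):
        cycle_start = cycle * pattern.cycle_s
        offset = 0.0
        for phase, dur in pattern.phase_durations:
            if dur <= 0:  # zero-length pause produces no interval
                continue
            start = cycle_start + offset
            end = min(cycle_start + offset + dur, duration_s)
            if end > start:
                intervals.append(PhaseInterval(start, end, phase, cycle))
            offset += dur
        cycle += 1
        t = cycle * pattern.cycle_s
    return ProtocolSchedule(pattern=pattern, duration_s=duration_s,
                            intervals=tuple(intervals))


def phase_at(schedule: ProtocolSchedule, t: float) -> Phase:
    """Phase of the unique schedule interval containing time ``t``.

    Intervals are half-open, so a timestamp on a boundary belongs to the
    later phase.  Computed by cycle arithmetic rather than interval search.
    """
    if not 0.0 <= t < schedule.duration_s:
        raise ValueError(
            f"t={t} outside the scheduled session [0, {schedule.duration_s})"
        )
    pat = schedule.pattern
    within = t - math.floor(t / pat.cycle_s) * pat.cycle_s
    for phase, dur in pat.phase_durations:
        if within < dur:
            return phase
        within -= dur
    # floating roundoff can leave `within` a hair past the pause end
    return Phase.PAUSE if pat.pause_s > 0 else Phase.EXHALE


def pattern_bpm(pattern: BreathingPattern) -> float:
    """Paced breathing rate in full cycles per minute (60 / cycle length)."""
    return 60.0 / pattern.cycle_s
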