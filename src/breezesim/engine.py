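"""Deterministic biofeedback game dynamics: wind, earned acceleration, speed.

The session is a time-stepped state machine driven by the protocol phase and
by whether the detected breathing matches it at each step:

* correct inhalation fills an "earned acceleration" potential (capped at
  ``e_max``) and strengthens the wind;
* during inhalation and pause the boat's speed always decays slowly (floored
  at ``v_min``);
* every exhalation grants a basic acceleration; a *correct* exhalation adds a
  bonus that scales from ``a_small`` (nothing earned) up to ``a_max_earned``
  (potential full) — the preceding inhalation determines the strength;
* the earned potential is spent on one exhalation phase and resets when that
  phase ends;
* distance integrates speed and is the session score; milestones map it onto
  the environment progression (snowy -> grassy -> beach -> open sea).

Wind strength is tracked as an output channel for a renderer; it does not
feed back into the dynamics.  The whole trajectory is a pure function of
(stream, schedule, config).
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

from .adherence import AdherenceSummary, BreathStream, adherence_summary, classify_adherence
from .protocol import Phase, ProtocolSchedule, phase_at

__all__ = [
    "EngineConfig",
    "EngineState",
    "SessionResult",
    "Environment",
    "DEFAULT_MILESTONES",
    "step_engine",
    "run_session",
    "environment_at",
]


class Environment(str, Enum):
    """Landscape stages passed as the distance score grows."""

    SNOWY = "snowy"
    GRASSY = "grassy"
    BEACH = "beach"
    OPEN_SEA = "open_sea"


_ENV_ORDER = (Environment.SNOWY, Environment.GRASSY, Environment.BEACH,
              Environment.OPEN_SEA)

#: Distance thresholds for GRASSY / BEACH / OPEN_SEA, frozen at 25% / 60% /
#: 85% of the distance a perfectly adherent default 6-min session achieves.
DEFAULT_MILESTONES: tuple[float, float, float] = (1872.2, 4493.4, 6365.6)


@dataclass(frozen=True)
class EngineConfig:
    """Dynamics parameters in normalized distance units.

    ``r_earn`` defaults so that one full correct 4-s inhalation exactly fills
    the earned-potential cap ``e_max``.
    """

    dt_s: float = 0.05
    countdown_s: float = 3.0
    v_base: float = 1.0
    v_min: float = 0.2
    k_dec: float = 0.05
    a_basic: float = 0.15
    a_small: float = 0.05
    a_max_earned: float = 0.6
    r_earn: float = 0.25
    e_max: float = 1.0
    w0: float = 0.3
    w_gain: float = 0.5
    w_decay: float = 0.3
    milestones: tuple[float, float, float] = DEFAULT_MILESTONES

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.v_min < 0:
            raise ValueError("v_min must be >= 0")
        for name in ("a_basic", "a_small", "a_max_earned", "r_earn", "e_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.a_small > self.a_max_earned:
            raise ValueError("a_small must not exceed a_max_earned")
        if list(self.milestones) != sorted(self.milestones) or len(
            set(self.milestones)
        ) != len(self.milestones):
            raise ValueError("milestones must be strictly increasing")


@dataclass(frozen=True)
class EngineState:
    t_s: float = 0.0
    wind: float = 0.3
    earned: float = 0.0
    speed: float = 1.0
    distance: float = 0.0


@dataclass(frozen=True)
class SessionResult:
    """Final score, sampled trajectory and adherence report for one session."""

    distance: float
    trace: pd.DataFrame = field(repr=False)
    adherence: AdherenceSummary | None
    environment_reached: Environment


def _check_finite(state: EngineState) -> None:
    for name in ("t_s", "wind", "earned", "speed", "distance"):
        if not math.isfinite(getattr(state, name)):
            raise ValueError(f"corrupt engine state: {name} is not finite")


def step_engine(
    state: EngineState,
    protocol_phase: Phase,
    user_correct: bool,
    config: EngineConfig,
) -> EngineState:
    """Advance the dynamics by one ``dt_s`` step.

    The earned-potential reset at the *end* of an exhalation phase is a
    transition event and is handled by the session loop, not here.
    """
    _check_finite(state)
    dt = config.dt_s
    wind, earned, speed = state.wind, state.earned, state.speed

    if protocol_phase is Phase.INHALE and user_correct:
        earned = min(config.e_max, earned + config.r_earn * dt)

    if protocol_phase in (Phase.INHALE, Phase.PAUSE):
        speed = max(config.v_min, speed - config.k_dec * dt)
    elif protocol_phase is Phase.EXHALE:
        speed += config.a_basic * dt
        if user_correct:
            frac = earned / config.e_max if config.e_max > 0 else 0.0
            bonus = config.a_small + (config.a_max_earned - config.a_small) * frac
            speed += bonus * dt

    correct_breathing = user_correct and protocol_phase in (Phase.INHALE, Phase.EXHALE)
    if correct_breathing:
        wind += config.w_gain * dt
    else:
        wind += (config.w0 - wind) * min(1.0, config.w_decay * dt)
    wind = max(0.0, wind)

    return EngineState(
        t_s=state.t_s + dt,
        wind=wind,
        earned=earned,
        speed=speed,
        distance=state.distance + speed * dt,
    )


def environment_at(
    distance: float,
    milestones: tuple[float, ...] = DEFAULT_MILESTONES,
) -> Environment:
    """Environment reached at a given distance; a threshold belongs to the
    later stage (half-open convention)."""
    if distance < 0:
        raise ValueError(f"distance must be >= 0, got {distance}")
    return _ENV_ORDER[bisect.bisect_right(list(milestones), distance)]


def run_session(
    stream: BreathStream,
    schedule: ProtocolSchedule,
    config: EngineConfig | None = None,
) -> SessionResult:
    """Run one full paced session and return its score and trajectory.

    The boat launches at ``v_base`` when the paced protocol starts (the
    pre-protocol countdown contributes no distance).  Each step evaluates
    correctness instantaneously: the detected label at the step midpoint must
    equal the protocol phase.  Full-phase correctness is kept for the
    adherence report only.
    """
    config = config or EngineConfig()
    if stream.events and schedule.duration_s > 0:
        last_end = stream.events[-1].end_s
        if last_end > schedule.duration_s + 1.0:
            raise ValueError(
                f"stream events end at {last_end:.2f} s, well past the "
                f"scheduled duration {schedule.duration_s:.2f} s — "
                "mismatched time origins?"
            )

    n_steps = int(round(schedule.duration_s / config.dt_s))
    if n_steps == 0:
        trace = pd.DataFrame(
            columns=["t_s", "phase", "user_correct", "wind", "earned",
                     "speed", "distance"]
        )
        return SessionResult(
            distance=0.0, trace=trace, adherence=None,
            environment_reached=Environment.SNOWY,
        )

    state = EngineState(t_s=0.0, wind=config.w0, earned=0.0,
                        speed=config.v_base, distance=0.0)
    rows = np.empty((n_steps, 5))
    phases: list[str] = []
    corrects = np.empty(n_steps, dtype=bool)

    midpoints = (np.arange(n_steps) + 0.5) * config.dt_s
    midpoints = np.minimum(midpoints, schedule.duration_s * (1 - 1e-12))
    step_phases = [phase_at(schedule, tm) for tm in midpoints]
    user_labels = stream.labels_at(midpoints)

    prev_phase: Phase | None = None
    for i in range(n_steps):
        phase = step_phases[i]
        if prev_phase is Phase.EXHALE and phase is not Phase.EXHALE:
            state = replace(state, earned=0.0)
        correct = user_labels[i] is phase
        state = step_engine(state, phase, correct, config)
        phases.append(phase.value)
        corrects[i] = correct
        rows[i] = (state.t_s, state.wind, state.earned, state.speed,
                   state.distance)
        prev_phase = phase

    trace = pd.DataFrame(
        {
            "t_s": rows[:, 0],
            "phase": phases,
            "user_correct": corrects,
            "wind": rows[:, 1],
            "earned": rows[:, 2],
            "speed": rows[:, 3],
            "distance": rows[:, 4],
        }
    )
    records = classify_adherence(stream, schedule)
    summary = adherence_summary(records) if records else None
    return SessionResult(
        distance=state.distance,
        trace=trace,
        adherence=summary,
        environment_reached=environment_at(state.distance, config.milestones),
    )
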