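"""One biofeedback session: protocol schedule, engine dynamics, distance score.

Builds the default 4-2-4 paced schedule (6 cycles/min, 6 minutes), runs the
boat engine against a perfectly adherent breath stream and against a sloppy
one (every other cycle followed), and prints the resulting distance scores
and environment milestones.
"""

from breezesim import (
    BreathEvent,
    BreathStream,
    BreathingPattern,
    build_schedule,
    pattern_bpm,
    run_session,
)

pattern = BreathingPattern()  # 4 s inhale, 2 s exhale, 4 s pause
schedule = build_schedule(pattern, 360.0)
print(f"pattern paces {pattern_bpm(pattern):.0f} cycles/min, "
      f"{len(schedule.intervals)} phase intervals over 6 min")

perfect = BreathStream(
    tuple(BreathEvent(iv.start_s, iv.end_s, iv.phase)
          for iv in schedule.intervals)
)
sloppy = BreathStream(
    tuple(BreathEvent(iv.start_s, iv.end_s, iv.phase)
          for iv in schedule.intervals if iv.cycle_index % 2 == 0)
)

for name, stream in [("perfect", perfect), ("every-other-cycle", sloppy),
                     ("absent", BreathStream(()))]:
    result = run_session(stream, schedule)
    frac = (result.adherence.overall_correct_fraction
            if result.adherence else 0.0)
    print(f"{name:>18}: distance {result.distance:8.1f}  "
          f"environment {result.environment_reached.value:8s}  "
          f"correct fraction {frac:.2f}")

# The distance score rewards adherence: correct inhalations charge an
# acceleration potential that correct exhalations spend, while speed decays
# whenever the pacer is not in an exhalation phase.
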