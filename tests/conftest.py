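import pytest

from breezesim import (
    BreathEvent,
    BreathStream,
    BreathingPattern,
    build_schedule,
)


@pytest.fixture(scope="session")
def pattern():
    return BreathingPattern()  # 4-2-4


@pytest.fixture(scope="session")
def schedule(pattern):
    """Default 6-min paced session."""
    return build_schedule(pattern, 360.0)


@pytest.fixture(scope="session")
def perfect_stream(schedule):
    """Detected stream identical to the protocol itself."""
    return BreathStream(
        tuple(
            BreathEvent(iv.start_s, iv.end_s, iv.phase)
            for iv in schedule.intervals
        ),
        origin="perfect",
    )


@pytest.fixture(scope="session")
def empty_stream():
    return BreathStream(())
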