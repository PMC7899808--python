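"""Synthetic users and physiology for end-to-end testing of the pipeline.

Three generators build on each other:

1. breathing-phase streams — per protocol cycle a simulated subject either
   reproduces the paced phases (with an onset latency) or breathes freely at
   their spontaneous rate;
2. respiratory waveforms — raised-cosine segments rising over inhalations and
   falling over exhalations, flat elsewhere, so the 4-s/2-s inhale/exhale
   asymmetry of the paced pattern is preserved;
3. R-R interval series — an integral pulse frequency modulation (IPFM) model:
   the instantaneous heart rate is the subject's mean rate modulated by the
   normalized respiration (respiratory sinus arrhythmia) plus autoregressive
   broadband jitter, and a beat fires each time the running integral of the
   rate crosses an integer.

``simulate_study`` assembles a full within-subject study: per subject a
spontaneous-breathing baseline and two paced conditions (a plain visual pacer,
CIRCLE, and the gameful variant, BREEZE), in randomized training order.  RSA
depth is larger in the paced conditions than at baseline and equal between
the two paced conditions, so in the generative truth paced breathing raises
HRV while the two trainings are physiologically equivalent.  All generators
are pure functions of (inputs, seed), with per-recording seeds derived
hierarchically from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .adherence import BreathEvent, BreathStream
from .protocol import BreathingPattern, Phase, ProtocolSchedule, build_schedule

__all__ = [
    "SubjectProfile",
    "RespSeries",
    "RRSeries",
    "StudyDesign",
    "Recording",
    "SubjectData",
    "StudyDataset",
    "CONDITIONS",
    "generate_breath_stream",
    "generate_free_breathing",
    "generate_resp_signal",
    "simulate_rr",
    "simulate_study",
    "default_profiles",
]

#: Study condition labels: spontaneous baseline, standard paced training
#: (a breathing-guide circle), and the gameful paced training (the sailboat).
CONDITIONS = ("BASELINE", "CIRCLE", "BREEZE")


class InvalidProfileError(ValueError):
    """Raised when a subject profile cannot drive the generators."""


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters for one simulated subject.

    Parameters
    ----------
    adherence_prob
        Probability that a paced cycle is followed correctly.
    latency_s
        Onset delay of correctly followed phases (detector + reaction lag).
    natural_bpm
        Spontaneous breathing rate, used at baseline and in non-adherent spans.
    hr_base
        Mean heart rate in beats/min.
    rsa_gain_by_condition
        RSA modulation depth per condition, as a dimensionless fraction of the
        mean heart rate.  Paced slow breathing deepens RSA, hence the paced
        defaults exceed the baseline default; CIRCLE and BREEZE are equal so
        the two trainings are physiologically equivalent by construction.
    rr_noise_ms
        Scale of broadband beat-to-beat jitter, in ms.
    ara_volts
        Respiratory peak-to-trough amplitude (abdominal belt, volts).
    """

    subject_id: str = ""
    adherence_prob: float = 0.9
    latency_s: float = 0.3
    natural_bpm: float = 12.0
    hr_base: float = 72.0
    rsa_gain_by_condition: dict[str, float] = field(
        default_factory=lambda: {"BASELINE": 0.05, "CIRCLE": 0.12, "BREEZE": 0.12}
    )
    rr_noise_ms: float = 25.0
    ara_volts: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.adherence_prob <= 1.0:
            raise InvalidProfileError("adherence_prob must be in [0, 1]")
        if self.hr_base <= 0 or self.natural_bpm <= 0:
            raise InvalidProfileError("hr_base and natural_bpm must be positive")
        if self.rr_noise_ms < 0 or self.ara_volts < 0 or self.latency_s < 0:
            raise InvalidProfileError(
                "latency_s, rr_noise_ms and ara_volts must be >= 0"
            )
        for cond, g in self.rsa_gain_by_condition.items():
            if g < 0:
                raise InvalidProfileError(f"rsa_gain for {cond} must be >= 0")


@dataclass(frozen=True)
class RespSeries:
    """Uniformly sampled respiratory waveform (volts)."""

    fs_hz: float
    samples: np.ndarray = field(repr=False)
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("respiratory samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.samples)) / self.fs_hz

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz


@dataclass(frozen=True)
class RRSeries:
    """Successive inter-beat intervals in milliseconds."""

    rr_ms: np.ndarray = field(repr=False)
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.rr_ms, dtype=float)
        if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr <= 0)):
            raise ValueError("all R-R intervals must be positive and finite")

    def __len__(self) -> int:
        return len(self.rr_ms)

    @property
    def beat_times_s(self) -> np.ndarray:
        """Beat timestamps (seconds), taking t0 as the first beat."""
        return self.t0_s + np.concatenate(([0.0], np.cumsum(self.rr_ms) / 1000.0))


def _free_breathing_events(
    start_s: float, end_s: float, natural_bpm: float, rng: np.random.Generator
) -> list[BreathEvent]:
    """Fill [start, end) with spontaneous cycles at roughly natural_bpm.

    Cycle lengths are jittered by ~3% and split into inhale/exhale/pause in
    the 4:2:4 proportion of a relaxed breath.
    """
    events: list[BreathEvent] = []
    t = start_s
    base_cycle = 60.0 / natural_bpm
    while t < end_s - 1e-9:
        cycle = base_cycle * max(0.5, 1.0 + 0.03 * rng.standard_normal())
        for phase, frac in ((Phase.INHALE, 0.4), (Phase.EXHALE, 0.2),
                            (Phase.PAUSE, 0.4)):
            a, b = t, min(t + cycle * frac, end_s)
            if b > a + 1e-9:
                events.append(BreathEvent(a, b, phase))
            t += cycle * frac
            if t >= end_s:
                break
    return events


def generate_free_breathing(
    duration_s: float, natural_bpm: float, seed: int
) -> BreathStream:
    """Spontaneous breathing at ``natural_bpm`` for a whole recording."""
    rng = np.random.default_rng(seed)
    events = _free_breathing_events(0.0, duration_s, natural_bpm, rng)
    return BreathStream(tuple(events), origin=f"free@{natural_bpm:g}bpm")


def generate_breath_stream(
    profile: SubjectProfile, schedule: ProtocolSchedule, seed: int
) -> BreathStream:
    """Simulate the detector output of a subject following the protocol.

    Per cycle, with probability ``adherence_prob`` the subject reproduces the
    cycle's phases shifted by ``latency_s``; otherwise the cycle span is
    filled with free breathing at ``natural_bpm``.
    """
    if profile.latency_s >= schedule.pattern.cycle_s:
        raise InvalidProfileError(
            f"latency_s={profile.latency_s} must be shorter than the "
            f"{schedule.pattern.cycle_s}-s protocol cycle"
        )
    rng = np.random.default_rng(seed)
    events: list[BreathEvent] = []
    by_cycle: dict[int, list] = {}
    for iv in schedule.intervals:
        by_cycle.setdefault(iv.cycle_index, []).append(iv)

    adherent = {c: bool(rng.random() < profile.adherence_prob)
                for c in sorted(by_cycle)}

    last_end = 0.0
    free_run_start: float | None = None
    cycle_ids = sorted(by_cycle)
    for cycle_idx in cycle_ids:
        ivs = by_cycle[cycle_idx]
        if adherent[cycle_idx]:
            if free_run_start is not None:
                # close the preceding run of non-adherent cycles in one piece
                a = max(free_run_start, last_end)
                free = _free_breathing_events(
                    a, ivs[0].start_s, profile.natural_bpm, rng
                )
                events.extend(free)
                if free:
                    last_end = free[-1].end_s
                free_run_start = None
            for iv in ivs:
                a = max(iv.start_s + profile.latency_s, last_end)
                b = min(iv.end_s + profile.latency_s, schedule.duration_s)
                if b > a + 1e-9:
                    events.append(BreathEvent(a, b, iv.phase))
                    last_end = b
        elif free_run_start is None:
            free_run_start = ivs[0].start_s
    if free_run_start is not None:
        a = max(free_run_start, last_end)
        events.extend(
            _free_breathing_events(a, schedule.duration_s, profile.natural_bpm,
                                   rng)
        )
    return BreathStream(tuple(events), origin="synthetic-detector")


def generate_resp_signal(
    stream: BreathStream,
    fs_hz: float,
    ara_volts: float,
    duration_s: float | None = None,
) -> RespSeries:
    """Render a breath stream as a respiratory-belt waveform.

    The signal rises from trough to peak over each inhalation and falls back
    over each exhalation, along raised-cosine ramps (smooth and band-limited);
    it holds its level during pauses, gaps and NONE spans.  Peak-to-trough
    equals ``ara_volts``.
    """
    if fs_hz < 4.0:
        raise ValueError("fs_hz must be at least 4 Hz")
    if duration_s is None:
        duration_s = stream.events[-1].end_s if stream.events else 0.0
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    x = np.zeros(n)
    level = 0.0
    cursor = 0
    for ev in stream.events:
        i0 = np.searchsorted(t, ev.start_s, side="left")
        i1 = np.searchsorted(t, ev.end_s, side="left")
        x[cursor:i0] = level  # hold through any gap
        if ev.label is Phase.INHALE:
            target = ara_volts
        elif ev.label is Phase.EXHALE:
            target = 0.0
        else:
            target = level
        if i1 > i0:
            u = (t[i0:i1] - ev.start_s) / (ev.end_s - ev.start_s)
            x[i0:i1] = level + (target - level) * (1 - np.cos(np.pi * u)) / 2
        level = target
        cursor = i1
    x[cursor:] = level
    return RespSeries(fs_hz=fs_hz, samples=x)


def simulate_rr(
    resp: RespSeries,
    profile: SubjectProfile,
    duration_s: float,
    seed: int,
    rsa_gain: float | None = None,
) -> RRSeries:
    """Generate heartbeats with an IPFM model driven by the respiration.

    The instantaneous beat rate (beats/s) is::

        m(t) = (hr_base / 60) * (1 + rsa_gain * resp_norm(t)) + noise(t)

    where ``resp_norm`` is the respiration centred on its mean and rescaled
    so its largest excursion is 1 (zero for a flat signal) — centring keeps
    ``hr_base`` the true mean rate despite the asymmetric inhale/exhale/pause
    waveform — and ``noise`` is first-order autoregressive jitter whose
    stationary scale maps ``rr_noise_ms`` from interval units into rate
    units.  A beat fires whenever the integral of ``m`` crosses an integer;
    the returned series is the successive beat gaps in ms.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if rsa_gain is None:
        rsa_gain = max(profile.rsa_gain_by_condition.values(), default=0.0)
    if rsa_gain >= 1.0:
        raise InvalidProfileError(
            f"rsa_gain={rsa_gain} would drive the beat rate non-positive"
        )
    rng = np.random.default_rng(seed)
    fs = resp.fs_hz
    n = int(round(duration_s * fs))
    t = np.arange(n + 1) / fs

    x = resp.samples
    if len(x) == 0:
        resp_norm = np.zeros(n + 1)
    else:
        xi = np.interp(t, resp.times, x)
        dev = xi - float(np.mean(xi))
        peak = float(np.max(np.abs(dev)))
        resp_norm = np.zeros(n + 1) if peak < 1e-12 else dev / peak

    m0 = profile.hr_base / 60.0
    m = m0 * (1.0 + rsa_gain * resp_norm)
    if profile.rr_noise_ms > 0:
        # stationary sd in rate units: delta_rr ~ delta_m / m^2
        sd_m = (profile.rr_noise_ms / 1000.0) * m0**2
        phi = np.exp(-1.0 / (fs * 1.0))  # ~1-s correlation time
        innov = rng.standard_normal(n + 1) * sd_m * np.sqrt(1 - phi**2)
        innov[0] = rng.standard_normal() * sd_m  # stationary start
        noise = sp_signal.lfilter([1.0], [1.0, -phi], innov)
        m = m + noise
    m = np.maximum(m, 0.05 * m0)

    # trapezoidal running integral of the rate; beats at integer crossings
    integral = np.concatenate(([0.0], np.cumsum((m[1:] + m[:-1]) / 2) / fs))
    n_beats = int(np.floor(integral[-1]))
    if n_beats < 2:
        return RRSeries(rr_ms=np.array([]))
    beat_times = np.interp(np.arange(1, n_beats + 1), integral, t)
    rr_ms = np.diff(beat_times) * 1000.0
    return RRSeries(rr_ms=rr_ms, t0_s=float(beat_times[0]))


@dataclass(frozen=True)
class StudyDesign:
    """Design of the simulated within-subject study."""

    pattern: BreathingPattern = BreathingPattern()
    duration_s: float = 360.0
    resp_fs_hz: float = 8.0


@dataclass(frozen=True)
class Recording:
    """One 6-min condition recording for one subject."""

    condition: str
    stream: BreathStream
    resp: RespSeries
    rr: RRSeries


@dataclass(frozen=True)
class SubjectData:
    profile: SubjectProfile
    condition_order: tuple[str, ...]
    recordings: dict[str, Recording]


@dataclass(frozen=True)
class StudyDataset:
    design: StudyDesign
    seed: int
    subjects: tuple[SubjectData, ...]

    def __len__(self) -> int:
        return len(self.subjects)


def default_profiles(n: int = 16, seed: int = 0) -> list[SubjectProfile]:
    """Draw ``n`` subject profiles with realistic between-subject spread."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    profiles = []
    for i in range(n):
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:02d}",
                adherence_prob=0.9,
                latency_s=float(rng.uniform(0.1, 0.5)),
                natural_bpm=float(np.clip(rng.normal(12.0, 1.5), 8.0, 18.0)),
                hr_base=float(np.clip(rng.normal(72.0, 8.0), 50.0, 100.0)),
                rr_noise_ms=25.0,
                ara_volts=float(np.clip(rng.normal(5.0, 1.2), 1.0, 10.0)),
            )
        )
    return profiles


def simulate_study(
    profiles: list[SubjectProfile],
    design: StudyDesign | None = None,
    seed: int = 0,
) -> StudyDataset:
    """Simulate the full three-condition within-subject study.

    Every subject contributes a spontaneous-breathing BASELINE recording and
    the two paced recordings (CIRCLE, BREEZE) at the protocol pattern with
    the subject's adherence; the order of the two trainings is randomized per
    subject (baseline always comes first, as in a physiological-baseline
    protocol).  The inter-condition washout leaves no data artifact.
    """
    if len(profiles) < 2:
        raise ValueError("a within-subject study needs at least 2 profiles")
    ids = [p.subject_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject identifiers in profiles")

    design = design or StudyDesign()
    schedule = build_schedule(design.pattern, design.duration_s)
    master = np.random.SeedSequence(seed)
    subject_seqs = master.spawn(len(profiles))

    subjects = []
    for profile, sub_seq in zip(profiles, subject_seqs):
        order_seed, *cond_seqs = sub_seq.spawn(1 + len(CONDITIONS))
        order_rng = np.random.default_rng(order_seed)
        paced = list(CONDITIONS[1:])
        order_rng.shuffle(paced)
        order = ("BASELINE", *paced)

        recordings: dict[str, Recording] = {}
        for cond, cond_seq in zip(CONDITIONS, cond_seqs):
            stream_seed, rr_seed = (int(s.generate_state(1)[0] % (2**31))
                                    for s in cond_seq.spawn(2))
            if cond == "BASELINE":
                stream = generate_free_breathing(
                    design.duration_s, profile.natural_bpm, stream_seed
                )
            else:
                stream = generate_breath_stream(profile, schedule, stream_seed)
            resp = generate_resp_signal(
                stream, design.resp_fs_hz, profile.ara_volts,
                duration_s=design.duration_s,
            )
            rr = simulate_rr(
                resp, profile, design.duration_s, rr_seed,
                rsa_gain=profile.rsa_gain_by_condition.get(cond, 0.0),
            )
            recordings[cond] = Recording(cond, stream, resp, rr)
        subjects.append(SubjectData(profile, order, recordings))
    return StudyDataset(design=design, seed=seed, subjects=tuple(subjects))
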