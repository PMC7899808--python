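import numpy as np
import pytest

from breezesim import (
    BreathingPattern,
    Phase,
    RespSeries,
    StudyDesign,
    SubjectProfile,
    build_schedule,
    classify_adherence,
    default_profiles,
    generate_breath_stream,
    generate_free_breathing,
    generate_resp_signal,
    simulate_rr,
    simulate_study,
)
from breezesim.hrv import frequency_domain_metrics, time_domain_metrics
from breezesim.synth import CONDITIONS, InvalidProfileError


def flat_resp(duration_s=400.0, fs=8.0):
    return RespSeries(fs_hz=fs, samples=np.zeros(int(duration_s * fs)))


class TestGenerateBreathStream:
    def test_full_adherence_reproduces_the_protocol(self, schedule):
        profile = SubjectProfile(adherence_prob=1.0, latency_s=0.0)
        stream = generate_breath_stream(profile, schedule, seed=1)
        records = classify_adherence(stream, schedule)
        assert all(r.coverage == pytest.approx(1.0) for r in records)

    def test_zero_adherence_breathes_at_the_natural_rate(self, schedule):
        profile = SubjectProfile(adherence_prob=0.0, natural_bpm=12.0)
        stream = generate_breath_stream(profile, schedule, seed=2)
        inhales = [e for e in stream.events if e.label is Phase.INHALE]
        rate = len(inhales) / 6.0  # cycles per minute over the 6-min session
        assert rate == pytest.approx(12.0, abs=0.5)

    def test_same_seed_same_stream(self, schedule):
        profile = SubjectProfile()
        a = generate_breath_stream(profile, schedule, seed=3)
        b = generate_breath_stream(profile, schedule, seed=3)
        assert a.events == b.events

    def test_latency_longer_than_cycle_rejected(self, schedule):
        profile = SubjectProfile(latency_s=11.0)
        with pytest.raises(InvalidProfileError):
            generate_breath_stream(profile, schedule, seed=4)


class TestGenerateRespSignal:
    def test_amplitude_contract(self, schedule, perfect_stream):
        resp = generate_resp_signal(perfect_stream, 8.0, 5.0)
        span = float(np.max(resp.samples) - np.min(resp.samples))
        assert span == pytest.approx(5.0, abs=5.0 / 8)

    def test_one_peak_per_paced_cycle(self, perfect_stream):
        resp = generate_resp_signal(perfect_stream, 8.0, 5.0)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(resp.samples, prominence=2.0)
        assert len(peaks) == 36

    def test_empty_stream_is_flat(self):
        from breezesim import BreathStream

        resp = generate_resp_signal(BreathStream(()), 8.0, 5.0,
                                    duration_s=60.0)
        assert np.ptp(resp.samples) == 0.0

    def test_low_sampling_rate_rejected(self, perfect_stream):
        with pytest.raises(ValueError):
            generate_resp_signal(perfect_stream, 2.0, 5.0)


class TestSimulateRR:
    def test_unmodulated_beats_are_exactly_one_second(self):
        profile = SubjectProfile(hr_base=60.0, rr_noise_ms=0.0)
        rr = simulate_rr(flat_resp(), profile, 60.0, seed=0, rsa_gain=0.0)
        assert np.allclose(rr.rr_ms, 1000.0, atol=1e-6)

    def test_beat_count_matches_the_rate_integral(self):
        profile = SubjectProfile(hr_base=60.0, rr_noise_ms=0.0)
        rr = simulate_rr(flat_resp(), profile, 60.0, seed=0, rsa_gain=0.0)
        assert len(rr.rr_ms) + 1 in (59, 60, 61)

    def test_mean_rate_recovery_within_two_percent(self):
        resp = generate_resp_signal(
            generate_free_breathing(300.0, 10.0, seed=5), 8.0, 5.0
        )
        for gain in (0.0, 0.1, 0.2):
            profile = SubjectProfile(hr_base=72.0, rr_noise_ms=0.0)
            rr = simulate_rr(resp, profile, 300.0, seed=6, rsa_gain=gain)
            mean_hr = float(np.mean(60000.0 / rr.rr_ms))
            assert mean_hr == pytest.approx(72.0, rel=0.02)

    def test_rsa_modulation_lands_in_the_respiratory_band(self):
        # 0.1-Hz respiration -> dominant R-R power inside 0.04-0.15 Hz
        t = np.arange(0, 360, 1 / 8)
        resp = RespSeries(fs_hz=8.0, samples=np.cos(2 * np.pi * 0.1 * t))
        profile = SubjectProfile(hr_base=60.0, rr_noise_ms=0.0)
        rr = simulate_rr(resp, profile, 360.0, seed=7, rsa_gain=0.1)
        m = frequency_domain_metrics(rr)
        assert m.lf_power > m.hf_power
        assert m.lf_power > m.vlf_power

    def test_rmssd_monotone_in_rsa_gain(self):
        resp = generate_resp_signal(
            generate_free_breathing(300.0, 6.0, seed=8), 8.0, 5.0
        )
        profile = SubjectProfile(hr_base=70.0, rr_noise_ms=0.0)
        rmssds = []
        for gain in (0.0, 0.05, 0.1, 0.15, 0.2):
            rr = simulate_rr(resp, profile, 300.0, seed=9, rsa_gain=gain)
            rmssds.append(time_domain_metrics(rr).rmssd_ms)
        assert all(b >= a for a, b in zip(rmssds, rmssds[1:]))

    def test_excessive_gain_rejected(self):
        with pytest.raises(InvalidProfileError):
            simulate_rr(flat_resp(), SubjectProfile(), 60.0, seed=0,
                        rsa_gain=1.0)


@pytest.fixture(scope="module")
def study():
    return simulate_study(default_profiles(6, seed=11), StudyDesign(), seed=11)


class TestSimulateStudy:
    def test_every_subject_has_three_recordings(self, study):
        assert len(study.subjects) == 6
        total = sum(len(s.recordings) for s in study.subjects)
        assert total == 18
        for sub in study.subjects:
            assert set(sub.recordings) == set(CONDITIONS)

    def test_baseline_first_then_randomized_trainings(self, study):
        orders = [s.condition_order for s in study.subjects]
        assert all(o[0] == "BASELINE" for o in orders)
        assert all(sorted(o[1:]) == ["BREEZE", "CIRCLE"] for o in orders)

    def test_same_seed_reproduces_the_dataset(self, study):
        again = simulate_study(default_profiles(6, seed=11),
                               StudyDesign(), seed=11)
        for a, b in zip(study.subjects, again.subjects):
            assert a.condition_order == b.condition_order
            for cond in CONDITIONS:
                np.testing.assert_array_equal(
                    a.recordings[cond].rr.rr_ms, b.recordings[cond].rr.rr_ms
                )

    def test_duplicate_subject_ids_rejected(self):
        profiles = [SubjectProfile(subject_id="S01"),
                    SubjectProfile(subject_id="S01")]
        with pytest.raises(ValueError, match="duplicate"):
            simulate_study(profiles, StudyDesign(), seed=0)

    def test_too_few_profiles_rejected(self):
        with pytest.raises(ValueError):
            simulate_study([SubjectProfile()], StudyDesign(), seed=0)
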