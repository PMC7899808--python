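"""The 11 physiological outcome measures from R-R and respiratory series.

Time domain: IBI (mean inter-beat interval, ms), HR (beats/min), SDNN
(sample SD of intervals), RMSSD (root mean square of successive differences),
pNN50 (percentage of successive differences strictly greater than 50 ms).

Frequency domain: HF (0.15-0.4 Hz), LF (0.04-0.15 Hz) and VLF
(0.0033-0.04 Hz) band powers of the beat-interval series in ms^2, plus the
LF/HF ratio.  The beat series is cubic-spline resampled onto a uniform grid,
linearly detrended and fed to a Hann-windowed averaged periodogram (Welch);
band powers are trapezoidal integrals of the PSD.  A Lomb-Scargle estimator
operating directly on the irregular beat times is available via the config.

Respiration: BPM (breathing rate, full cycles/min) and ARA (mean respiratory
peak-to-trough amplitude, volts) from the belt waveform via band-limited
peak detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy.interpolate import CubicSpline

from .synth import RespSeries, RRSeries

__all__ = [
    "HRVMetrics",
    "SpectralConfig",
    "InsufficientDataError",
    "MEASURE_NAMES",
    "time_domain_metrics",
    "frequency_domain_metrics",
    "breathing_metrics",
    "analyze_recording",
]

#: Canonical measure names, in reporting order.
MEASURE_NAMES = (
    "IBI", "HR", "SDNN", "RMSSD", "pNN50",
    "HF-HRV", "LF-HRV", "VLF-HRV", "LF/HF ratio", "BPM", "ARA",
)

VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)


class InsufficientDataError(ValueError):
    """Raised when a series is too short for the requested metric."""


@dataclass
class HRVMetrics:
    """Partial or complete set of the 11 outcome measures.

    Unset fields are NaN; ``lf_hf_ratio`` is NaN when HF power is zero
    (undefined, never infinity).
    """

    ibi_ms: float = math.nan
    hr_bpm: float = math.nan
    sdnn_ms: float = math.nan
    rmssd_ms: float = math.nan
    pnn50_pct: float = math.nan
    hf_power: float = math.nan
    lf_power: float = math.nan
    vlf_power: float = math.nan
    lf_hf_ratio: float = math.nan
    bpm: float = math.nan
    ara_volts: float = math.nan

    def as_dict(self) -> dict[str, float]:
        """Measures keyed by their canonical names."""
        return {
            "IBI": self.ibi_ms,
            "HR": self.hr_bpm,
            "SDNN": self.sdnn_ms,
            "RMSSD": self.rmssd_ms,
            "pNN50": self.pnn50_pct,
            "HF-HRV": self.hf_power,
            "LF-HRV": self.lf_power,
            "VLF-HRV": self.vlf_power,
            "LF/HF ratio": self.lf_hf_ratio,
            "BPM": self.bpm,
            "ARA": self.ara_volts,
        }

    def update(self, other: "HRVMetrics") -> "HRVMetrics":
        """Merge: fields set (non-NaN) in ``other`` overwrite this one's."""
        merged = HRVMetrics()
        for name in vars(merged):
            theirs = getattr(other, name)
            setattr(merged, name, getattr(self, name) if math.isnan(theirs) else theirs)
        return merged


@dataclass(frozen=True)
class SpectralConfig:
    resample_hz: float = 4.0
    detrend: str = "linear"
    window_s: float = 120.0
    overlap: float = 0.5
    method: str = "welch"  # or "lombscargle"

    def __post_init__(self) -> None:
        if self.resample_hz < 2 * HF_BAND[1]:
            raise ValueError("resample_hz must satisfy Nyquist for the HF band")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")


def time_domain_metrics(rr: RRSeries) -> HRVMetrics:
    """IBI, HR, SDNN, RMSSD and pNN50 of a beat-interval series.

    SDNN uses the sample (n-1) standard deviation; pNN50 counts successive
    differences strictly greater than 50 ms.  Inputs are assumed to be clean
    normal-beat series (no artifact filtering is applied).
    """
    x = np.asarray(rr.rr_ms, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(
            f"need at least 2 intervals, got {x.size}"
        )
    diffs = np.diff(x)
    ibi = float(np.mean(x))
    return HRVMetrics(
        ibi_ms=ibi,
        hr_bpm=60000.0 / ibi,
        sdnn_ms=float(np.std(x, ddof=1)),
        rmssd_ms=float(np.sqrt(np.mean(diffs**2))),
        pnn50_pct=100.0 * float(np.mean(np.abs(diffs) > 50.0)),
    )


def _band_power(f: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    lo, hi = band
    mask = (f >= lo) & (f <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], f[mask]))


def frequency_domain_metrics(
    rr: RRSeries, cfg: SpectralConfig | None = None
) -> HRVMetrics:
    """HF / LF / VLF band powers (ms^2) and the LF/HF ratio."""
    cfg = cfg or SpectralConfig()
    x = np.asarray(rr.rr_ms, dtype=float)
    if x.size < 4:
        raise InsufficientDataError("need at least 4 intervals for a spectrum")
    beat_t = rr.beat_times_s[1:]  # interval value attributed to its ending beat
    span = beat_t[-1] - beat_t[0]
    if span < 60.0:
        raise InsufficientDataError(
            f"recording spans {span:.1f} s; at least 60 s required"
        )

    if cfg.method == "lombscargle":
        f = np.linspace(VLF_BAND[0], HF_BAND[1], 512)
        xc = x - np.mean(x)
        pxx = sp_signal.lombscargle(beat_t, xc, 2 * np.pi * f, normalize=False)
        # convert angular-frequency periodogram to a one-sided density in ms^2/Hz
        psd = pxx * 4.0 / len(xc) * span
    else:
        grid = np.arange(beat_t[0], beat_t[-1], 1.0 / cfg.resample_hz)
        xs = CubicSpline(beat_t, x)(grid)
        nperseg = int(cfg.window_s * cfg.resample_hz)
        if len(grid) < 2 * nperseg:  # shorter than 2 segments: one full window
            nperseg = len(grid)
        f, psd = sp_signal.welch(
            xs,
            fs=cfg.resample_hz,
            window="hann",
            nperseg=nperseg,
            noverlap=int(nperseg * cfg.overlap),
            detrend=cfg.detrend,
        )

    hf = _band_power(f, psd, HF_BAND)
    lf = _band_power(f, psd, LF_BAND)
    vlf = _band_power(f, psd, VLF_BAND)
    return HRVMetrics(
        hf_power=hf,
        lf_power=lf,
        vlf_power=vlf,
        lf_hf_ratio=lf / hf if hf > 1e-12 else math.nan,
    )


def breathing_metrics(resp: RespSeries) -> HRVMetrics:
    """Breathing rate (BPM) and respiratory amplitude (ARA) from the belt.

    The waveform is band-limited to 0.05-1 Hz, cycle peaks are detected with
    a minimum-prominence rule, and the rate is reported as 60 over the median
    peak-to-peak interval — the median instantaneous respiratory rate, robust
    to occasional off-pattern cycles.  ARA is the mean peak-to-trough
    amplitude of the raw signal between consecutive peaks.  A flat signal
    reports BPM 0 and ARA 0.
    """
    x = np.asarray(resp.samples, dtype=float)
    if len(x) / resp.fs_hz < 30.0:
        raise InsufficientDataError("need at least 30 s of respiratory signal")
    rng_amp = float(np.max(x) - np.min(x))
    if rng_amp < 1e-9:
        return HRVMetrics(bpm=0.0, ara_volts=0.0)

    sos = sp_signal.butter(
        2, [0.05, 1.0], btype="bandpass", fs=resp.fs_hz, output="sos"
    )
    xf = sp_signal.sosfiltfilt(sos, x)
    min_dist = int(resp.fs_hz / 1.0)  # no faster than 60 cycles/min
    peaks, _ = sp_signal.find_peaks(
        xf, prominence=0.25 * np.std(xf), distance=max(min_dist, 1)
    )
    if len(peaks) < 2:
        return HRVMetrics(bpm=0.0, ara_volts=rng_amp if len(peaks) else 0.0)

    intervals = np.diff(peaks) / resp.fs_hz
    bpm = 60.0 / float(np.median(intervals))
    troughs = [int(i0 + np.argmin(x[i0:i1])) for i0, i1 in zip(peaks[:-1], peaks[1:])]
    ara = float(np.mean(x[peaks[:-1]] - x[troughs]))
    return HRVMetrics(bpm=bpm, ara_volts=ara)


def cycle_count_bpm(resp: RespSeries) -> float:
    """Breathing rate as detected cycle peaks per minute (count-based)."""
    x = np.asarray(resp.samples, dtype=float)
    if np.max(x) - np.min(x) < 1e-9:
        return 0.0
    sos = sp_signal.butter(
        2, [0.05, 1.0], btype="bandpass", fs=resp.fs_hz, output="sos"
    )
    xf = sp_signal.sosfiltfilt(sos, x)
    peaks, _ = sp_signal.find_peaks(
        xf, prominence=0.25 * np.std(xf), distance=max(int(resp.fs_hz), 1)
    )
    return len(peaks) / (len(x) / resp.fs_hz) * 60.0


def analyze_recording(
    rr: RRSeries,
    resp: RespSeries | None = None,
    cfg: SpectralConfig | None = None,
) -> HRVMetrics:
    """All 11 measures for one recording (respiration metrics if given)."""
    out = time_domain_metrics(rr).update(frequency_domain_metrics(rr, cfg))
    if resp is not None:
        out = out.update(breathing_metrics(resp))
    return out


def compute_study_metrics(study, cfg: SpectralConfig | None = None):
    """All 11 measures for every recording of a simulated or loaded study.

    Returns a tidy DataFrame with columns measure / subject / condition /
    value, ready for the statistical analysis.
    """
    import pandas as pd

    rows = []
    for sub in study.subjects:
        sid = sub.profile.subject_id
        for cond, rec in sub.recordings.items():
            metrics = analyze_recording(rec.rr, rec.resp, cfg).as_dict()
            for measure in MEASURE_NAMES:
                rows.append(
                    {"measure": measure, "subject": sid, "condition": cond,
                     "value": metrics[measure]}
                )
    return pd.DataFrame(rows)
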