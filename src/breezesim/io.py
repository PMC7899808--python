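"""CSV / JSON interchange for streams, series, schedules, traces and configs.

All CSV files are comma-separated UTF-8 with a required header row and '.'
decimals.  Schema violations raise :class:`SchemaError` naming the offending
line (1-based, counting the header as line 1).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .adherence import BreathEvent, BreathStream
from .engine import EngineConfig, SessionResult
from .hrv import SpectralConfig
from .protocol import BreathingPattern, Phase, ProtocolSchedule
from .synth import (
    CONDITIONS,
    Recording,
    RespSeries,
    RRSeries,
    StudyDataset,
    StudyDesign,
    SubjectData,
    SubjectProfile,
)

__all__ = [
    "SchemaError",
    "read_breath_stream", "write_breath_stream",
    "read_rr", "write_rr",
    "read_resp", "write_resp",
    "write_schedule", "write_trace", "write_session_result",
    "read_codes",
    "load_config", "RunConfig",
    "write_study", "read_study",
]


class SchemaError(ValueError):
    """Malformed input file; the message names the file and line."""


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


_LABELS = {p.value: p for p in Phase}


def read_breath_stream(path: str | Path) -> BreathStream:
    """Read a detected-phase stream (columns start_s, end_s, label)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["start_s", "end_s", "label"], path)
    events = []
    prev_end = -np.inf
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start, end = float(row.start_s), float(row.end_s)
        except (TypeError, ValueError):
            raise SchemaError(f"{path}:{i}: non-numeric timestamps") from None
        if not start < end:
            raise SchemaError(f"{path}:{i}: start_s must be < end_s")
        if start < prev_end - 1e-9:
            raise SchemaError(f"{path}:{i}: event overlaps the previous one")
        label = str(row.label).strip().lower()
        if label not in _LABELS:
            raise SchemaError(
                f"{path}:{i}: unknown label {row.label!r} "
                f"(expected one of {sorted(_LABELS)})"
            )
        events.append(BreathEvent(start, end, _LABELS[label]))
        prev_end = end
    return BreathStream(tuple(events), origin=str(path))


def write_breath_stream(stream: BreathStream, path: str | Path) -> None:
    pd.DataFrame(
        {
            "start_s": [e.start_s for e in stream.events],
            "end_s": [e.end_s for e in stream.events],
            "label": [e.label.value for e in stream.events],
        }
    ).to_csv(path, index=False)


def read_rr(path: str | Path) -> RRSeries:
    """Read an R-R series (columns t_s, rr_ms)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["t_s", "rr_ms"], path)
    rr = df["rr_ms"].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(rr) | (rr <= 0))
    if bad.size:
        raise SchemaError(f"{path}:{bad[0] + 2}: non-positive R-R interval")
    t = df["t_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        line = int(np.flatnonzero(np.diff(t) < 0)[0]) + 3
        raise SchemaError(f"{path}:{line}: unsorted timestamps")
    t0 = float(t[0]) if len(t) else 0.0
    return RRSeries(rr_ms=rr, t0_s=t0)


def write_rr(rr: RRSeries, path: str | Path) -> None:
    # t_s is the ending beat time of each interval
    t = rr.beat_times_s[1:] if len(rr) else np.array([])
    pd.DataFrame({"t_s": t, "rr_ms": rr.rr_ms}).to_csv(path, index=False)


def read_resp(path: str | Path) -> RespSeries:
    """Read a respiratory waveform (columns t_s, volts; uniform sampling)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["t_s", "volts"], path)
    t = df["t_s"].to_numpy(dtype=float)
    v = df["volts"].to_numpy(dtype=float)
    if len(t) < 2:
        raise SchemaError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        line = int(np.flatnonzero(dt <= 0)[0]) + 3
        raise SchemaError(f"{path}:{line}: unsorted timestamps")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise SchemaError(f"{path}: sampling is not uniform")
    if not np.all(np.isfinite(v)):
        line = int(np.flatnonzero(~np.isfinite(v))[0]) + 2
        raise SchemaError(f"{path}:{line}: non-finite sample")
    return RespSeries(fs_hz=1.0 / float(dt[0]), samples=v, t0_s=float(t[0]))


def write_resp(resp: RespSeries, path: str | Path) -> None:
    pd.DataFrame({"t_s": resp.times, "volts": resp.samples}).to_csv(
        path, index=False, float_format="%.6f"
    )


def write_schedule(schedule: ProtocolSchedule, path: str | Path) -> None:
    pd.DataFrame(
        {
            "start_s": [iv.start_s for iv in schedule.intervals],
            "end_s": [iv.end_s for iv in schedule.intervals],
            "phase": [iv.phase.value for iv in schedule.intervals],
            "cycle_index": [iv.cycle_index for iv in schedule.intervals],
        }
    ).to_csv(path, index=False)


def write_trace(result: SessionResult, path: str | Path) -> None:
    result.trace.to_csv(path, index=False, float_format="%.6f")


def write_session_result(
    result: SessionResult, config: EngineConfig, path: str | Path
) -> None:
    adher: dict[str, Any] = {}
    if result.adherence is not None:
        adher = {
            "mean_coverage_by_phase": {
                k.value: v for k, v in result.adherence.mean_coverage_by_phase.items()
            },
            "full_inhale_fraction": result.adherence.full_inhale_fraction,
            "full_exhale_fraction": result.adherence.full_exhale_fraction,
            "overall_correct_fraction": result.adherence.overall_correct_fraction,
        }
    payload = {
        "distance": result.distance,
        "environment_reached": result.environment_reached.value,
        "adherence": adher,
        "config": dataclasses.asdict(config),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_codes(path: str | Path) -> list[str]:
    """One qualitative code label per row; optional 'code' header."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if lines and lines[0].lower() == "code":
        lines = lines[1:]
    if not lines:
        raise SchemaError(f"{path}: no codes found")
    return lines


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Serializable top-level configuration (pattern, session, engine, spectral)."""

    pattern: BreathingPattern = BreathingPattern()
    duration_s: float = 360.0
    engine: EngineConfig = EngineConfig()
    spectral: SpectralConfig = SpectralConfig()

    def to_dict(self) -> dict[str, Any]:
        return {
            "pattern": {
                "inhale_s": self.pattern.inhale_s,
                "exhale_s": self.pattern.exhale_s,
                "pause_s": self.pattern.pause_s,
            },
            "session": {"duration_s": self.duration_s},
            "engine": dataclasses.asdict(self.engine),
            "spectral": dataclasses.asdict(self.spectral),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        pat = d.get("pattern", {})
        eng = dict(d.get("engine", {}))
        if "milestones" in eng:
            eng["milestones"] = tuple(eng["milestones"])
        return cls(
            pattern=BreathingPattern(
                inhale_s=pat.get("inhale_s", 4.0),
                exhale_s=pat.get("exhale_s", 2.0),
                pause_s=pat.get("pause_s", 4.0),
            ),
            duration_s=d.get("session", {}).get("duration_s", 360.0),
            engine=EngineConfig(**eng),
            spectral=SpectralConfig(**d.get("spectral", {})),
        )


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    return RunConfig.from_dict(json.loads(Path(path).read_text()))


_STUDY_FILES = {
    "BASELINE": "baseline", "CIRCLE": "circle", "BREEZE": "breeze",
}


def write_study(study: StudyDataset, out_dir: str | Path) -> None:
    """Write a study dataset: one directory per subject plus manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": study.seed,
        "design": {
            "pattern": {
                "inhale_s": study.design.pattern.inhale_s,
                "exhale_s": study.design.pattern.exhale_s,
                "pause_s": study.design.pattern.pause_s,
            },
            "duration_s": study.design.duration_s,
            "resp_fs_hz": study.design.resp_fs_hz,
        },
        "subjects": [],
    }
    for sub in study.subjects:
        sid = sub.profile.subject_id
        sub_dir = out / sid
        sub_dir.mkdir(exist_ok=True)
        for cond, rec in sub.recordings.items():
            stem = _STUDY_FILES[cond]
            write_rr(rec.rr, sub_dir / f"{stem}_rr.csv")
            write_resp(rec.resp, sub_dir / f"{stem}_resp.csv")
            write_breath_stream(rec.stream, sub_dir / f"{stem}_stream.csv")
        prof = dataclasses.asdict(sub.profile)
        manifest["subjects"].append(
            {"id": sid, "profile": prof, "condition_order": list(sub.condition_order)}
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def read_study(study_dir: str | Path) -> StudyDataset:
    """Read back a study dataset written by :func:`write_study`."""
    root = Path(study_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    dsg = manifest["design"]
    design = StudyDesign(
        pattern=BreathingPattern(**dsg["pattern"]),
        duration_s=dsg["duration_s"],
        resp_fs_hz=dsg["resp_fs_hz"],
    )
    subjects = []
    for entry in manifest["subjects"]:
        profile = SubjectProfile(**entry["profile"])
        recordings = {}
        for cond in CONDITIONS:
            stem = _STUDY_FILES[cond]
            recordings[cond] = Recording(
                condition=cond,
                stream=read_breath_stream(root / entry["id"] / f"{stem}_stream.csv"),
                resp=read_resp(root / entry["id"] / f"{stem}_resp.csv"),
                rr=read_rr(root / entry["id"] / f"{stem}_rr.csv"),
            )
        subjects.append(
            SubjectData(profile, tuple(entry["condition_order"]), recordings)
        )
    return StudyDataset(design=design, seed=manifest["seed"],
                        subjects=tuple(subjects))
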