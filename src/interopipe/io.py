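"""Recording readers/writers and the pipeline configuration.

A recording on disk is one CSV per modality (a ``# fs_hz=...`` comment line,
then a header and the samples) plus an ``events.json`` sidecar listing the
protocol events as onset/duration seconds relative to the record start
(half-open intervals) with their attributes.  Synthetic ground truth, when
present, travels in ``truth.json`` and is never read by analysis stages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import (
    MultiModalRecording,
    ProtocolEvent,
    ProtocolSchedule,
    SimTruth,
)

__all__ = ["PipelineConfig", "write_recording", "read_recording"]


@dataclass
class PipelineConfig:
    """Every stage parameter of the analysis, defaulting to the protocol's
    published processing settings."""

    # cohort
    n_subjects: int = 19
    n_fnirs_subjects: int = 12
    seed: int = 0
    # simulator cohort physiology
    mean_hr: float = 1.18  # Hz
    free_breathing_rate: float = 0.24  # Hz
    rsa_gain: float = 0.15
    rsa_lag_s: float = 10.0
    lf_gain: float = 0.05
    ecg_noise_sd: float = 0.05
    hr_counting_drop_hz: float = 0.05
    br_counting_drop_hz: float = 0.02
    # sampling
    fs_ecg: float = 250.0
    fs_fnirs: float = 50.0
    grid_fs: float = 4.0
    # filters
    ecg_band: tuple[float, float] = (0.5, 45.0)
    ecg_filter_order: int = 4
    fnirs_band: tuple[float, float] = (0.05, 0.6)
    fnirs_filter_order: int = 3
    # spectra
    ar_order: int = 16
    main_freq_band: tuple[float, float] = (0.0, 0.5)
    # coupling / PCA
    lag_range_s: tuple[float, float] = (-30.0, 30.0)
    component_rho_threshold: float = 0.6
    # statistics
    n_perm: int = 10_000
    alpha: float = 0.05
    n_channels: int = 23
    smooth_window_s: float = 2.0

    def validate(self) -> None:
        if not (0 < self.n_fnirs_subjects <= self.n_subjects):
            raise ValueError("n_fnirs_subjects must be in (0, n_subjects]")
        if self.n_perm <= 0 or not (0 < self.alpha < 1):
            raise ValueError("invalid statistical settings")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {
            k: tuple(v) if isinstance(getattr(cls, k, None), tuple) else v
            for k, v in data.items()
        }
        if "n_subjects" in kwargs and "n_fnirs_subjects" not in kwargs:
            kwargs["n_fnirs_subjects"] = min(cls.n_fnirs_subjects, kwargs["n_subjects"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self).items()}

    def apply_overrides(self, overrides: list[str]) -> "PipelineConfig":
        """Apply ``key=value`` strings (YAML-parsed values) on top of self."""
        data = self.to_dict()
        for item in overrides:
            key, _, value = item.partition("=")
            if not _:
                raise ValueError(f"override '{item}' is not key=value")
            data[key.strip()] = yaml.safe_load(value)
        return PipelineConfig.from_dict(data)


# ---------------------------------------------------------------------------
# Recording writer / reader
# ---------------------------------------------------------------------------

def _write_series_csv(path: Path, fs: float, frame: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={fs}\n")
        frame.to_csv(fh, index=False, float_format="%.9g")


def _read_series_csv(path: Path) -> tuple[float, pd.DataFrame]:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# fs_hz="):
            raise ValueError(f"{path.name}: missing '# fs_hz=' header line")
        fs = float(header.split("=", 1)[1])
        frame = pd.read_csv(fh)
    return fs, frame


def write_recording(rec: MultiModalRecording, outdir: str | Path) -> Path:
    """Write one CSV per modality plus the JSON events sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = np.arange(rec.ecg.size) / rec.fs_ecg
    _write_series_csv(outdir / "ecg.csv", rec.fs_ecg,
                      pd.DataFrame({"t_s": t, "ecg": rec.ecg}))
    _write_series_csv(outdir / "breathing.csv", rec.fs_ecg,
                      pd.DataFrame({"t_s": t, "breathing": rec.breathing}))
    if rec.fnirs_od is not None:
        nc, _, n = rec.fnirs_od.shape
        tf = np.arange(n) / rec.fs_fnirs
        cols = {"t_s": tf}
        for c in range(nc):
            cols[f"ch{c + 1:02d}_760nm"] = rec.fnirs_od[c, 0]
            cols[f"ch{c + 1:02d}_840nm"] = rec.fnirs_od[c, 1]
        _write_series_csv(outdir / "fnirs_od.csv", rec.fs_fnirs, pd.DataFrame(cols))
    events = [
        {
            "label": e.label,
            "onset_s": e.start_s,
            "duration_s": e.duration_s,
            "target_breathing_rate_hz": e.target_breathing_rate,
            "counted_heartbeats": e.counted_heartbeats,
            "confidence": e.confidence,
        }
        for e in rec.schedule.events
    ]
    (outdir / "events.json").write_text(json.dumps({"events": events}, indent=1))
    if rec.truth is not None:
        truth = {
            "beat_times_s": rec.truth.beat_times.tolist(),
            "breath_peak_times_s": rec.truth.breath_peak_times.tolist(),
            "rsa_gain": rec.truth.rsa_gain,
            "rsa_lag_s": rec.truth.rsa_lag_s,
        }
        (outdir / "truth.json").write_text(json.dumps(truth))
    return outdir


def read_recording(path: str | Path) -> MultiModalRecording:
    """Read a recording directory written by :func:`write_recording`,
    validating lengths, sampling rates and events."""
    path = Path(path)
    for required in ("ecg.csv", "breathing.csv", "events.json"):
        if not (path / required).exists():
            raise FileNotFoundError(f"missing modality file: {required}")
    fs_ecg, ecg_df = _read_series_csv(path / "ecg.csv")
    fs_br, br_df = _read_series_csv(path / "breathing.csv")
    if fs_br != fs_ecg:
        raise ValueError("breathing.csv: sampling rate differs from ecg.csv")
    if len(br_df) != len(ecg_df):
        raise ValueError("breathing.csv: length mismatch against ecg.csv")

    raw = json.loads((path / "events.json").read_text())
    events = []
    for e in raw["events"]:
        events.append(ProtocolEvent(
            label=e["label"],
            start_s=float(e["onset_s"]),
            end_s=float(e["onset_s"]) + float(e["duration_s"]),
            target_breathing_rate=e.get("target_breathing_rate_hz"),
            counted_heartbeats=e.get("counted_heartbeats"),
            confidence=e.get("confidence"),
        ))
    schedule = ProtocolSchedule(tuple(events))
    schedule.validate()

    rec = MultiModalRecording(
        ecg=ecg_df["ecg"].to_numpy(),
        breathing=br_df["breathing"].to_numpy(),
        fs_ecg=fs_ecg,
        schedule=schedule,
    )
    od_path = path / "fnirs_od.csv"
    if od_path.exists():
        fs_f, od_df = _read_series_csv(od_path)
        chan_cols = [c for c in od_df.columns if c != "t_s"]
        nc = len(chan_cols) // 2
        if len(chan_cols) != 2 * nc:
            raise ValueError("fnirs_od.csv: expected two wavelengths per channel")
        od = np.empty((nc, 2, len(od_df)))
        for c in range(nc):
            od[c, 0] = od_df[f"ch{c + 1:02d}_760nm"].to_numpy()
            od[c, 1] = od_df[f"ch{c + 1:02d}_840nm"].to_numpy()
        rec.fnirs_od = od
        rec.fs_fnirs = fs_f
    truth_path = path / "truth.json"
    if truth_path.exists():
        tr = json.loads(truth_path.read_text())
        rec.truth = SimTruth(
            beat_times=np.asarray(tr["beat_times_s"], dtype=float),
            breath_peak_times=np.asarray(tr["breath_peak_times_s"], dtype=float),
            rsa_gain=tr.get("rsa_gain"),
            rsa_lag_s=tr.get("rsa_lag_s"),
        )
    return rec
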