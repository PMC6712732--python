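"""CSV/JSON/YAML interchange for recordings, configs and results.

A recording is a CSV with header ``time_s, mx, my, mz[, label]`` (time
in seconds, field components in μT along roll/pitch/yaw) plus a JSON
sidecar ``<name>.meta.json`` holding individual/session IDs, the
sampling rate and the local field model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import NO_LABEL, FieldModel, Recording, ValidationError

__all__ = [
    "PipelineConfig",
    "read_recording_csv",
    "write_recording_csv",
    "sidecar_path",
]

_REQUIRED_COLUMNS = ("time_s", "mx", "my", "mz")


def sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.name + ".meta.json")


def write_recording_csv(rec: Recording, path: str | Path,
                        float_format: str = "%.9g") -> None:
    """Write a recording to CSV plus its JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({
        "time_s": rec.times,
        "mx": rec.samples[:, 0],
        "my": rec.samples[:, 1],
        "mz": rec.samples[:, 2],
        "label": rec.labels,
    })
    df.to_csv(path, index=False, float_format=float_format)
    meta = {
        "individual_id": rec.individual_id,
        "session_id": rec.session_id,
        "fs_hz": rec.fs,
    }
    if rec.field is not None:
        meta["field"] = {"magnitude": rec.field.magnitude, "dip": rec.field.dip,
                         "declination": rec.field.declination}
    sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_recording_csv(path: str | Path) -> Recording:
    """Read a recording CSV (+ sidecar if present).

    Malformed input is rejected with the first offending line number
    (header is line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) == 0:
        raise ValidationError(f"{path}: no samples")
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if len(bad):
        raise ValidationError(
            f"{path}: non-increasing time at data line {int(bad[0]) + 3} "
            f"(t={t[bad[0] + 1]!r} follows t={t[bad[0]]!r})")
    for col in ("mx", "my", "mz"):
        vals = df[col].to_numpy()
        nan_rows = np.nonzero(~np.isfinite(vals.astype(float)))[0]
        if len(nan_rows):
            raise ValidationError(
                f"{path}: non-numeric {col} at data line {int(nan_rows[0]) + 2}")

    meta_path = sidecar_path(path)
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    fs = meta.get("fs_hz")
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    fieldinfo = meta.get("field")
    fmodel = (FieldModel(**fieldinfo) if fieldinfo else None)
    labels = (df["label"].fillna(NO_LABEL).astype(object).to_numpy()
              if "label" in df.columns else None)
    return Recording(
        times=t,
        samples=df[["mx", "my", "mz"]].to_numpy(dtype=float),
        fs=float(fs),
        individual_id=str(meta.get("individual_id", "ind0")),
        session_id=str(meta.get("session_id", path.stem)),
        labels=labels,
        field=fmodel,
    )


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; defaults mirror the study protocol."""

    native_fs: float = 50.0  # logger rate, Hz
    target_fs: float = 100.0  # analysis rate after linear resampling, Hz
    window_len: float = 2.0  # s
    overlap_frac: float = 0.5
    filter_order: int = 4
    filter_cutoff: float = 10.0  # Hz
    zero_phase: bool = False
    spectrum_resolution: float = 0.01  # U, Hz
    spectrum_pad: int = 100  # zeros per side
    svm_c: float = 1.0
    cv_scheme: str = "strat"  # strat | loio
    cv_folds: int = 10
    seed: int = 0
    field_magnitude: float = 27.3  # μT
    field_dip: float = 65.0  # deg, upward
    field_declination: float = -17.9  # deg (westwards)
    calibration_target: str = "field"  # field | unit
    drift_threshold: float = 0.05
    selected_features: dict | None = None  # None → run feature selection

    def __post_init__(self) -> None:
        for name in ("native_fs", "target_fs", "window_len", "filter_order",
                     "filter_cutoff", "spectrum_resolution", "svm_c",
                     "field_magnitude"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if self.target_fs < self.native_fs:
            raise ValidationError(
                "target sampling rate must be >= native rate for the "
                "upsampling analysis path")
        if self.cv_scheme not in ("strat", "loio"):
            raise ValidationError(f"unknown CV scheme {self.cv_scheme!r}")

    @property
    def target_norm(self) -> float:
        return self.field_magnitude if self.calibration_target == "field" else 1.0

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return PipelineConfig(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
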