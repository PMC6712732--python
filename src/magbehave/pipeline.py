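"""End-to-end workflow: calibrate → resample → filter → window → features
→ (select) → train → cross-validate."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .calibration import CalibrationParams, apply_calibration
from .core import Recording, ValidationError
from .evaluation import EvalReport, loio_cv, stratified_kfold_cv
from .features import SpectrumConfig, extract_feature_matrix
from .io import PipelineConfig
from .preprocessing import filter_recording, resample_linear, segment_windows
from .selection import select_descriptor_features

__all__ = ["PipelineResult", "recordings_to_features", "run_pipeline"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Wraps an error with the pipeline stage it occurred in."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@dataclass
class PipelineResult:
    features: pd.DataFrame
    selected_features: dict[str, str]
    report: EvalReport
    config: PipelineConfig

    def manifest(self) -> dict:
        """Reproducibility manifest: config hash, seed, feature wiring."""
        import magbehave
        cfg_json = json.dumps(self.config.__dict__, sort_keys=True, default=str)
        return {
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": self.config.seed,
            "scheme": self.config.cv_scheme,
            "selected_features": self.selected_features,
            "n_windows": int(len(self.features)),
            "version": magbehave.__version__,
        }


@_stage("features")
def recordings_to_features(recordings: list[Recording], config: PipelineConfig,
                           calibration: CalibrationParams | None = None,
                           ) -> pd.DataFrame:
    """Per-recording preprocessing and feature extraction, concatenated."""
    if not recordings:
        raise ValidationError("no recordings given")
    spectrum = SpectrumConfig(resolution_hz=config.spectrum_resolution,
                              pad=config.spectrum_pad,
                              lowpass_order=config.filter_order,
                              lowpass_cutoff=config.filter_cutoff)
    parts = []
    for rec in recordings:
        if calibration is not None:
            rec = apply_calibration(rec, calibration)
        if rec.fs != config.target_fs:
            rec = resample_linear(rec, config.target_fs)
        rec = filter_recording(rec, order=config.filter_order,
                               cutoff=config.filter_cutoff,
                               zero_phase=config.zero_phase)
        windows = segment_windows(rec, window_len=config.window_len,
                                  overlap_frac=config.overlap_frac)
        if windows:
            parts.append(extract_feature_matrix(windows, cfg=spectrum))
    if not parts:
        raise ValidationError("no single-behaviour windows were retained")
    return pd.concat(parts, ignore_index=True)


def run_pipeline(recordings: list[Recording], config: PipelineConfig | None = None,
                 calibration: CalibrationParams | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full workflow and optionally persist every intermediate.

    ``calibration`` is applied to raw recordings when given; omit it for
    already-calibrated input.  With ``out_dir`` set, the feature matrix,
    selection summary, evaluation report and a reproducibility manifest
    are written there.
    """
    config = config or PipelineConfig()
    fm = recordings_to_features(recordings, config, calibration)

    try:
        selected = config.selected_features or select_descriptor_features(fm)
    except Exception as exc:
        raise StageError(f"stage 'selection' failed: {exc}") from exc
    logger.info("selected features: %s", selected)

    try:
        if config.cv_scheme == "strat":
            report = stratified_kfold_cv(fm, selected, k=config.cv_folds,
                                         seed=config.seed, C=config.svm_c)
        else:
            report = loio_cv(fm, selected, C=config.svm_c)
            if report.discarded_sessions:
                logger.info("LOIO discarded sessions: %s", report.discarded_sessions)
    except Exception as exc:
        raise StageError(f"stage 'evaluation' failed: {exc}") from exc

    result = PipelineResult(features=fm, selected_features=dict(selected),
                            report=report, config=config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fm.to_csv(out / "features.csv", index=False)
        (out / "selection.json").write_text(json.dumps(selected, indent=2))
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        (out / "report.txt").write_text(report.summary() + "\n")
        (out / "manifest.json").write_text(json.dumps(result.manifest(), indent=2))
    return result
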