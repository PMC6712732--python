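"""Hard-iron / soft-iron magnetometer calibration and norm-drift diagnostics.

A magnetometer near ferromagnetic material reads ``A·m + o`` instead of
the true field ``m``: the additive offset ``o`` is the hard-iron bias and
the linear map ``A`` (axis gains plus cross-axis coupling) the soft-iron
distortion.  Since the true samples lie on a sphere of radius equal to
the local field magnitude, the distorted samples lie on an ellipsoid; a
least-squares quadric fit recovers the ellipsoid centre and shape, and
the symmetric square root of the shape matrix maps the ellipsoid back to
a sphere of the requested target norm.

Field calibrations are taken at the start of a session, but the
correction need not stay valid for hours of recording (temperature,
collar shifts): :func:`norm_drift_diagnostic` screens a calibrated
recording for blocks whose median sample norm drifts off the target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Recording, ValidationError


class CalibrationError(RuntimeError):
    """Raised when the sample cloud cannot support an ellipsoid fit."""


@dataclass(frozen=True)
class CalibrationParams:
    """Affine correction: calibrated = gain · (sample − offset)."""

    offset: np.ndarray  # (3,), μT
    gain: np.ndarray  # (3, 3), maps distorted units to μT on the target sphere
    target_norm: float  # μT

    def __post_init__(self) -> None:
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float).reshape(3))
        object.__setattr__(self, "gain", np.asarray(self.gain, dtype=float).reshape(3, 3))
        if not self.target_norm > 0:
            raise ValidationError("target norm must be > 0")
        if abs(np.linalg.det(self.gain)) < 1e-15:
            raise ValidationError("gain matrix must be invertible")

    @staticmethod
    def identity(target_norm: float = 1.0) -> "CalibrationParams":
        return CalibrationParams(np.zeros(3), np.eye(3), target_norm)

    def to_dict(self) -> dict:
        return {"offset": self.offset.tolist(), "gain": self.gain.tolist(),
                "target_norm": self.target_norm}

    @staticmethod
    def from_dict(d: dict) -> "CalibrationParams":
        return CalibrationParams(np.array(d["offset"]), np.array(d["gain"]),
                                 float(d["target_norm"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @staticmethod
    def load(path: str | Path) -> "CalibrationParams":
        return CalibrationParams.from_dict(json.loads(Path(path).read_text()))


def _check_span(samples: np.ndarray) -> None:
    centred = samples - samples.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[0] == 0 or sv[2] / sv[0] < 1e-6:
        raise CalibrationError(
            "sample cloud is (nearly) coplanar or collinear: singular values "
            f"{sv.tolist()}; rotate the sensor through diverse orientations")


def fit_ellipsoid_calibration(samples, target_norm: float) -> CalibrationParams:
    """Least-squares ellipsoid fit of a distorted sample cloud.

    Fits the general quadric ``s'M₀s + 2b's + d = 0`` by the null vector
    of the design matrix, recentres it as ``(s−o)'M(s−o) = 1`` and takes
    ``gain = target_norm · M^{1/2}`` (symmetric square root), so that
    ``‖gain·(s−offset)‖ ≈ target_norm`` over the cloud.

    Raises :class:`CalibrationError` for degenerate (coplanar/collinear)
    clouds or non-ellipsoidal fits.
    """
    samples = np.asarray(samples, dtype=float).reshape(-1, 3)
    if len(samples) < 10:
        raise CalibrationError(f"need at least 10 samples, got {len(samples)}")
    if not target_norm > 0:
        raise ValidationError("target norm must be > 0")
    _check_span(samples)

    x, y, z = samples.T
    # columns: x², y², z², 2yz, 2xz, 2xy, 2x, 2y, 2z, 1
    D = np.column_stack([x * x, y * y, z * z, 2 * y * z, 2 * x * z, 2 * x * y,
                         2 * x, 2 * y, 2 * z, np.ones_like(x)])
    # scale for conditioning; the quadric is scale-equivariant
    scale = np.abs(samples).max()
    Ds = np.column_stack([x * x, y * y, z * z, 2 * y * z, 2 * x * z, 2 * x * y,
                          2 * x * scale, 2 * y * scale, 2 * z * scale,
                          np.full_like(x, scale * scale)])
    _, _, vt = np.linalg.svd(Ds, full_matrices=False)
    v = vt[-1]
    a, b_, c, f, g, h = v[:6]
    p, q, r = v[6:9] * scale
    d = v[9] * scale * scale

    M0 = np.array([[a, h, g], [h, b_, f], [g, f, c]])
    if np.trace(M0) < 0:
        M0, p, q, r, d = -M0, -p, -q, -r, -d
    eigvals = np.linalg.eigvalsh(M0)
    if eigvals.min() <= 0:
        raise CalibrationError(
            f"fitted quadric is not an ellipsoid (eigenvalues {eigvals.tolist()})")

    bvec = np.array([p, q, r])
    offset = -np.linalg.solve(M0, bvec)
    k = float(offset @ M0 @ offset) - d
    if k <= 0:
        raise CalibrationError("degenerate quadric: non-positive radius term")
    M = M0 / k
    w, Q = np.linalg.eigh(M)
    gain = target_norm * (Q * np.sqrt(w)) @ Q.T
    return CalibrationParams(offset=offset, gain=gain, target_norm=float(target_norm))


def apply_calibration(rec: Recording, params: CalibrationParams) -> Recording:
    """Map every sample through ``gain · (sample − offset)``; labels and
    times are untouched."""
    corrected = (rec.samples - params.offset) @ params.gain.T
    return rec.with_samples(corrected)


def norm_drift_diagnostic(rec: Recording, block_len: float,
                          target_norm: float | None = None,
                          threshold: float = 0.05) -> pd.DataFrame:
    """Per-block median sample norm, flagging drift off the target.

    Splits the recording into consecutive blocks of ``block_len`` seconds
    and reports each block's start time and median norm; blocks whose
    median deviates from ``target_norm`` by more than ``threshold``
    (relative, default 5%) are flagged.  ``target_norm`` defaults to the
    recording's field magnitude when available, else the overall median
    norm.
    """
    if block_len < 1.0:
        raise ValidationError("block length must be at least 1 s")
    if target_norm is None:
        target_norm = rec.field.magnitude if rec.field is not None else float(
            np.median(rec.norms()))
    norms = rec.norms()
    n_per_block = max(1, int(round(block_len * rec.fs)))
    starts = np.arange(0, len(norms), n_per_block)
    rows = []
    for s in starts:
        block = norms[s:s + n_per_block]
        med = float(np.median(block))
        rows.append({
            "block_time": s / rec.fs,
            "median_norm": med,
            "flagged": abs(med - target_norm) > threshold * target_norm,
        })
    return pd.DataFrame(rows)
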