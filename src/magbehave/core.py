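"""Core containers shared across the pipeline.

Conventions used throughout the package:

* Field magnitudes are in microtesla (μT), angles in degrees, time in
  seconds, sampling rates in Hz.
* The Earth frame has x along magnetic North, y along magnetic East and
  z pointing up; the dip (inclination) angle is positive when the field
  vector points above the horizontal plane.
* Sensor samples are stored as an ``(n, 3)`` array with columns
  ``(m_roll, m_pitch, m_yaw)``, the collar's body axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: The ethogram: the four behaviour classes recognised, in canonical order.
BEHAVIOURS: tuple[str, ...] = ("vigilance", "resting", "foraging", "running")

#: Behaviours with negligible body movement (first split of the hierarchy).
STATIC_BEHAVIOURS: frozenset[str] = frozenset({"vigilance", "resting"})
#: Behaviours with substantial body movement.
DYNAMIC_BEHAVIOURS: frozenset[str] = frozenset({"foraging", "running"})

#: Label used for unannotated samples.
NO_LABEL = ""


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class FieldModel:
    """Earth's magnetic field at a study site.

    Parameters
    ----------
    magnitude:
        Total field intensity in μT; must be positive.
    dip:
        Inclination angle in degrees, positive when the field points
        upward out of the horizontal plane (the convention at the
        Kalahari study site, where the field dips 65° upward).
    declination:
        Horizontal angle between magnetic and geographic North, degrees.
        Carried as metadata; simulated azimuths are measured from
        magnetic North, so declination does not enter the signal model.
    """

    magnitude: float
    dip: float
    declination: float = 0.0

    def __post_init__(self) -> None:
        if not self.magnitude > 0:
            raise ValidationError(f"field magnitude must be > 0, got {self.magnitude}")
        if not -90.0 <= self.dip <= 90.0:
            raise ValidationError(f"dip angle must lie in [-90, 90], got {self.dip}")

    @property
    def vertical(self) -> float:
        """Vertical field component, magnitude·sin(dip), μT (signed)."""
        return self.magnitude * float(np.sin(np.radians(self.dip)))

    @property
    def horizontal(self) -> float:
        """Horizontal field component, magnitude·cos(dip), μT."""
        return self.magnitude * float(np.cos(np.radians(self.dip)))

    def vector(self) -> np.ndarray:
        """Field vector in the magnetic-North/East/Up Earth frame."""
        return np.array([self.horizontal, 0.0, self.vertical])


def make_earth_field(magnitude: float, dip: float, declination: float = 0.0) -> FieldModel:
    """Construct a validated :class:`FieldModel`.

    >>> f = make_earth_field(27.3, 65.0, 17.9)
    >>> round(f.vertical, 2)
    24.74
    """
    return FieldModel(magnitude=magnitude, dip=dip, declination=declination)


@dataclass
class Recording:
    """One session of triaxial magnetometer data with per-sample labels.

    ``labels`` holds one behaviour name per sample (or :data:`NO_LABEL`
    for unannotated gaps).  Times must be uniform at ``1/fs``.
    """

    times: np.ndarray
    samples: np.ndarray  # (n, 3): m_roll, m_pitch, m_yaw, μT
    fs: float
    individual_id: str = "ind0"
    session_id: str = "sess0"
    labels: np.ndarray | None = None
    field: FieldModel | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValidationError(f"samples must be (n, 3), got {self.samples.shape}")
        if self.times.shape[0] != self.samples.shape[0]:
            raise ValidationError("times and samples length mismatch")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be > 0, got {self.fs}")
        if self.labels is None:
            self.labels = np.full(len(self.times), NO_LABEL, dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape[0] != self.times.shape[0]:
                raise ValidationError("labels and samples length mismatch")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValidationError("sample times must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.fs, rtol=1e-6, atol=1e-9):
                raise ValidationError("sample times must be uniform at 1/fs")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Span covered by the samples, in seconds (n/fs)."""
        return len(self.times) / self.fs

    def norms(self) -> np.ndarray:
        """Per-sample Euclidean norm ‖(m_roll, m_pitch, m_yaw)‖, μT."""
        return np.linalg.norm(self.samples, axis=1)

    def with_samples(self, samples: np.ndarray) -> "Recording":
        """Copy of this recording with replaced sample values."""
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class Window:
    """One single-label analysis segment (default 2 s → N = fs·2 samples)."""

    samples: np.ndarray  # (N, 3)
    label: str
    session_id: str
    individual_id: str
    start_time: float
    fs: float

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def roll(self) -> np.ndarray:
        return self.samples[:, 0]


def as_behaviour_array(labels: Sequence[str]) -> np.ndarray:
    """Validate that every label is one of the four behaviours."""
    arr = np.asarray(labels, dtype=object)
    bad = set(arr.tolist()) - set(BEHAVIOURS)
    if bad:
        raise ValidationError(f"unknown behaviour labels: {sorted(bad)}")
    return arr
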