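"""Forward model of collar magnetometer signals for four meerkat behaviours.

A triaxial magnetometer on a neck collar measures the projection of the
local geomagnetic field onto the sensor's roll/pitch/yaw axes.  Because
the field is constant in the Earth frame, the measured signal is a pure
function of sensor orientation: rotating the animal's neck sweeps the
field vector through the sensor frame, and with zero measurement noise
every sample lies on a sphere of radius equal to the field magnitude.

The simulator models the orientation trajectory of the collar with three
angles:

* *elevation* — angle of the roll axis above the horizontal plane.  In
  idealised bipedal vigilance the roll axis points straight up
  (elevation +90°, roll channel reads +|B|·sin δ); in curled-up resting
  straight down (−90°, roll channel reads −|B|·sin δ).
* *azimuth* α — heading of the roll axis from magnetic North.  When the
  roll axis is horizontal the roll channel reads |B|·cos δ·cos α, so an
  arbitrary heading confounds posture — the simulator reproduces this by
  letting α drift as a random walk during dynamic behaviours.
* *collar rotation* — rotation of the sensor about the neck (roll) axis;
  it varies between individuals because collars settle differently.

Behaviour archetypes:

* static (vigilance, resting): fixed elevation plus small
  Ornstein–Uhlenbeck angular tremor;
* foraging: aperiodic Ornstein–Uhlenbeck wander of elevation around the
  horizontal with a drifting azimuth — moderate angular velocity;
* running: sinusoidal elevation/azimuth oscillation at a stride
  frequency (default 3 Hz) — large, periodic signal oscillations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.signal import lfilter

from .core import (
    BEHAVIOURS,
    FieldModel,
    Recording,
    ValidationError,
    make_earth_field,
)

__all__ = [
    "BehaviourProfile",
    "IndividualParams",
    "DEFAULT_FIELD",
    "DEFAULT_PROFILES",
    "DEFAULT_MIX",
    "STUDY_NO_RESTING_SESSIONS",
    "orientation_to_samples",
    "simulate_recording",
    "make_schedule",
    "simulate_dataset",
    "make_study_dataset",
    "apply_sensor_distortion",
]

#: Geomagnetic field at the Kalahari study site (IGRF): 27.3 μT total
#: intensity, dip 65° pointing upward, declination 17.9° westwards.
DEFAULT_FIELD = make_earth_field(27.3, 65.0, -17.9)


@dataclass(frozen=True)
class BehaviourProfile:
    """Orientation-trajectory parameters for one behaviour archetype.

    Parameters
    ----------
    name:
        One of the four ethogram behaviours.
    elevation_mean:
        Mean roll-axis elevation above the horizontal plane, degrees.
    tremor_sd:
        Stationary SD of the Ornstein–Uhlenbeck angular tremor/wander on
        the elevation angle, degrees.
    ang_vel_scale:
        Scale of azimuthal drift, deg/s (random-walk step SD per second).
    osc_freq:
        Stride/oscillation frequency in Hz; 0 means aperiodic.
    osc_amp:
        Amplitude of the sinusoidal elevation/azimuth oscillation, degrees.
    tremor_tau:
        Correlation time of the OU tremor, seconds.
    """

    name: str
    elevation_mean: float
    tremor_sd: float
    ang_vel_scale: float
    osc_freq: float = 0.0
    osc_amp: float = 0.0
    tremor_tau: float = 0.6

    def __post_init__(self) -> None:
        if self.osc_freq < 0:
            raise ValidationError(f"oscillation frequency must be >= 0, got {self.osc_freq}")
        if self.tremor_sd < 0 or self.ang_vel_scale < 0 or self.osc_amp < 0:
            raise ValidationError("profile scales must be non-negative")


#: Default archetypes.  Static behaviours keep the roll axis near the
#: vertical with a few degrees of tremor; foraging wanders aperiodically
#: about the horizontal; running oscillates at a 3 Hz stride frequency
#: (plausible for small-mammal locomotion and below the 10 Hz low-pass
#: cut-off used downstream).
DEFAULT_PROFILES: dict[str, BehaviourProfile] = {
    "vigilance": BehaviourProfile("vigilance", elevation_mean=90.0, tremor_sd=6.0,
                                  ang_vel_scale=4.0),
    "resting": BehaviourProfile("resting", elevation_mean=-90.0, tremor_sd=5.0,
                                ang_vel_scale=1.0, tremor_tau=1.5),
    "foraging": BehaviourProfile("foraging", elevation_mean=0.0, tremor_sd=22.0,
                                 ang_vel_scale=40.0, tremor_tau=0.8),
    "running": BehaviourProfile("running", elevation_mean=0.0, tremor_sd=6.0,
                                ang_vel_scale=15.0, osc_freq=3.0, osc_amp=22.0),
}

#: Behaviour time-budget mix matching the skew of the field study:
#: foraging 56.2% of bouts, vigilance 38.2%, resting 4.6%, running 1%.
DEFAULT_MIX: dict[str, float] = {
    "foraging": 0.562,
    "vigilance": 0.382,
    "resting": 0.046,
    "running": 0.010,
}

#: Bout-duration ranges (s) used when drawing behaviour schedules.
_BOUT_RANGES: dict[str, tuple[float, float]] = {
    "vigilance": (6.0, 40.0),
    "resting": (30.0, 120.0),
    "foraging": (10.0, 60.0),
    "running": (3.0, 8.0),
}

#: 1-based session numbers without any resting behaviour in the study's
#: eleven-session structure.
STUDY_NO_RESTING_SESSIONS: frozenset[int] = frozenset({3, 4, 5, 8, 9, 10})


@dataclass(frozen=True)
class IndividualParams:
    """Per-individual variability applied on top of behaviour profiles."""

    collar_offset: float = 0.0  # deg, rotation of the sensor about the neck axis
    intensity_scale: float = 1.0  # multiplies tremor / oscillation amplitudes
    elevation_bias: float = 0.0  # deg, systematic posture offset

    @staticmethod
    def draw(rng: np.random.Generator) -> "IndividualParams":
        return IndividualParams(
            collar_offset=float(rng.uniform(0.0, 360.0)),
            intensity_scale=float(np.exp(rng.normal(0.0, 0.15))),
            elevation_bias=float(rng.normal(0.0, 4.0)),
        )


def _ou(n: int, sd: float, tau: float, dt: float, rng: np.random.Generator,
        x0: float = 0.0) -> np.ndarray:
    """Stationary-SD Ornstein–Uhlenbeck path via its exact AR(1) discretisation."""
    if n == 0:
        return np.empty(0)
    if sd == 0.0:
        return np.full(n, x0)
    a = math.exp(-dt / tau)
    w = rng.normal(0.0, sd * math.sqrt(1.0 - a * a), size=n)
    x, _ = lfilter([1.0], [1.0, -a], w, zi=np.array([a * x0]))
    return x


def orientation_to_samples(elevation: np.ndarray, azimuth: np.ndarray,
                           collar: np.ndarray, field: FieldModel) -> np.ndarray:
    """Project the Earth field onto the sensor axes for an orientation path.

    The sensor frame is built from the roll-axis direction (elevation,
    azimuth) and the collar-rotation angle about that axis; the returned
    ``(n, 3)`` array holds the components of the field along roll, pitch
    and yaw.  The frame is orthonormal, so sample norms equal the field
    magnitude exactly.
    """
    el = np.radians(np.asarray(elevation, dtype=float))
    az = np.radians(np.asarray(azimuth, dtype=float))
    co = np.radians(np.asarray(collar, dtype=float))

    cos_el, sin_el = np.cos(el), np.sin(el)
    cos_az, sin_az = np.cos(az), np.sin(az)

    # roll axis in the (North, East, Up) frame
    r = np.stack([cos_el * cos_az, cos_el * sin_az, sin_el], axis=1)
    # horizontal axis perpendicular to the roll axis' heading
    p0 = np.stack([-sin_az, cos_az, np.zeros_like(az)], axis=1)
    y0 = np.cross(r, p0)
    cc, sc = np.cos(co)[:, None], np.sin(co)[:, None]
    p = cc * p0 + sc * y0
    y = np.cross(r, p)

    b = field.vector()
    return np.stack([r @ b, p @ b, y @ b], axis=1)


def _bout_angles(behaviour: str, n: int, dt: float, profile: BehaviourProfile,
                 indiv: IndividualParams, rng: np.random.Generator,
                 azimuth0: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Elevation/azimuth/collar trajectories (deg) for one behaviour bout."""
    t = np.arange(n) * dt
    scale = indiv.intensity_scale
    tremor = _ou(n, profile.tremor_sd * scale, profile.tremor_tau, dt, rng)
    elevation = profile.elevation_mean + indiv.elevation_bias + tremor

    if profile.osc_freq > 0:
        # Stride oscillation engages all three rotation angles: the neck
        # pitches up and down, the heading sways, and the collar swings
        # about the neck axis.  How the stride energy splits across the
        # angles varies from bout to bout (gait, terrain, collar seating),
        # so no single sensor axis carries the periodicity reliably.
        phase = rng.uniform(0.0, 2.0 * np.pi)
        arg = 2.0 * np.pi * profile.osc_freq * t + phase
        amp = profile.osc_amp * scale
        a_el, a_az, a_co = rng.uniform(0.3, 1.0, size=3)
        osc = amp * a_el * np.sin(arg)
        elevation = elevation + osc
        az_osc = amp * a_az * np.sin(arg + np.pi / 2.0)
        co_osc = amp * a_co * np.sin(arg + rng.uniform(0.0, 2.0 * np.pi))
    else:
        az_osc = 0.0
        co_osc = 0.0

    if behaviour in ("foraging", "running"):
        # drifting heading: the arbitrary-azimuth confound
        steps = rng.normal(0.0, profile.ang_vel_scale * dt, size=n)
        azimuth = azimuth0 + np.cumsum(steps) + az_osc
    else:
        azimuth = azimuth0 + _ou(n, profile.ang_vel_scale * scale, 2.0, dt, rng)

    collar = indiv.collar_offset + co_osc + _ou(n, 0.3 * profile.tremor_sd * scale,
                                                profile.tremor_tau, dt, rng)
    return elevation, np.mod(azimuth, 360.0), collar


def simulate_recording(field: FieldModel,
                       schedule: list[tuple[str, float]],
                       profiles: dict[str, BehaviourProfile] | None = None,
                       individual: IndividualParams | None = None,
                       fs: float = 50.0,
                       noise_sd: float = 0.3,
                       seed: int | np.random.Generator | None = None,
                       individual_id: str = "ind0",
                       session_id: str = "sess0") -> Recording:
    """Simulate a labelled collar magnetometer recording.

    Parameters
    ----------
    field:
        Local geomagnetic field model.
    schedule:
        Sequence of ``(behaviour, duration_s)`` bouts, executed in order.
    profiles:
        Per-behaviour trajectory parameters (defaults to
        :data:`DEFAULT_PROFILES`).
    individual:
        Collar-rotation offset / intensity scaling for this animal.
    fs:
        Output sampling rate, Hz (the study's logger recorded at 50 Hz).
    noise_sd:
        Additive white Gaussian sensor noise per channel, μT.
    seed:
        Integer seed or a ``numpy`` Generator; identical seeds give
        identical recordings.
    """
    profiles = DEFAULT_PROFILES if profiles is None else profiles
    individual = individual or IndividualParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if fs <= 0:
        raise ValidationError(f"sampling rate must be > 0, got {fs}")
    for behaviour, duration in schedule:
        if behaviour not in BEHAVIOURS:
            raise ValidationError(f"unknown behaviour {behaviour!r}")
        if behaviour not in profiles:
            raise ValidationError(f"no profile for behaviour {behaviour!r}")
        if duration <= 0:
            raise ValidationError("bout durations must be > 0")
        prof = profiles[behaviour]
        if prof.osc_freq >= fs / 2.0:
            raise ValidationError(
                f"profile {behaviour!r} oscillates at {prof.osc_freq} Hz, "
                f"at/above Nyquist of {fs} Hz sampling")

    dt = 1.0 / fs
    azimuth = float(rng.uniform(0.0, 360.0))
    el_parts, az_parts, co_parts, labels = [], [], [], []
    for behaviour, duration in schedule:
        n = int(round(duration * fs))
        el, az, co = _bout_angles(behaviour, n, dt, profiles[behaviour],
                                  individual, rng, azimuth)
        if len(az):
            azimuth = float(az[-1])
        el_parts.append(el)
        az_parts.append(az)
        co_parts.append(co)
        labels.extend([behaviour] * n)

    elevation = np.concatenate(el_parts)
    az_all = np.concatenate(az_parts)
    collar = np.concatenate(co_parts)
    samples = orientation_to_samples(elevation, az_all, collar, field)
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, size=samples.shape)

    times = np.arange(len(samples)) * dt
    return Recording(times=times, samples=samples, fs=fs,
                     individual_id=individual_id, session_id=session_id,
                     labels=np.asarray(labels, dtype=object), field=field)


def make_schedule(total_duration: float, mix: dict[str, float],
                  rng: np.random.Generator,
                  min_bout: float = 3.0) -> list[tuple[str, float]]:
    """Draw a random bout schedule whose time budget matches ``mix``.

    Bout durations are drawn uniformly from behaviour-specific ranges and
    capped so each behaviour's total time matches its target share of
    ``total_duration``; consecutive identical behaviours are avoided when
    possible.
    """
    total_mix = sum(mix.values())
    remaining = {b: total_duration * p / total_mix for b, p in mix.items() if p > 0}
    schedule: list[tuple[str, float]] = []
    prev = None
    while remaining:
        choices = [b for b in remaining if b != prev] or list(remaining)
        weights = np.array([remaining[b] for b in choices])
        behaviour = choices[int(rng.choice(len(choices), p=weights / weights.sum()))]
        lo, hi = _BOUT_RANGES.get(behaviour, (5.0, 30.0))
        duration = min(float(rng.uniform(lo, hi)), remaining[behaviour])
        if remaining[behaviour] - duration < min_bout:
            duration = remaining[behaviour]
        duration = max(duration, min_bout)
        schedule.append((behaviour, duration))
        remaining[behaviour] -= duration
        if remaining[behaviour] <= 1e-9:
            del remaining[behaviour]
        prev = behaviour
    return schedule


def simulate_dataset(n_individuals: int = 10,
                     sessions_per_individual: int = 1,
                     seed: int | None = None,
                     *,
                     session_minutes: float = 30.0,
                     fs: float = 50.0,
                     field: FieldModel = DEFAULT_FIELD,
                     mix: dict[str, float] | None = None,
                     profiles: dict[str, BehaviourProfile] | None = None,
                     noise_sd: float = 0.3,
                     no_resting_sessions: frozenset[int] | set[int] = frozenset(),
                     ) -> list[Recording]:
    """Simulate a multi-individual dataset of labelled recordings.

    Sessions are numbered 1..n in generation order; sessions listed in
    ``no_resting_sessions`` have resting removed from their behaviour mix
    (its share redistributed proportionally), which exercises the LOIO
    session-discard rule downstream.  Each individual receives its own
    collar-rotation offset and intensity scaling.
    """
    if n_individuals < 1:
        raise ValidationError("need at least one individual")
    mix = DEFAULT_MIX if mix is None else mix
    rng = np.random.default_rng(seed)
    recordings: list[Recording] = []
    session_no = 0
    for i in range(n_individuals):
        indiv = IndividualParams.draw(rng)
        for _ in range(sessions_per_individual):
            session_no += 1
            session_mix = dict(mix)
            if session_no in no_resting_sessions:
                session_mix.pop("resting", None)
            schedule = make_schedule(session_minutes * 60.0, session_mix, rng)
            recordings.append(simulate_recording(
                field, schedule, profiles=profiles, individual=indiv, fs=fs,
                noise_sd=noise_sd, seed=rng,
                individual_id=f"ind{i + 1:02d}", session_id=f"sess{session_no:02d}"))
    return recordings


def make_study_dataset(seed: int | None = None, *,
                       session_minutes: float = 30.0,
                       fs: float = 50.0,
                       noise_sd: float = 0.3,
                       field: FieldModel = DEFAULT_FIELD,
                       profiles: dict[str, BehaviourProfile] | None = None,
                       ) -> list[Recording]:
    """Dataset mirroring the field study's session structure.

    Eleven sessions on ten individuals (sessions 4 and 7 recorded on the
    same individual); sessions {3, 4, 5, 8, 9, 10} contain no resting.
    Resting's overall time share is spread evenly over the five sessions
    that do contain it.
    """
    rng = np.random.default_rng(seed)
    n_sessions = 11
    session_to_individual = {s: s for s in range(1, n_sessions + 1)}
    session_to_individual[7] = 4  # one individual recorded twice
    # compress individual numbering to 1..10
    ids = sorted(set(session_to_individual.values()))
    renum = {old: new for new, old in enumerate(ids, start=1)}

    indiv_params = {new: IndividualParams.draw(rng) for new in renum.values()}
    resting_sessions = n_sessions - len(STUDY_NO_RESTING_SESSIONS)
    recordings = []
    for s in range(1, n_sessions + 1):
        mix = dict(DEFAULT_MIX)
        if s in STUDY_NO_RESTING_SESSIONS:
            mix.pop("resting")
        else:
            # concentrate resting so the dataset-wide share matches DEFAULT_MIX
            mix["resting"] = DEFAULT_MIX["resting"] * n_sessions / resting_sessions
        ind = renum[session_to_individual[s]]
        schedule = make_schedule(session_minutes * 60.0, mix, rng)
        recordings.append(simulate_recording(
            field, schedule, profiles=profiles, individual=indiv_params[ind],
            fs=fs, noise_sd=noise_sd, seed=rng,
            individual_id=f"ind{ind:02d}", session_id=f"sess{s:02d}"))
    return recordings


def apply_sensor_distortion(rec: Recording, hard_iron, soft_iron,
                            noise_sd: float = 0.0,
                            seed: int | None = None) -> Recording:
    """Distort a recording with hard-iron offset and soft-iron matrix.

    Each output sample is ``soft_iron @ sample + hard_iron`` plus optional
    Gaussian noise — the model an ellipsoid calibration must invert.
    """
    hard_iron = np.asarray(hard_iron, dtype=float).reshape(3)
    soft_iron = np.asarray(soft_iron, dtype=float).reshape(3, 3)
    if abs(np.linalg.det(soft_iron)) < 1e-12:
        raise ValidationError("soft-iron matrix must be invertible")
    out = rec.samples @ soft_iron.T + hard_iron
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return rec.with_samples(out)
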