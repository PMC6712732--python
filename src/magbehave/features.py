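"""The nine candidate features describing posture, intensity and periodicity.

Per 2-second window ``w`` of calibrated triaxial magnetometer data
(roll, pitch, yaw):

====================  ============================================================
meanRoll              mean of the roll channel (posture: ±|B|·sin δ when the
                      roll axis points up/down)
stdRoll               sample SD of the roll channel
meanAbsDiffRoll       mean |d/dt roll| (magnetometer-derived angular-velocity
                      proxy; movement intensity)
axMaxMeanAbsDiff      max over axes of the per-axis mean |d/dt|
avgMeanAbsDiff        mean over axes of the per-axis mean |d/dt|
rollFftPeakPower      peak power of the roll-channel spectrum
avgFftPeakPower       peak of the axis-averaged power spectrum
rollDiffFftPeakPower  peak power of the differentiated roll channel
avgDiffFftPeakPower   peak of the axis-averaged differentiated spectrum
====================  ============================================================

The spectral features z-normalise each series, taper it with a
Blackman-Harris window, zero-pad it by 100 samples on each side and
evaluate the DFT on a grid of spacing ``U`` (default 0.01 Hz, i.e.
``L = Fs/U = 10 000`` evaluation frequencies at 100 Hz); the feature is
the maximum squared coefficient over all non-DC frequencies.  Because of
the normalisation, peak power is a pure measure of spectral
concentration (periodicity), independent of signal amplitude.

Feature functions assume windows cut from an already low-pass-filtered
recording (the pipeline filters once per recording to avoid per-window
startup transients); :func:`power_spectrum` retains an ``apply_lowpass``
switch for standalone spectral analysis of raw series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import blackmanharris

from .core import ValidationError, Window
from .preprocessing import lowpass_filter, time_differentiate

__all__ = [
    "SpectrumConfig",
    "PowerSpectrum",
    "FEATURE_NAMES",
    "mean_roll",
    "std_roll",
    "mean_abs_diff_roll",
    "ax_max_mean_abs_diff",
    "avg_mean_abs_diff",
    "power_spectrum",
    "periodicity_feature",
    "extract_feature_matrix",
]


@dataclass(frozen=True)
class SpectrumConfig:
    """Configuration of the zero-padded, tapered DFT.

    ``resolution_hz`` is the evaluation-grid spacing U; the number of
    evaluation frequencies is ``L = fs / U`` and must be an integer.
    ``pad`` zeros are added before and after the tapered series.
    """

    resolution_hz: float = 0.01
    pad: int = 100
    taper: str = "blackmanharris"
    lowpass_order: int = 4
    lowpass_cutoff: float = 10.0

    def __post_init__(self) -> None:
        if self.resolution_hz <= 0:
            raise ValidationError("frequency resolution U must be > 0")
        if self.pad < 0:
            raise ValidationError("pad length must be >= 0")
        if self.taper != "blackmanharris":
            raise ValidationError(f"unsupported taper {self.taper!r}")

    def n_freqs(self, fs: float) -> int:
        """L = fs / U, the number of DFT evaluation frequencies."""
        L = fs / self.resolution_hz
        if abs(L - round(L)) > 1e-9:
            raise ValidationError(
                f"fs/U = {L} is not an integer; choose U dividing fs")
        return int(round(L))


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectrum on the U-spaced evaluation grid."""

    freqs: np.ndarray  # Hz, 0 .. fs/2
    power: np.ndarray  # squared DFT magnitudes (axis-averaged if triaxial)
    n_eval: int  # L, total DFT evaluation frequencies

    def peak_power(self) -> float:
        """Maximum power over non-DC frequencies."""
        return float(self.power[self.freqs > 0].max())

    def peak_frequency(self) -> float:
        """Frequency (Hz) of the non-DC power maximum."""
        mask = self.freqs > 0
        return float(self.freqs[mask][int(np.argmax(self.power[mask]))])


def mean_roll(win: Window) -> float:
    """Mean of the roll channel, μT (the posture feature)."""
    return float(win.roll.mean())


def std_roll(win: Window) -> float:
    """Sample standard deviation (ddof=1) of the roll channel, μT."""
    return float(win.roll.std(ddof=1))


def mean_abs_diff_roll(win: Window) -> float:
    """Mean absolute time-derivative of the roll channel, μT/s."""
    return float(np.abs(time_differentiate(win.roll, win.fs)).mean())


def _per_axis_mad(win: Window) -> np.ndarray:
    return np.abs(time_differentiate(win.samples, win.fs)).mean(axis=0)


def ax_max_mean_abs_diff(win: Window) -> float:
    """Maximum over the three axes of the mean absolute derivative, μT/s."""
    return float(_per_axis_mad(win).max())


def avg_mean_abs_diff(win: Window) -> float:
    """Mean over the three axes of the mean absolute derivative, μT/s."""
    return float(_per_axis_mad(win).mean())


def _normalise(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each column; returns (normalised, zero-variance mask)."""
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    dead = sd[0] < 1e-12
    safe = np.where(sd < 1e-12, 1.0, sd)
    return (x - mu) / safe, dead


def power_spectrum(series: np.ndarray, fs: float,
                   cfg: SpectrumConfig | None = None,
                   apply_lowpass: bool = True) -> PowerSpectrum:
    """Zero-padded, Blackman-Harris-tapered power spectrum of a window.

    ``series`` may be 1-D or ``(N, 3)``; triaxial input returns the
    axis-averaged power spectrum.  Pipeline per axis: optional low-pass
    (order/cut-off from ``cfg``) → z-normalisation → taper → zero-pad →
    DFT on the U-spaced grid → squared magnitudes.  A zero-variance
    series yields an all-zero spectrum.
    """
    cfg = cfg or SpectrumConfig()
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    # zero-variance guard on the input: a flat series has no periodicity,
    # and the filter's own startup transient must not masquerade as one
    dead_input = x.std(axis=0) < 1e-12
    if apply_lowpass:
        x = lowpass_filter(x, fs, order=cfg.lowpass_order, cutoff=cfg.lowpass_cutoff)
    L = cfg.n_freqs(fs)
    xn, dead = _normalise(x)
    dead = dead | dead_input
    taper = blackmanharris(x.shape[0])
    xt = xn * taper[:, None]
    padded = np.pad(xt, ((cfg.pad, cfg.pad), (0, 0)))
    if padded.shape[0] > L:
        raise ValidationError(
            f"padded window ({padded.shape[0]} samples) exceeds the DFT "
            f"evaluation length L = {L}")
    coef = np.fft.rfft(padded, n=L, axis=0)
    power = np.abs(coef) ** 2
    power[:, dead] = 0.0
    freqs = np.fft.rfftfreq(L, d=1.0 / fs)
    return PowerSpectrum(freqs=freqs, power=power.mean(axis=1), n_eval=L)


def periodicity_feature(win: Window, input: str = "raw", axes: str = "roll",
                        cfg: SpectrumConfig | None = None) -> float:
    """Peak spectral power of a window (the four periodicity features).

    ``input="differentiated"`` first applies the discrete time derivative;
    ``axes="triaxial"`` averages the per-axis power spectra before taking
    the maximum.  Windows are assumed already low-pass filtered.
    """
    if input not in ("raw", "differentiated"):
        raise ValidationError(f"unknown input kind {input!r}")
    if axes not in ("roll", "triaxial"):
        raise ValidationError(f"unknown axes selection {axes!r}")
    data = win.samples if axes == "triaxial" else win.roll
    if input == "differentiated":
        data = time_differentiate(data, win.fs)
    return power_spectrum(data, win.fs, cfg=cfg, apply_lowpass=False).peak_power()


_SPECTRAL_VARIANTS = {
    "rollFftPeakPower": ("raw", "roll"),
    "avgFftPeakPower": ("raw", "triaxial"),
    "rollDiffFftPeakPower": ("differentiated", "roll"),
    "avgDiffFftPeakPower": ("differentiated", "triaxial"),
}

_SCALAR_FEATURES = {
    "meanRoll": mean_roll,
    "stdRoll": std_roll,
    "meanAbsDiffRoll": mean_abs_diff_roll,
    "axMaxMeanAbsDiff": ax_max_mean_abs_diff,
    "avgMeanAbsDiff": avg_mean_abs_diff,
}

#: Canonical ordering of the nine candidate features.
FEATURE_NAMES: tuple[str, ...] = tuple(_SCALAR_FEATURES) + tuple(_SPECTRAL_VARIANTS)


def compute_feature(win: Window, name: str, cfg: SpectrumConfig | None = None) -> float:
    """Compute a single named feature for one window."""
    if name in _SCALAR_FEATURES:
        return _SCALAR_FEATURES[name](win)
    if name in _SPECTRAL_VARIANTS:
        kind, axes = _SPECTRAL_VARIANTS[name]
        return periodicity_feature(win, input=kind, axes=axes, cfg=cfg)
    raise ValidationError(f"unknown feature {name!r}")


def _batch_peak_powers(blocks: np.ndarray, fs: float, cfg: SpectrumConfig,
                       chunk: int = 256) -> dict[str, np.ndarray]:
    """Vectorised spectral features for uniformly sized windows.

    ``blocks`` is ``(n_windows, N, 3)``.  Returns peak powers for the
    four spectral variants.  Matches the per-window path exactly (same
    normalisation, taper, padding and DFT grid).
    """
    n_win, N, _ = blocks.shape
    L = cfg.n_freqs(fs)
    out = {name: np.empty(n_win) for name in _SPECTRAL_VARIANTS}
    diff = np.diff(blocks, axis=1) * fs
    for kind, data in (("raw", blocks), ("diff", diff)):
        taper = blackmanharris(data.shape[1])
        for lo in range(0, n_win, chunk):
            seg = data[lo:lo + chunk]
            mu = seg.mean(axis=1, keepdims=True)
            sd = seg.std(axis=1, keepdims=True)
            dead = (sd < 1e-12)
            xn = (seg - mu) / np.where(dead, 1.0, sd)
            xt = xn * taper[None, :, None]
            padded = np.pad(xt, ((0, 0), (cfg.pad, cfg.pad), (0, 0)))
            coef = np.fft.rfft(padded, n=L, axis=1)
            power = np.abs(coef) ** 2
            power[np.broadcast_to(dead, power.shape)] = 0.0
            nz = power[:, 1:, :]  # exclude DC
            roll_peak = nz[:, :, 0].max(axis=1)
            avg_peak = nz.mean(axis=2).max(axis=1)
            if kind == "raw":
                out["rollFftPeakPower"][lo:lo + chunk] = roll_peak
                out["avgFftPeakPower"][lo:lo + chunk] = avg_peak
            else:
                out["rollDiffFftPeakPower"][lo:lo + chunk] = roll_peak
                out["avgDiffFftPeakPower"][lo:lo + chunk] = avg_peak
    return out


def extract_feature_matrix(windows: list[Window],
                           feature_names: tuple[str, ...] | list[str] | None = None,
                           cfg: SpectrumConfig | None = None) -> pd.DataFrame:
    """Feature matrix: one row per window, one column per named feature.

    Metadata columns ``label``, ``session_id``, ``individual_id`` and
    ``start_time`` are appended.  Uses a vectorised fast path when all
    windows share the same length and sampling rate.
    """
    if not windows:
        raise ValidationError("window list is empty")
    names = tuple(feature_names) if feature_names is not None else FEATURE_NAMES
    unknown = set(names) - set(FEATURE_NAMES)
    if unknown:
        raise ValidationError(f"unknown features: {sorted(unknown)}")
    cfg = cfg or SpectrumConfig()

    cols: dict[str, np.ndarray] = {}
    uniform = (len({w.samples.shape[0] for w in windows}) == 1
               and len({w.fs for w in windows}) == 1)
    spectral_requested = [n for n in names if n in _SPECTRAL_VARIANTS]
    if uniform:
        blocks = np.stack([w.samples for w in windows])
        fs = windows[0].fs
        roll = blocks[:, :, 0]
        diff = np.diff(blocks, axis=1) * fs
        mad = np.abs(diff).mean(axis=1)
        scalar_vals = {
            "meanRoll": roll.mean(axis=1),
            "stdRoll": roll.std(axis=1, ddof=1),
            "meanAbsDiffRoll": mad[:, 0],
            "axMaxMeanAbsDiff": mad.max(axis=1),
            "avgMeanAbsDiff": mad.mean(axis=1),
        }
        spectral_vals = (_batch_peak_powers(blocks, fs, cfg)
                         if spectral_requested else {})
        for n in names:
            cols[n] = scalar_vals[n] if n in scalar_vals else spectral_vals[n]
    else:
        for n in names:
            cols[n] = np.array([compute_feature(w, n, cfg) for w in windows])

    fm = pd.DataFrame(cols)
    fm["label"] = [w.label for w in windows]
    fm["session_id"] = [w.session_id for w in windows]
    fm["individual_id"] = [w.individual_id for w in windows]
    fm["start_time"] = [w.start_time for w in windows]
    return fm
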