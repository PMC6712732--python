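"""Resampling, low-pass filtering, time differentiation and windowing.

The acquisition chain of the study this pipeline models is: magnetometer
logged at 50 Hz/axis, linearly resampled to 100 Hz/axis, low-pass
filtered with a 4th-order Butterworth at 10 Hz, and cut into 2-second
windows with 50% overlap; windows containing a behaviour transition are
excluded.  Time differentiation (first differences × sampling rate)
turns field components into a magnetometer-derived angular-velocity
proxy and is the basis of the movement-intensity features.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import NO_LABEL, Recording, ValidationError, Window

__all__ = [
    "resample_linear",
    "lowpass_filter",
    "filter_recording",
    "time_differentiate",
    "segment_windows",
]


def resample_linear(rec: Recording, target_fs: float) -> Recording:
    """Resample a recording to ``target_fs`` by linear interpolation.

    Output times run from the first input time at a uniform 1/target_fs
    spacing over the same span.  Labels are carried over from the input
    sample bracketing each new time on the left (half-open convention).
    """
    if target_fs <= 0:
        raise ValidationError("target sampling rate must be > 0")
    if len(rec) == 0:
        raise ValidationError("cannot resample an empty recording")
    t0, t1 = rec.times[0], rec.times[-1]
    n_out = int(np.floor((t1 - t0) * target_fs)) + 1
    new_times = t0 + np.arange(n_out) / target_fs
    new_samples = np.column_stack([
        np.interp(new_times, rec.times, rec.samples[:, k]) for k in range(3)])
    src = np.minimum(((new_times - t0) * rec.fs).astype(int), len(rec) - 1)
    new_labels = rec.labels[src]
    return Recording(times=new_times, samples=new_samples, fs=target_fs,
                     individual_id=rec.individual_id, session_id=rec.session_id,
                     labels=new_labels, field=rec.field)


def lowpass_filter(x: np.ndarray, fs: float, order: int = 4,
                   cutoff: float = 10.0, zero_phase: bool = False) -> np.ndarray:
    """Butterworth low-pass filter (DC gain 1) along the first axis.

    The default is a single forward (causal) pass; ``zero_phase=True``
    uses forward-backward filtering for phase-sensitive analyses.
    """
    if cutoff >= fs / 2.0:
        raise ValidationError(
            f"cut-off {cutoff} Hz must be below the Nyquist frequency {fs / 2} Hz")
    b, a = sps.butter(order, cutoff, btype="low", fs=fs)
    x = np.asarray(x, dtype=float)
    if zero_phase:
        return sps.filtfilt(b, a, x, axis=0)
    return sps.lfilter(b, a, x, axis=0)


def filter_recording(rec: Recording, order: int = 4, cutoff: float = 10.0,
                     zero_phase: bool = False) -> Recording:
    """Low-pass filter all three channels of a recording."""
    return rec.with_samples(lowpass_filter(rec.samples, rec.fs, order=order,
                                           cutoff=cutoff, zero_phase=zero_phase))


def time_differentiate(x: np.ndarray, fs: float) -> np.ndarray:
    """First differences of successive samples multiplied by the sampling
    rate — the discrete d/dt (units/s).  Output is one sample shorter."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 samples to differentiate")
    return np.diff(x, axis=0) * fs


def segment_windows(rec: Recording, window_len: float = 2.0,
                    overlap_frac: float = 0.5) -> list[Window]:
    """Cut a recording into fixed-length single-behaviour windows.

    Windows cover half-open spans ``[start, start + window_len)`` and
    start every ``window_len · (1 − overlap_frac)`` seconds.  A window is
    retained iff all of its samples carry the same (non-empty) behaviour
    label; windows containing a transition or unlabelled samples are
    dropped.  A window longer than the recording yields an empty list.
    """
    if window_len <= 0:
        raise ValidationError("window length must be > 0")
    if not 0.0 <= overlap_frac < 1.0:
        raise ValidationError("overlap fraction must lie in [0, 1)")
    n = int(round(window_len * rec.fs))
    stride = int(round(n * (1.0 - overlap_frac)))
    if stride < 1:
        raise ValidationError("stride below one sample; reduce overlap")
    windows: list[Window] = []
    labels = rec.labels
    for start in range(0, len(rec) - n + 1, stride):
        block_labels = labels[start:start + n]
        first = block_labels[0]
        if first == NO_LABEL or not (block_labels == first).all():
            continue
        windows.append(Window(
            samples=rec.samples[start:start + n].copy(),
            label=str(first),
            session_id=rec.session_id,
            individual_id=rec.individual_id,
            start_time=float(rec.times[start]),
            fs=rec.fs,
        ))
    return windows
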