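"""Instantaneous heart rate, HRV signal and time-domain stage parameters.

The instantaneous heart rate follows the time-varying IPFM reading of the
beat series: the beat-count function ``k(t)`` (cubic spline through the beat
times) is differentiated to give HR(t) in Hz, resampled at 4 Hz.  The mean
heart rate mHR is its 0.03 Hz zero-phase low-pass, and HRV = HR - mHR by
construction; with the ``normalized`` flag the modulating-signal estimate
(HR - mHR)/mHR is returned instead, compensating the mean-rate influence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .filters import lowpass_zero_phase

__all__ = ["HrvSignals", "TimeParams", "instantaneous_hr", "split_hrv",
           "time_params"]


@dataclass
class HrvSignals:
    t: np.ndarray
    hr: np.ndarray    # Hz
    mhr: np.ndarray   # Hz
    hrv: np.ndarray   # Hz (or dimensionless when normalized)
    fs: float = 4.0


@dataclass
class TimeParams:
    nn_median: float   # s
    nn_iqr: float      # s
    rmssd: float       # s
    pnn50: float       # %


def instantaneous_hr(beat_times: np.ndarray, fs_out: float = 4.0,
                     t_start: float | None = None,
                     t_end: float | None = None,
                     max_gap: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous HR(t) in Hz on a ``fs_out`` grid from beat times.

    Gaps longer than ``max_gap`` seconds are bridged by the spline and
    reported via a warning.  A constant 1 s rhythm maps to HR = 1 Hz.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size < 4:
        raise ValueError("need at least 4 beats")
    if np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat times must be strictly increasing")
    if np.max(np.diff(beat_times)) > max_gap:
        import warnings
        warnings.warn("gap > 3 s bridged by interpolation", stacklevel=2)
    counts = np.arange(beat_times.size, dtype=float)
    spline = CubicSpline(beat_times, counts)
    lo = beat_times[0] if t_start is None else t_start
    hi = beat_times[-1] if t_end is None else t_end
    n0 = int(np.ceil(lo * fs_out))
    n1 = int(np.floor(hi * fs_out))
    t = np.arange(n0, n1 + 1) / fs_out
    tc = np.clip(t, beat_times[0], beat_times[-1])
    hr = spline.derivative()(tc)
    return t, np.maximum(hr, 1e-6)


def split_hrv(t: np.ndarray, hr: np.ndarray, fs: float = 4.0,
              cutoff: float = 0.03, normalized: bool = False) -> HrvSignals:
    """Split HR into mean trend (0.03 Hz zero-phase low-pass) and HRV.

    ``HRV = HR - mHR`` exactly (the three signals share the time base and
    reconstruct additively); ``normalized=True`` returns the modulating
    estimate (HR - mHR)/mHR instead.
    """
    hr = np.asarray(hr, dtype=float)
    if hr.size < 2 * fs / cutoff / 8:
        raise ValueError("record too short for the 0.03 Hz trend filter")
    mhr = lowpass_zero_phase(hr, fs, cutoff)
    hrv = hr - mhr
    if normalized:
        hrv = hrv / np.maximum(mhr, 1e-9)
    return HrvSignals(t=np.asarray(t, dtype=float), hr=hr, mhr=mhr, hrv=hrv,
                      fs=fs)


def time_params(nn: np.ndarray, nn_times: np.ndarray | None = None,
                window: tuple[float, float] | None = None,
                pnn50_denominator: str = "intervals",
                min_intervals: int = 30) -> TimeParams:
    """Time-domain HRV parameters over a stage window.

    ``window = (t_lo, t_hi)`` selects the NN intervals whose end-beat time
    falls inside it (the per-stage convention is the final 240 s of the
    stage).  pNN50 counts successive-interval pairs differing by more than
    50 ms; its denominator is the NN-interval count by default (the
    ``"differences"`` option uses the pair count instead).
    """
    nn = np.asarray(nn, dtype=float)
    if window is not None:
        if nn_times is None:
            raise ValueError("window selection needs nn_times")
        m = (nn_times >= window[0]) & (nn_times <= window[1])
        nn = nn[m]
    if nn.size < min_intervals:
        raise ValueError(f"too few intervals in window ({nn.size})")
    d = np.diff(nn)
    n_over = int(np.sum(np.abs(d) > 0.050))
    denom = nn.size if pnn50_denominator == "intervals" else max(d.size, 1)
    q1, q3 = np.percentile(nn, [25, 75])
    return TimeParams(
        nn_median=float(np.median(nn)),
        nn_iqr=float(q3 - q1),
        rmssd=float(np.sqrt(np.mean(d ** 2))) if d.size else 0.0,
        pnn50=100.0 * n_over / denom,
    )
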