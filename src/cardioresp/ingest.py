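"""ECG preprocessing: baseline removal, beat detection, ectopic correction.

The beat detector is a derivative/adaptive-threshold (Pan-Tompkins-style)
detector; the analysis contract downstream is only the beat times, so the
detector family is interchangeable.  Q and S fiducials are located as the
minima in fixed search windows around each R peak.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .filters import remove_trend
from .records import BeatAnnotations, EcgRecord

__all__ = ["remove_baseline", "detect_beats", "correct_ectopics",
           "nn_intervals"]


def remove_baseline(record: EcgRecord, cutoff: float = 0.03) -> EcgRecord:
    """Subtract the zero-phase low-pass (default 0.03 Hz) baseline per lead."""
    min_len = int(2 * record.fs / cutoff) // 8
    if record.n_samples < min_len:
        raise ValueError("record shorter than twice the baseline filter span")
    leads = np.vstack([remove_trend(ld, record.fs, cutoff)
                       for ld in record.leads])
    return EcgRecord(leads=leads, fs=record.fs, stages=list(record.stages),
                     subject_id=record.subject_id)


def detect_beats(lead: np.ndarray, fs: float,
                 refractory: float = 0.25,
                 q_window: tuple[float, float] = (0.060, 0.004),
                 s_window: tuple[float, float] = (0.004, 0.100),
                 ) -> BeatAnnotations:
    """Detect R peaks and locate Q/S fiducials on a baseline-removed lead.

    Pipeline: band-pass 5-25 Hz, differentiate, square, 150 ms moving-window
    integration, adaptive threshold with a refractory period; the R peak is
    refined as the signal maximum within +/-60 ms of each envelope peak.
    Q = minimum in [R-60 ms, R-4 ms]; S = minimum in [R+4 ms, R+100 ms].
    """
    lead = np.asarray(lead, dtype=float)
    n = lead.size
    if n < int(0.5 * fs) or np.ptp(lead) == 0:
        warnings.warn("no beats found", stacklevel=2)
        return BeatAnnotations(r_times=np.empty(0), q_times=np.empty(0),
                               s_times=np.empty(0))
    sos = signal.butter(3, [5.0, min(25.0, 0.45 * fs)], btype="band", fs=fs,
                        output="sos")
    bp = signal.sosfiltfilt(sos, lead)
    env = np.convolve(np.gradient(bp) ** 2,
                      np.ones(int(0.150 * fs)) / int(0.150 * fs), mode="same")
    thr = 0.15 * np.median(
        np.sort(env)[-max(10, int(n / fs)):])  # fraction of typical peak level
    peaks, _ = signal.find_peaks(env, height=thr,
                                 distance=max(1, int(refractory * fs)))
    if peaks.size == 0:
        warnings.warn("no beats found", stacklevel=2)
        return BeatAnnotations(r_times=np.empty(0), q_times=np.empty(0),
                               s_times=np.empty(0))
    half = int(0.060 * fs)
    r_idx = []
    for p in peaks:
        lo, hi = max(0, p - half), min(n, p + half + 1)
        r_idx.append(lo + int(np.argmax(lead[lo:hi])))
    r_idx = np.unique(np.asarray(r_idx, dtype=int))
    # enforce refractory after refinement
    keep = [0]
    for i in range(1, r_idx.size):
        if r_idx[i] - r_idx[keep[-1]] >= int(refractory * fs):
            keep.append(i)
        elif lead[r_idx[i]] > lead[r_idx[keep[-1]]]:
            keep[-1] = i
    r_idx = r_idx[keep]

    q_idx = np.empty(r_idx.size, dtype=int)
    s_idx = np.empty(r_idx.size, dtype=int)
    for i, r in enumerate(r_idx):
        lo = max(0, r - int(q_window[0] * fs))
        hi = max(lo + 1, r - int(q_window[1] * fs))
        q_idx[i] = lo + int(np.argmin(lead[lo:hi]))
        lo = min(n - 2, r + int(s_window[0] * fs))
        hi = min(n, r + int(s_window[1] * fs))
        s_idx[i] = lo + int(np.argmin(lead[lo:hi]))
    return BeatAnnotations(r_times=r_idx / fs, q_times=q_idx / fs,
                           s_times=s_idx / fs)


def nn_intervals(beats: BeatAnnotations) -> np.ndarray:
    """Raw RR intervals (s) from the R-peak times."""
    return np.diff(beats.r_times)


def correct_ectopics(beats: BeatAnnotations, factor: float = 0.3,
                     window: int = 5,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normal-to-normal interval series after ectopic/artifact correction.

    Intervals deviating from a running median (``window`` intervals) by more
    than ``factor`` times that median are flagged and replaced by cubic-spline
    interpolation over the unflagged intervals (value-wise; a false detection
    splitting a 1.0 s interval yields two corrected ~1.0 s intervals).

    Returns ``(nn, nn_times, flagged)`` where ``nn_times`` are the end-beat
    times of each interval.  Idempotent on clean series; emits a
    record-quality warning when more than 20% of intervals are flagged.
    """
    if beats.n_beats < 3:
        raise ValueError("need at least 3 beats")
    rr = np.diff(beats.r_times)
    t_rr = beats.r_times[1:]
    n = rr.size
    med = np.empty(n)
    half = window // 2
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        med[i] = np.median(rr[lo:hi])
    flagged = np.abs(rr - med) > factor * med
    # a window dominated by its own outliers: fall back to global median
    if flagged.all():
        flagged = np.abs(rr - np.median(rr)) > factor * np.median(rr)
    if flagged.mean() > 0.20:
        warnings.warn(
            f"{100 * flagged.mean():.0f}% of intervals flagged: poor record "
            "quality", stacklevel=2)
    nn = rr.copy()
    if flagged.any() and (~flagged).sum() >= 2:
        good = ~flagged
        if good.sum() >= 4:
            from scipy.interpolate import CubicSpline
            cs = CubicSpline(t_rr[good], rr[good])
            nn[flagged] = cs(t_rr[flagged])
        else:
            nn[flagged] = np.interp(t_rr[flagged], t_rr[good], rr[good])
    return nn, t_rr, flagged
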