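"""Zero-phase filtering helpers shared across the pipeline.

All filters are applied forward-backward (``filtfilt``) so fiducial timing is
never phase-shifted.  The very-low-frequency low-passes (0.03 Hz baseline /
mean-heart-rate trends) use a 4th-order Butterworth: at these cutoffs a
linear-phase FIR with a usable transition band would exceed typical record
lengths.  The respiration band-pass is a Kaiser-window FIR sized for >= 40 dB
stop-band attenuation at the spec'd stop edges.
"""

from __future__ import annotations

import numpy as np
from scipy import signal


def lowpass_zero_phase(x: np.ndarray, fs: float, cutoff: float,
                       order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass of ``x`` sampled at ``fs`` Hz."""
    x = np.asarray(x, dtype=float)
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    padlen = min(x.size - 1, 3 * int(fs / cutoff))
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def remove_trend(x: np.ndarray, fs: float, cutoff: float = 0.03) -> np.ndarray:
    """Return ``x`` minus its zero-phase low-pass trend (cutoff in Hz)."""
    return x - lowpass_zero_phase(x, fs, cutoff)


def bandpass_fir_zero_phase(x: np.ndarray, fs: float,
                            f_lo: float = 0.07, f_hi: float = 1.0,
                            stop_lo: float = 0.04, stop_hi: float = 1.2,
                            atten_db: float = 40.0) -> np.ndarray:
    """Zero-phase Kaiser-window FIR band-pass.

    Taps are sized from the narrower of the two transition bands so the
    stop-band attenuation target holds at both ``stop_lo`` and ``stop_hi``.
    """
    x = np.asarray(x, dtype=float)
    width = min(f_lo - stop_lo, stop_hi - f_hi)
    if width <= 0:
        raise ValueError("stop edges must lie outside the pass band")
    numtaps, beta = signal.kaiserord(atten_db, width / (0.5 * fs))
    numtaps |= 1  # odd length -> symmetric, integer group delay
    if x.size <= 3 * numtaps:
        # short record: fall back to the longest filter filtfilt can pad
        numtaps = max(5, (x.size // 3) | 1)
    taps = signal.firwin(numtaps, [f_lo, f_hi], pass_zero=False, fs=fs,
                         window=("kaiser", beta))
    padlen = min(x.size - 1, 3 * numtaps)
    return signal.filtfilt(taps, [1.0], x, padlen=padlen)
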