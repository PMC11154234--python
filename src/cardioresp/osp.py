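"""Orthogonal subspace projection of HRV onto the respiratory subspace.

The respiratory subspace ``V`` holds the (mean-centred) respiration signal
and its delayed copies; projecting HRV onto span(V) yields the respiratory
component HRV_R (everything linearly explained by respiration, the
respiratory-sinus-arrhythmia channel) and the residual HRV_perp = HRV -
HRV_R (sympathetic and non-respiratory vagal dynamics).  Because the split
is an orthogonal projection, ``P_R + P_perp = 1`` under the relative-power
normalisation, and the residual's LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz)
band powers can be read without excluding subjects whose respiratory rate
leaves the classical HF band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["OspDecomposition", "FreqParams", "build_resp_subspace",
           "project", "component_powers"]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass
class OspDecomposition:
    hrv: np.ndarray        # trimmed, centred HRV segment
    hrv_r: np.ndarray      # respiratory component
    hrv_perp: np.ndarray   # residual
    v: np.ndarray          # subspace matrix actually used
    fs: float = 4.0


@dataclass
class FreqParams:
    p_r: float        # relative power of the respiratory component, a.u.
    p_perp: float     # relative power of the residual, a.u.
    p_lf_perp: float  # residual LF power / total HRV power, a.u.
    p_hf_perp: float  # residual HF power / total HRV power, a.u.


def build_resp_subspace(resp: np.ndarray, max_delay: int = 40) -> np.ndarray:
    """Delay-embedded respiration matrix (columns: lags 0..max_delay).

    Edge rows are trimmed so every column is fully populated, then each
    column is mean-centred.  Raises on a (numerically) constant respiration.
    """
    resp = np.asarray(resp, dtype=float)
    n = resp.size - max_delay
    if n <= max_delay + 1:
        raise ValueError("window too short for the requested delay span")
    cols = [resp[max_delay - d:max_delay - d + n] for d in range(max_delay + 1)]
    v = np.column_stack(cols)
    v = v - v.mean(axis=0)
    if np.max(np.abs(v)) < 1e-12:
        raise ValueError("respiration signal is constant; subspace is empty")
    return v


def project(hrv: np.ndarray, v: np.ndarray, rcond: float = 1e-10,
            fs: float = 4.0) -> OspDecomposition:
    """Least-squares projection of HRV onto span(V).

    ``hrv`` longer than V's row count is tail-trimmed symmetrically with the
    delay-embedding convention (the first ``len(hrv) - rows`` samples are
    dropped, matching the rows removed when embedding).  The pseudoinverse
    handles rank deficiency (e.g. a sinusoidal respiration of rank 2).
    """
    hrv = np.asarray(hrv, dtype=float)
    if hrv.size < v.shape[0]:
        raise ValueError("HRV shorter than the subspace rows")
    hrv = hrv[hrv.size - v.shape[0]:]
    hrv = hrv - hrv.mean()
    beta, *_ = np.linalg.lstsq(v, hrv, rcond=rcond)
    hrv_r = v @ beta
    return OspDecomposition(hrv=hrv, hrv_r=hrv_r, hrv_perp=hrv - hrv_r, v=v,
                            fs=fs)


def component_powers(decomp: OspDecomposition,
                     normalize_bands_by: str = "total") -> FreqParams:
    """Relative component powers and residual LF/HF band powers.

    ``P_R`` and ``P_perp`` are the squared-norm fractions of the two
    components (they sum to 1 by orthogonality).  The residual band powers
    integrate the Welch PSD of HRV_perp over 0.04-0.15 / 0.15-0.4 Hz,
    normalised by total HRV power (``normalize_bands_by="residual"``
    switches to residual power).
    """
    total = float(np.sum(decomp.hrv ** 2))
    if total <= 0:
        raise ValueError("zero-power HRV window")
    p_r = float(np.sum(decomp.hrv_r ** 2)) / total
    p_perp = float(np.sum(decomp.hrv_perp ** 2)) / total
    n = decomp.hrv_perp.size
    nper = min(n, int(64 * decomp.fs))
    f, psd = signal.welch(decomp.hrv_perp, fs=decomp.fs, window="hann",
                          nperseg=nper, noverlap=nper // 2,
                          nfft=max(1024, nper), detrend="constant")
    var_perp = float(np.mean(decomp.hrv_perp ** 2))
    var_total = float(np.mean(decomp.hrv ** 2))

    def band(lo, hi):
        m = (f >= lo) & (f <= hi)
        return float(np.trapezoid(psd[m], f[m]))

    ref = var_total if normalize_bands_by == "total" else max(var_perp, 1e-30)
    return FreqParams(p_r=p_r, p_perp=p_perp,
                      p_lf_perp=band(*LF_BAND) / ref,
                      p_hf_perp=band(*HF_BAND) / ref)
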