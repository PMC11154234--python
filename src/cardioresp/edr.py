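"""ECG-derived respiration (EDR) from R-wave slopes and angle.

Respiration modulates QRS morphology; three beat-indexed series per lead
capture it: the R-wave up-slope ``I_US`` (least-squares line over an 8 ms
window centred on the steepest rising point between Q and R), the down-slope
``I_DS`` (steepest falling point between R and S) and the R-wave angle

    phi_R = arctan( (I_US - I_DS) / (0.4 * (6.25 + I_US * I_DS)) ),

the smallest angle between the two fitted lines once slopes are expressed in
mV/ms (the constants 0.4 and 6.25 are bound to that unit choice: the formula
equals the angle between lines of slopes I_US/2.5 and I_DS/2.5).

The beat-indexed series are cleaned by MAD outlier rejection, cubic-spline
resampled to 4 Hz and band-passed to 0.07-1 Hz; with three leads this yields
the nine EDR signals fused downstream.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .filters import bandpass_fir_zero_phase
from .records import BeatAnnotations, EcgRecord, EdrSignal

__all__ = ["locate_slope_points", "fit_slopes", "rwave_angle",
           "build_edr_signals", "slope_series", "record_edr_signals"]

EDR_KINDS = ("Us", "Ds", "Ra")


def locate_slope_points(lead: np.ndarray, fs: float, beats: BeatAnnotations,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Steepest-variation sample indices on the QRS flanks.

    ``n_U`` maximizes the lead derivative on [n_Q, n_R]; ``n_D`` maximizes
    its magnitude (minimizes the derivative) on [n_R, n_S] — the literal
    maximum there would sit at the interval edge for an upright QRS.  Ties
    break to the earliest sample.  Beats with a degenerate window are
    dropped (the returned ``valid`` mask indexes ``beats``).
    """
    lead = np.asarray(lead, dtype=float)
    deriv = np.gradient(lead) * fs  # mV/s
    nq = np.round(beats.q_times * fs).astype(int)
    nr = np.round(beats.r_times * fs).astype(int)
    ns = np.round(beats.s_times * fs).astype(int)
    n_u = np.empty(nr.size, dtype=int)
    n_d = np.empty(nr.size, dtype=int)
    valid = np.ones(nr.size, dtype=bool)
    for i in range(nr.size):
        if nq[i] >= nr[i] or nr[i] >= ns[i]:
            valid[i] = False
            continue
        seg = deriv[nq[i]:nr[i] + 1]
        # earliest sample within float jitter of the maximum (documented
        # tie-break; exact ties occur on piecewise-linear flanks)
        tol = 1e-9 * max(np.max(np.abs(seg)), 1e-30)
        n_u[i] = nq[i] + int(np.flatnonzero(seg >= seg.max() - tol)[0])
        seg = deriv[nr[i]:ns[i] + 1]
        tol = 1e-9 * max(np.max(np.abs(seg)), 1e-30)
        n_d[i] = nr[i] + int(np.flatnonzero(seg <= seg.min() + tol)[0])
    return n_u[valid], n_d[valid], valid


def fit_slopes(lead: np.ndarray, fs: float, n_u: np.ndarray, n_d: np.ndarray,
               window_ms: float = 8.0,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares line slopes (mV/ms) in 8 ms windows centred on n_U/n_D.

    The window is the nearest odd sample count spanning ``window_ms``.
    Beats whose window is truncated by the record edge are dropped (mask
    returned).
    """
    lead = np.asarray(lead, dtype=float)
    half = max(1, int(round(window_ms / 2 * 1e-3 * fs)))
    k = np.arange(-half, half + 1)
    denom = np.sum(k.astype(float) ** 2)
    i_us = np.empty(n_u.size)
    i_ds = np.empty(n_u.size)
    valid = np.ones(n_u.size, dtype=bool)
    for i, (u, d) in enumerate(zip(n_u, n_d)):
        if u - half < 0 or d + half >= lead.size:
            valid[i] = False
            continue
        yu = lead[u - half:u + half + 1]
        yd = lead[d - half:d + half + 1]
        # OLS slope with centred abscissa: sum(k*y)/sum(k^2), per sample
        i_us[i] = np.dot(k, yu - yu.mean()) / denom * fs / 1000.0
        i_ds[i] = np.dot(k, yd - yd.mean()) / denom * fs / 1000.0
    return i_us[valid], i_ds[valid], valid


def rwave_angle(i_us, i_ds):
    """R-wave angle (rad) from the up/down slopes in mV/ms.

    Total in both arguments; a vanishing denominator (``I_US * I_DS =
    -6.25``) is the perpendicular-lines limit, phi_R = pi/2.
    """
    i_us = np.asarray(i_us, dtype=float)
    i_ds = np.asarray(i_ds, dtype=float)
    num = i_us - i_ds
    den = 0.4 * (6.25 + i_us * i_ds)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(den == 0.0, np.pi / 2, np.arctan(num / np.where(den == 0, 1.0, den)))
    return phi if phi.ndim else float(phi)


def slope_series(lead: np.ndarray, fs: float, beats: BeatAnnotations):
    """Per-beat (t, I_US, I_DS, phi_R) for one lead.

    Combines fiducial location and slope fitting; returns the beat times of
    the retained beats alongside the three morphology series.
    """
    n_u, n_d, v1 = locate_slope_points(lead, fs, beats)
    t = beats.r_times[v1]
    i_us, i_ds, v2 = fit_slopes(lead, fs, n_u, n_d)
    t = t[v2]
    return t, i_us, i_ds, rwave_angle(i_us, i_ds)


def build_edr_signals(values: np.ndarray, beat_times: np.ndarray,
                      kind: str, lead: int,
                      fs_out: float = 4.0, mad_factor: float = 5.0,
                      f_band: tuple[float, float] = (0.07, 1.0),
                      t_start: float | None = None,
                      t_end: float | None = None) -> EdrSignal:
    """Condition one beat-indexed morphology series into an EDR signal.

    MAD outlier rejection (|x - median| > ``mad_factor`` * MAD), cubic-spline
    resampling onto the record-aligned 4 Hz grid, then a zero-phase FIR
    band-pass confined to the plausible respiratory band.
    """
    values = np.asarray(values, dtype=float)
    beat_times = np.asarray(beat_times, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 beats for an EDR signal")
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        keep = np.ones(values.size, dtype=bool)
    else:
        keep = np.abs(values - med) <= mad_factor * mad
    if keep.sum() < 4:
        raise ValueError("all EDR samples rejected as outliers")
    cs = CubicSpline(beat_times[keep], values[keep])
    lo = beat_times[keep][0] if t_start is None else t_start
    hi = beat_times[keep][-1] if t_end is None else t_end
    n0 = int(np.ceil(lo * fs_out))
    n1 = int(np.floor(hi * fs_out))
    grid = np.arange(n0, n1 + 1) / fs_out
    x = cs(np.clip(grid, beat_times[keep][0], beat_times[keep][-1]))
    x = bandpass_fir_zero_phase(x, fs_out, f_band[0], f_band[1])
    return EdrSignal(kind=kind, lead=lead, samples=x, t0=n0 / fs_out,
                     fs=fs_out)


def record_edr_signals(record: EcgRecord, beats: BeatAnnotations,
                       **kwargs) -> list[EdrSignal]:
    """The nine EDR signals of a 3-lead record (3 leads x Us/Ds/Ra)."""
    out: list[EdrSignal] = []
    t_end = record.duration
    for li in range(record.n_leads):
        t, i_us, i_ds, phi = slope_series(record.leads[li], record.fs, beats)
        for kind, vals in (("Us", i_us), ("Ds", i_ds), ("Ra", phi)):
            out.append(build_edr_signals(vals, t, kind, li, t_start=0.0,
                                         t_end=t_end, **kwargs))
    return out
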