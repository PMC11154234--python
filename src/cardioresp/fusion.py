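"""Respiratory-rate estimation by peaked-conditioned spectral fusion.

Every 5 s, each of the nine EDR signals contributes a Welch power spectral
density from the trailing 40 s window (12 s sub-windows, 50% overlap,
zero-padded to a <= 0.005 Hz grid).  Around the previous rate estimate
``F_R(k-1)`` a reference interval ``Omega_R = [F_R(k-1) - delta,
F_R(k-1) + 2*delta]`` (delta = 0.1 Hz) is searched: among the local maxima
reaching 85% of the global peak height, the one nearest the previous
estimate is selected, and its *peakness* — the percentage of Omega_R power
concentrated within +/-0.05 Hz of it — gates which spectra are averaged.
Spectra from the ``2*L_s + 1`` neighbouring windows (L_s = 2, so at most
five per EDR signal) whose peakness passes both criteria are summed into the
fused spectrum, whose argmax over Omega_R is the new estimate.

An empty selection is a defined fallback: the previous fused spectrum and
rate are held.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .records import EdrSignal

__all__ = ["FusionConfig", "SpectrumWindow", "RespRateTrack",
           "welch_spectrum", "select_peak", "fuse_spectra", "estimate_fr",
           "respiratory_rate_track"]


@dataclass
class FusionConfig:
    fs: float = 4.0
    window: float = 40.0        # s, running analysis window
    step: float = 5.0           # s, estimate cadence
    subwindow: float = 12.0     # s, Welch sub-window (50% overlap)
    nfft: int = 1024            # zero-padded grid: 4/1024 < 0.005 Hz
    band: tuple[float, float] = (0.07, 1.0)
    delta: float = 0.1          # Hz, reference-interval half-structure
    peak_frac: float = 0.85     # candidate peaks >= 85% of global peak
    #: +/- window defining peakness, Hz.  Matched to the ~0.17 Hz-wide
    #: mainlobe of the 12 s Hann sub-windows: a narrower window cannot reach
    #: the 85% gate even for a noiseless sinusoid.
    peakness_halfwidth: float = 0.10
    peakness_thresh: float = 85.0     # %, criterion A
    lam: float = 0.05           # criterion B margin
    criterion_b: str = "peakness"     # "peakness" (default) or "power"
    n_pool: int = 2             # L_s
    causal: bool = False        # pool l in [0, 2*L_s] instead of [-L_s, L_s]
    max_gap_frac: float = 0.25  # unusable window threshold


@dataclass
class SpectrumWindow:
    j: int
    k: int
    psd: np.ndarray
    usable: bool = True
    f_i: float | None = None
    f_ii: float | None = None
    peakness: float = 0.0
    chi_a: bool = False
    chi_b: bool = False


@dataclass
class RespRateTrack:
    t: np.ndarray                 # s, window centres
    f_r: np.ndarray               # Hz
    n_averaged: np.ndarray        # spectra pooled per estimate
    freqs: np.ndarray | None = None
    fused: list = field(default_factory=list)


def welch_spectrum(x: np.ndarray, cfg: FusionConfig | None = None,
                   ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Welch PSD of one 40 s EDR window; returns (freqs, psd, usable).

    Windows with more than ``max_gap_frac`` rejected (NaN) samples are
    flagged unusable; smaller gaps are linearly bridged.
    """
    cfg = cfg or FusionConfig()
    x = np.asarray(x, dtype=float)
    bad = ~np.isfinite(x)
    usable = bad.mean() <= cfg.max_gap_frac
    if bad.any() and usable:
        idx = np.arange(x.size)
        x = np.interp(idx, idx[~bad], x[~bad])
    elif bad.any():
        x = np.where(bad, 0.0, x)
    nper = int(cfg.subwindow * cfg.fs)
    f, p = signal.welch(x, fs=cfg.fs, window="hann", nperseg=nper,
                        noverlap=nper // 2, nfft=cfg.nfft, detrend="constant")
    return f, p, usable


def _band_power(f: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    m = (f >= lo) & (f <= hi)
    if m.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[m], f[m]))


def select_peak(f: np.ndarray, psd: np.ndarray, f_prev: float,
                cfg: FusionConfig | None = None,
                ) -> tuple[float, float | None, float]:
    """Largest peak, reference-interval peak and peakness for one spectrum.

    Returns ``(f_I, f_II, P)``; ``f_II`` is None (and P forced to 0) when no
    candidate local maximum reaches ``peak_frac`` of the global peak height
    inside ``Omega_R = [f_prev - delta, f_prev + 2*delta]``.
    """
    cfg = cfg or FusionConfig()
    band = (f >= cfg.band[0]) & (f <= cfg.band[1])
    fb, pb = f[band], psd[band]
    if fb.size == 0 or np.all(pb <= 0):
        return float("nan"), None, 0.0
    f_i = float(fb[np.argmax(pb)])
    h_i = float(np.max(pb))
    lo = max(cfg.band[0], f_prev - cfg.delta)
    hi = min(cfg.band[1], f_prev + 2 * cfg.delta)
    peaks, _ = signal.find_peaks(pb)
    # the band edges can hold a maximum without being a find_peaks local max
    edge = [i for i in (0, pb.size - 1)
            if pb[i] >= (pb[1] if i == 0 else pb[-2])]
    cand = np.concatenate([peaks, np.asarray(edge, dtype=int)]).astype(int)
    cand = cand[(fb[cand] >= lo) & (fb[cand] <= hi)
                & (pb[cand] >= cfg.peak_frac * h_i)]
    if cand.size == 0:
        return f_i, None, 0.0
    order = np.lexsort((fb[cand], np.abs(fb[cand] - f_prev)))
    f_ii = float(fb[cand[order[0]]])
    p_omega = _band_power(fb, pb, lo, hi)
    p_peak = _band_power(fb, pb, f_ii - cfg.peakness_halfwidth,
                         f_ii + cfg.peakness_halfwidth)
    peakness = 100.0 * p_peak / p_omega if p_omega > 0 else 0.0
    return f_i, f_ii, min(peakness, 100.0)


def fuse_spectra(windows: list[SpectrumWindow], f: np.ndarray,
                 f_prev: float, cfg: FusionConfig | None = None,
                 ) -> tuple[np.ndarray | None, int]:
    """Peaked-conditioned sum of the qualifying spectra.

    ``windows`` are the candidate (j, k-l) spectra for one fused step; the
    peak-selection reference for all of them is the current previous
    estimate.  Criterion A: peakness >= 85%.  Criterion B (per pooled
    window): peakness within ``lam`` of the best signal (peakness normalised
    to [0, 1]); the alternative ``criterion_b="power"`` reading admits
    spectra whose total band power is within a fraction ``lam`` of the
    maximum.  Returns ``(fused_psd or None, n_averaged)``.
    """
    cfg = cfg or FusionConfig()
    by_k: dict[int, list[SpectrumWindow]] = {}
    for w in windows:
        if not w.usable:
            continue
        w.f_i, w.f_ii, w.peakness = select_peak(f, w.psd, f_prev, cfg)
        w.chi_a = w.f_ii is not None and w.peakness >= cfg.peakness_thresh
        by_k.setdefault(w.k, []).append(w)
    for group in by_k.values():
        if cfg.criterion_b == "power":
            tot = [_band_power(f, w.psd, *cfg.band) for w in group]
            best = max(tot) if tot else 0.0
            for w, p in zip(group, tot):
                w.chi_b = best > 0 and p >= (1.0 - cfg.lam) * best
        else:
            best = max(w.peakness for w in group)
            for w in group:
                w.chi_b = w.peakness / 100.0 >= best / 100.0 - cfg.lam
    chosen = [w for w in windows if w.chi_a and w.chi_b]
    if not chosen:
        return None, 0
    fused = np.sum([w.psd for w in chosen], axis=0)
    return fused, len(chosen)


def estimate_fr(f: np.ndarray, fused: np.ndarray, f_prev: float,
                cfg: FusionConfig | None = None) -> float:
    """Argmax of the fused spectrum inside the reference interval."""
    cfg = cfg or FusionConfig()
    lo = max(cfg.band[0], f_prev - cfg.delta)
    hi = min(cfg.band[1], f_prev + 2 * cfg.delta)
    m = (f >= lo) & (f <= hi)
    if not m.any():
        m = (f >= cfg.band[0]) & (f <= cfg.band[1])
    return float(f[m][np.argmax(fused[m])])


def _initial_rate(f: np.ndarray, psds: list[np.ndarray],
                  cfg: FusionConfig) -> float:
    """Pooled vote over the first-window largest peaks (Eq. 6 seed)."""
    f_is = []
    for p in psds:
        f_i, _, _ = select_peak(f, p, f_prev=0.5 * sum(cfg.band), cfg=cfg)
        if np.isfinite(f_i):
            f_is.append(f_i)
    if not f_is:
        return 0.5 * sum(cfg.band)
    binned = np.round(np.asarray(f_is) / 0.04) * 0.04
    vals, counts = np.unique(binned, return_counts=True)
    modal = vals[counts == counts.max()].min()
    if counts.max() >= 3:
        members = [x for x, b in zip(f_is, binned) if b == modal]
        return float(np.median(members))
    # no clear majority: argmax of the unit-normalised pooled spectrum
    band = (f >= cfg.band[0]) & (f <= cfg.band[1])
    pooled = np.sum([p[band] / max(p[band].max(), 1e-30) for p in psds],
                    axis=0)
    return float(f[band][np.argmax(pooled)])


def respiratory_rate_track(edrs: list[EdrSignal],
                           cfg: FusionConfig | None = None,
                           keep_spectra: bool = False) -> RespRateTrack:
    """Run the full fusion estimator over a set of EDR signals."""
    cfg = cfg or FusionConfig()
    if not edrs:
        raise ValueError("no EDR signals")
    t_lo = max(e.t0 for e in edrs)
    t_hi = min(e.t0 + (e.samples.size - 1) / e.fs for e in edrs)
    n_win = int(np.floor((t_hi - t_lo - cfg.window) / cfg.step)) + 1
    if n_win < 1:
        raise ValueError("records shorter than one analysis window")
    wlen = int(cfg.window * cfg.fs)

    # precompute all spectra
    freqs = None
    spectra: list[list[SpectrumWindow]] = []
    for k in range(n_win):
        t_start = t_lo + k * cfg.step
        row = []
        for j, e in enumerate(edrs):
            i0 = int(round((t_start - e.t0) * e.fs))
            seg = e.samples[i0:i0 + wlen]
            f, p, usable = welch_spectrum(seg, cfg)
            freqs = f
            row.append(SpectrumWindow(j=j, k=k, psd=p, usable=usable))
        spectra.append(row)

    f_prev = _initial_rate(freqs, [w.psd for w in spectra[0]], cfg)
    f_r = np.empty(n_win)
    n_avg = np.zeros(n_win, dtype=int)
    fused_prev: np.ndarray | None = None
    fused_list: list = []
    for k in range(n_win):
        if cfg.causal:
            ks = range(max(0, k - 2 * cfg.n_pool), k + 1)
        else:
            ks = range(max(0, k - cfg.n_pool),
                       min(n_win, k + cfg.n_pool + 1))
        pool = [w for kk in ks for w in spectra[kk]]
        fused, n = fuse_spectra(pool, freqs, f_prev, cfg)
        if fused is None:
            fused = fused_prev
            f_k = f_prev
        else:
            f_k = estimate_fr(freqs, fused, f_prev, cfg)
        fused_prev = fused
        f_r[k] = f_k
        n_avg[k] = n
        f_prev = f_k
        if keep_spectra:
            fused_list.append(fused)
    t = t_lo + cfg.window / 2 + np.arange(n_win) * cfg.step
    return RespRateTrack(t=t, f_r=f_r, n_averaged=n_avg, freqs=freqs,
                         fused=fused_list)
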