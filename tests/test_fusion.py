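"""Spectral-fusion respiratory-rate estimator tests."""

import numpy as np
import pytest
from scipy import signal

from cardioresp import fusion
from cardioresp.fusion import (FusionConfig, SpectrumWindow, estimate_fr,
                               fuse_spectra, respiratory_rate_track,
                               select_peak, welch_spectrum)
from cardioresp.records import EdrSignal
from conftest import make_record


CFG = FusionConfig()


def tone(freq, n=160, fs=4.0, amp=1.0):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def bump_spectrum(f, centers, heights, width=0.02):
    """Synthetic PSD: Gaussian bumps at given centres/heights."""
    s = np.zeros_like(f)
    for c, h in zip(centers, heights):
        s += h * np.exp(-0.5 * ((f - c) / width) ** 2)
    return s


class TestWelchSpectrum:
    def test_pure_tone_argmax_within_one_bin(self):
        f, p, usable = welch_spectrum(tone(0.3), CFG)
        assert usable
        df = f[1] - f[0]
        assert abs(f[np.argmax(p)] - 0.3) <= df + 1e-12

    def test_zero_input_zero_spectrum(self):
        f, p, usable = welch_spectrum(np.zeros(160), CFG)
        assert usable and np.allclose(p, 0.0)

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(160)
        f, p, _ = welch_spectrum(x, CFG)
        total = np.trapezoid(p, f)
        assert abs(total - np.var(x)) / np.var(x) < 0.10

    def test_gappy_window_flagged_unusable(self):
        x = tone(0.3)
        x[:60] = np.nan
        _, _, usable = welch_spectrum(x, CFG)
        assert not usable

    def test_small_gap_bridged(self):
        x = tone(0.3)
        x[10:14] = np.nan
        f, p, usable = welch_spectrum(x, CFG)
        assert usable
        assert abs(f[np.argmax(p)] - 0.3) < 0.05


class TestSelectPeak:
    f = np.linspace(0.0, 2.0, 2048)

    def test_single_peak_selected(self):
        s = bump_spectrum(self.f, [0.30], [1.0])
        f_i, f_ii, p = select_peak(self.f, s, f_prev=0.28, cfg=CFG)
        assert f_i == pytest.approx(0.30, abs=0.005)
        assert f_ii == pytest.approx(0.30, abs=0.005)
        assert p > 85

    def test_nearest_qualifying_peak_wins_over_largest(self):
        # largest peak at 0.42, an 90%-height peak at 0.26 nearer the prior
        s = bump_spectrum(self.f, [0.42, 0.26], [1.0, 0.9])
        f_i, f_ii, _ = select_peak(self.f, s, f_prev=0.25, cfg=CFG)
        assert f_i == pytest.approx(0.42, abs=0.005)
        assert f_ii == pytest.approx(0.26, abs=0.005)

    def test_sub_threshold_peak_excluded(self):
        s = bump_spectrum(self.f, [0.42, 0.26], [1.0, 0.80])
        f_i, f_ii, _ = select_peak(self.f, s, f_prev=0.25, cfg=CFG)
        # 0.26 peak is below 85% of the global height -> the largest is used
        assert f_ii == pytest.approx(0.42, abs=0.005)

    def test_no_candidate_in_reference_interval(self):
        s = bump_spectrum(self.f, [0.80], [1.0])
        _, f_ii, p = select_peak(self.f, s, f_prev=0.20, cfg=CFG)
        assert f_ii is None and p == 0.0


class TestFuseSpectra:
    f = np.linspace(0.0, 2.0, 2048)

    def _window(self, j, k, centers, heights):
        return SpectrumWindow(j=j, k=k,
                              psd=bump_spectrum(self.f, centers, heights))

    def test_single_qualifying_spectrum_passes_through(self):
        peaked = self._window(0, 0, [0.30], [1.0])
        flat = SpectrumWindow(j=1, k=0, psd=np.full_like(self.f, 0.1))
        fused, n = fuse_spectra([peaked, flat], self.f, f_prev=0.30, cfg=CFG)
        assert n == 1
        assert np.allclose(fused, peaked.psd)

    def test_all_below_threshold_falls_back(self):
        flat1 = SpectrumWindow(j=0, k=0, psd=np.full_like(self.f, 0.1))
        flat2 = SpectrumWindow(j=1, k=0, psd=np.full_like(self.f, 0.1))
        fused, n = fuse_spectra([flat1, flat2], self.f, f_prev=0.30, cfg=CFG)
        assert fused is None and n == 0

    def test_permutation_invariance_over_signals(self):
        wins = [self._window(j, 0, [0.30], [1.0 - 0.01 * j])
                for j in range(5)]
        f1, n1 = fuse_spectra(list(wins), self.f, 0.30, CFG)
        f2, n2 = fuse_spectra(wins[::-1], self.f, 0.30, CFG)
        assert n1 == n2 and np.allclose(f1, f2)

    def test_criterion_b_power_mode(self):
        cfg = FusionConfig(criterion_b="power")
        big = self._window(0, 0, [0.30], [1.0])
        small = self._window(1, 0, [0.30], [0.5])  # half the total power
        fused, n = fuse_spectra([big, small], self.f, 0.30, cfg)
        assert n == 1  # the low-power spectrum fails criterion B


class TestEstimateFr:
    def test_argmax_within_reference_interval(self):
        f = np.linspace(0, 2, 2048)
        fused = bump_spectrum(f, [0.25, 0.9], [1.0, 2.0])
        # the 0.9 Hz maximum lies outside Omega_R and must be ignored
        assert estimate_fr(f, fused, f_prev=0.25, cfg=CFG) == pytest.approx(
            0.25, abs=0.005)


class TestTrack:
    def test_steady_rate_recovered(self, edr_signals):
        tr = respiratory_rate_track(edr_signals)
        steady = tr.t > 60
        df = tr.freqs[1] - tr.freqs[0]
        assert np.max(np.abs(tr.f_r[steady] - 0.30)) <= 3 * df

    def test_track_continuity_bound(self, edr_signals):
        tr = respiratory_rate_track(edr_signals)
        assert np.max(np.abs(np.diff(tr.f_r))) <= 2 * CFG.delta + 1e-9

    def test_pool_bookkeeping_limits(self, edr_signals):
        tr = respiratory_rate_track(edr_signals)
        # (2 L_s + 1) windows x 9 EDR signals
        assert np.max(tr.n_averaged) <= (2 * CFG.n_pool + 1) * 9

    def test_causal_mode_runs(self, edr_signals):
        tr = respiratory_rate_track(edr_signals,
                                    FusionConfig(causal=True))
        steady = tr.t > 90
        assert np.max(np.abs(tr.f_r[steady] - 0.30)) <= 0.025

    def test_drifting_rate_followed(self):
        # true rate 0.2 -> 0.3 Hz over 4 min
        from cardioresp import edr as edr_mod, ingest
        from cardioresp.synth import (StageParams, generate_beat_series,
                                      generate_ecg, respiration_phase)
        duration = 300.0
        drift = 0.1 / (duration / 60.0)  # Hz per minute
        params = StageParams(mean_hr=70, rsa_amp=0.06, lf_amp=0.03,
                             resp_rate=0.2, resp_rate_drift=drift)
        bt, truth = generate_beat_series(params, duration, seed=5)

        def resp_fn(t):
            ph, _ = respiration_phase(t, 0.2, drift)
            return np.sin(ph)

        rec = generate_ecg(bt, resp_fn, fs=500, seed=6, duration=duration)
        clean = ingest.remove_baseline(rec)
        beats = ingest.detect_beats(clean.leads[1], 500)
        sigs = edr_mod.record_edr_signals(clean, beats)
        tr = respiratory_rate_track(sigs)
        true_rate = 0.2 + drift * tr.t / 60.0
        steady = tr.t > 60
        assert np.max(np.abs(tr.f_r[steady] - true_rate[steady])) <= 0.025

    def test_short_record_rejected(self):
        sig = EdrSignal(kind="Us", lead=0, samples=np.zeros(40))
        with pytest.raises(ValueError):
            respiratory_rate_track([sig])
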