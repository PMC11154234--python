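"""Synthetic hyperbaric-cohort generator with known ground truth.

Emulates the study conditions every downstream stage is tested against: a
cohort of subjects, each recorded over five 5-minute hyperbaric protocol
stages (1D, 3D, 5, 3A, 1A), with

* beat timing driven by an integral pulse frequency modulation (IPFM) model —
  beats fire when the integral of ``(1 + m(t)) * HR_mean / 60`` crosses
  integer thresholds, with ``m(t)`` carrying respiratory sinus arrhythmia
  (RSA) at the respiratory rate plus a low-frequency (0.1 Hz) autonomic term;
* 3-lead ECG built from a Gaussian-mixture QRS template whose amplitude (and
  hence R-wave slopes and angle) is modulated by respiration, plus
  band-limited noise and optional baseline drift;
* stage-dependent parameter shifts following the cohort trend (heart rate
  falls with pressure, RSA rises, the low-frequency term rises on descent and
  falls on ascent), with a minority of "anomalous" subjects whose shifts
  oppose the trend.

Every generated quantity is retained as ground truth so parameter-recovery
tests need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import STAGES, EcgRecord, StageAnnotation

__all__ = [
    "StageParams", "SubjectProfile", "GroundTruth", "QrsTemplate",
    "CohortConfig", "SubjectData",
    "generate_beat_series", "generate_ecg", "generate_cohort",
    "modulating_signal", "respiration_phase", "noise_sd_for_snr",
]


@dataclass
class StageParams:
    """Generative parameters for one protocol stage of one subject."""

    mean_hr: float        # beats/min
    rsa_amp: float        # dimensionless modulation depth
    lf_amp: float         # dimensionless
    resp_rate: float      # Hz
    resp_rate_drift: float = 0.0  # Hz/min
    noise_sd: float = 0.0  # mV, additive ECG noise

    def validate(self) -> None:
        if not (0.07 <= self.resp_rate <= 1.0):
            raise ValueError(f"resp_rate {self.resp_rate} outside [0.07, 1] Hz")
        if not (30.0 <= self.mean_hr <= 180.0):
            raise ValueError(f"mean_hr {self.mean_hr} outside [30, 180] bpm")
        if self.rsa_amp < 0 or self.lf_amp < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass
class SubjectProfile:
    subject_id: int
    stage_params: dict[str, StageParams]
    anomalous: bool = False

    def validate(self) -> None:
        if set(self.stage_params) != set(STAGES):
            raise ValueError("profile must define exactly the five stages")
        for p in self.stage_params.values():
            p.validate()


@dataclass
class GroundTruth:
    """Everything the generator knows, kept for oracle tests."""

    beat_times: np.ndarray          # s
    m_t: np.ndarray                 # modulating signal at m_fs
    m_fs: float                     # Hz (4 Hz)
    resp_signal: np.ndarray         # respiration at m_fs (unit amplitude)
    resp_rate_track: np.ndarray     # Hz, every 5 s
    params: StageParams | None = None


@dataclass
class QrsTemplate:
    """Gaussian-mixture QRS: negative Q and S lobes flanking the R wave.

    Smooth flanks give a unique interior derivative maximum, and over the
    8 ms slope-fit windows the flanks are close to linear, which makes the
    EDR ground truth analytically controllable.
    """

    r_amp: float = 1.0      # mV
    q_amp: float = -0.15
    s_amp: float = -0.25
    r_sigma: float = 0.006  # s; R width ~20 ms, up-slope ~0.1 mV/ms
    qs_sigma: float = 0.005
    q_offset: float = -0.030  # s relative to R
    s_offset: float = 0.030
    half_span: float = 0.08   # template support is [-half_span, +half_span]

    def waveform(self, t: np.ndarray) -> np.ndarray:
        w = (self.r_amp * np.exp(-0.5 * (t / self.r_sigma) ** 2)
             + self.q_amp * np.exp(-0.5 * ((t - self.q_offset) / self.qs_sigma) ** 2)
             + self.s_amp * np.exp(-0.5 * ((t - self.s_offset) / self.qs_sigma) ** 2))
        return w


def respiration_phase(t: np.ndarray, resp_rate: float,
                      drift_hz_per_min: float = 0.0) -> np.ndarray:
    """Phase of a respiration whose rate drifts linearly in time."""
    f_t = resp_rate + drift_hz_per_min * t / 60.0
    return 2.0 * np.pi * (resp_rate * t + 0.5 * drift_hz_per_min * t ** 2 / 60.0), f_t


def modulating_signal(t: np.ndarray, params: StageParams,
                      rng: np.random.Generator | None = None,
                      m_noise_sd: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Autonomic modulating signal m(t) and the unit respiration trace."""
    phase, _ = respiration_phase(t, params.resp_rate, params.resp_rate_drift)
    resp = np.sin(phase)
    m = params.rsa_amp * resp + params.lf_amp * np.sin(2 * np.pi * 0.1 * t)
    if m_noise_sd > 0:
        if rng is None:
            raise ValueError("noise requested without rng")
        # broadband autonomic variability: band-limited (< ~0.9 Hz) noise,
        # rescaled to the requested sd
        from scipy import signal as sg
        fs_t = 1.0 / max(np.median(np.diff(t)), 1e-9) if t.size > 1 else 4.0
        w = rng.standard_normal(t.size)
        if fs_t > 2.0:
            sos = sg.butter(2, 0.9, btype="low", fs=fs_t, output="sos")
            w = sg.sosfilt(sos, w)
        m = m + m_noise_sd * w / max(np.std(w), 1e-12)
    return m, resp


def generate_beat_series(params: StageParams, duration: float, seed: int,
                         m_fs: float = 4.0, m_noise_sd: float = 0.0,
                         ) -> tuple[np.ndarray, GroundTruth]:
    """Beat times from the IPFM model plus full ground truth.

    Beats fire at integer crossings of ``Lambda(t) = int_0^t (1+m) HR/60``;
    a beat is placed at t = 0 and crossings up to ``duration`` are kept (the
    final partial interval is discarded, so a constant 60 bpm, 60 s series
    yields 61 beats at 0, 1, ..., 60 s when the last crossing lands exactly
    on the end point).
    """
    if duration <= 10:
        raise ValueError("duration must exceed 10 s")
    params.validate()
    rng = np.random.default_rng(seed)
    # dense grid for the integral; 8x the 4 Hz ground-truth grid
    dense_fs = 32.0
    t = np.arange(0.0, duration + 0.5 / dense_fs, 1.0 / dense_fs)
    m_dense, _ = modulating_signal(t, params, rng, m_noise_sd)
    rate = (1.0 + m_dense) * params.mean_hr / 60.0
    lam = np.concatenate(([0.0], np.cumsum((rate[1:] + rate[:-1]) / 2) / dense_fs))
    n_max = int(np.floor(lam[-1] + 1e-9))
    thresholds = np.arange(1, n_max + 1, dtype=float)
    crossings = np.interp(thresholds, lam, t)
    beat_times = np.concatenate(([0.0], crossings[crossings <= duration + 1e-9]))

    tg = np.arange(0.0, duration, 1.0 / m_fs)
    m_t, resp = modulating_signal(tg, params)  # noiseless ground-truth copy
    t5 = np.arange(0.0, duration, 5.0)
    _, f_track = respiration_phase(t5, params.resp_rate, params.resp_rate_drift)
    gt = GroundTruth(beat_times=beat_times, m_t=m_t, m_fs=m_fs,
                     resp_signal=resp, resp_rate_track=f_track, params=params)
    return beat_times, gt


#: per-lead R amplitudes (mV); three chest leads with different projections
DEFAULT_LEAD_AMPLITUDES = (1.0, 0.8, 1.2)


def noise_sd_for_snr(snr_db: float, beat_times: np.ndarray,
                     template: QrsTemplate | None = None,
                     lead_amp: float = 1.0, duration: float | None = None,
                     fs: float = 500.0) -> float:
    """Noise sd (mV) giving the requested signal-to-noise ratio in dB.

    SNR is defined on the clean single-lead ECG as
    ``10 * log10(mean(signal^2) / noise_var)``.
    """
    tpl = template or QrsTemplate()
    beat_times = np.asarray(beat_times, dtype=float)
    if duration is None:
        duration = float(beat_times[-1])
    # mean-square of one template burst times the beat duty cycle
    t = np.arange(-tpl.half_span, tpl.half_span, 1.0 / fs)
    w = lead_amp * tpl.waveform(t)
    ms = np.sum(w ** 2) / fs / (duration / max(beat_times.size, 1))
    return float(np.sqrt(ms / 10 ** (snr_db / 10.0)))


def generate_ecg(beat_times: np.ndarray, resp_signal_fn, fs: float, seed: int,
                 template: QrsTemplate | None = None,
                 lead_amplitudes=DEFAULT_LEAD_AMPLITUDES,
                 mod_depth: float = 0.10, width_mod_depth: float = 0.0,
                 noise_sd: float = 0.0,
                 drift_amp: float = 0.0, drift_freq: float = 0.01,
                 duration: float | None = None) -> EcgRecord:
    """Place QRS templates at beat times with respiration-modulated morphology.

    ``resp_signal_fn`` maps beat times (s) to the respiration value in
    [-1, 1]; each beat's template amplitude is scaled by
    ``1 + mod_depth * resp`` (and its time axis by ``1 + width_mod_depth *
    resp``), so the R-wave up/down slopes and angle carry the respiratory
    modulation the EDR stage recovers.
    """
    if fs < 250:
        raise ValueError("fs must be >= 250 Hz")
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size >= 2:
        tpl = template or QrsTemplate()
        if np.min(np.diff(beat_times)) < 2 * tpl.half_span:
            raise ValueError("beat interval shorter than QRS template width")
    template = template or QrsTemplate()
    if duration is None:
        duration = float(beat_times[-1]) + template.half_span + 0.1
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    resp_at_beats = np.asarray(resp_signal_fn(beat_times), dtype=float)

    half = int(round(template.half_span * fs))
    t_tpl = np.arange(-half, half + 1) / fs
    leads = np.zeros((len(lead_amplitudes), n))
    for bi, (bt, r) in enumerate(zip(beat_times, resp_at_beats)):
        c = int(round(bt * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if lo >= hi:
            continue
        scale_t = 1.0 + width_mod_depth * r
        wave = template.waveform(t_tpl[lo - (c - half):hi - (c - half)] / scale_t)
        amp = 1.0 + mod_depth * r
        for li, la in enumerate(lead_amplitudes):
            leads[li, lo:hi] += la * amp * wave
    if noise_sd > 0:
        from scipy import signal as sg
        for li in range(leads.shape[0]):
            w = rng.standard_normal(n)
            # band-limit the noise below 45 Hz (muscle-noise-like)
            sos = sg.butter(4, min(45.0, 0.45 * fs), btype="low", fs=fs,
                            output="sos")
            w = sg.sosfilt(sos, w)
            leads[li] += noise_sd * w / np.std(w)
    if drift_amp > 0:
        tt = np.arange(n) / fs
        drift = drift_amp * np.sin(2 * np.pi * drift_freq * tt)
        leads += drift[None, :]
    return EcgRecord(leads=leads, fs=fs)


# ---------------------------------------------------------------------------
# cohort generation

#: normal-cohort stage-effect template: multiplicative shifts vs baseline 1D.
#: Directions follow the hyperbaric literature (HR falls with pressure, RSA /
#: vagal modulation rises peaking at 5 atm, LF rises on descent and falls on
#: ascent, respiratory rate rises slightly peaking on ascent); magnitudes are
#: package defaults — the study reports directions and significance only.
DEFAULT_STAGE_EFFECTS = {
    "1D": {"mean_hr": 1.00, "rsa_amp": 1.00, "lf_amp": 1.00, "resp_rate": 1.00},
    "3D": {"mean_hr": 0.95, "rsa_amp": 1.22, "lf_amp": 1.25, "resp_rate": 1.03},
    "5":  {"mean_hr": 0.90, "rsa_amp": 1.45, "lf_amp": 1.40, "resp_rate": 1.06},
    "3A": {"mean_hr": 0.94, "rsa_amp": 1.30, "lf_amp": 0.85, "resp_rate": 1.10},
    "1A": {"mean_hr": 0.97, "rsa_amp": 1.15, "lf_amp": 0.80, "resp_rate": 1.08},
}


@dataclass
class CohortConfig:
    n_subjects: int = 28
    n_anomalous: int = 6
    stage_duration: float = 300.0   # s per protocol stop
    fs: float = 500.0               # ECG sampling rate (study device: 2000)
    mean_hr: float = 70.0           # cohort baseline, bpm
    mean_hr_sd: float = 7.0
    resp_rate: float = 0.25         # Hz
    resp_rate_sd: float = 0.04
    rsa_amp: float = 0.05
    rsa_amp_sd: float = 0.010
    lf_amp: float = 0.030
    lf_amp_sd: float = 0.008
    noise_sd: float = 0.02          # mV on the synthesized ECG
    effect_jitter: float = 0.25     # intersubject sd as fraction of the effect
    anomalous_alpha_sd: float = 1.0  # scatter of the opposed-effect exponent
    m_noise_sd: float = 0.02        # broadband autonomic noise in m(t)
    mod_depth: float = 0.05         # respiratory morphology modulation
    stage_effects: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_STAGE_EFFECTS.items()})


@dataclass
class SubjectData:
    profile: SubjectProfile
    #: per-stage ground truth (always present)
    truth: dict[str, GroundTruth]
    #: full ECG record with stage annotations (level="ecg" only)
    record: EcgRecord | None = None
    #: per-stage beat times (level="beats")
    beats: dict[str, np.ndarray] | None = None


def _draw_profile(subject_id: int, anomalous: bool, cfg: CohortConfig,
                  rng: np.random.Generator) -> SubjectProfile:
    base = StageParams(
        mean_hr=float(np.clip(rng.normal(cfg.mean_hr, cfg.mean_hr_sd), 45, 110)),
        rsa_amp=float(np.clip(rng.normal(cfg.rsa_amp, cfg.rsa_amp_sd), 0.015, 0.2)),
        lf_amp=float(np.clip(rng.normal(cfg.lf_amp, cfg.lf_amp_sd), 0.008, 0.15)),
        resp_rate=float(np.clip(rng.normal(cfg.resp_rate, cfg.resp_rate_sd),
                                0.12, 0.45)),
        noise_sd=cfg.noise_sd,
    )
    keys = ("mean_hr", "rsa_amp", "lf_amp", "resp_rate")
    stage_params: dict[str, StageParams] = {}
    for stage in STAGES:
        eff = cfg.stage_effects[stage]
        p = {}
        for key in keys:
            mult = eff[key]
            if anomalous and stage != "1D":
                # anomalous subjects oppose the cohort trend, each stage and
                # parameter in its own way: exponent -(0.3 + |N(0, sd)|) on
                # the stage multiplier — always opposed (the deviation is
                # real for every injected subject) with idiosyncratic
                # magnitudes drawn independently per stage and parameter, so
                # neither the anomalous minority nor its per-stage response
                # profile forms a learnable pattern of its own
                alpha = -(0.3 + abs(rng.normal(0.0, cfg.anomalous_alpha_sd)))
                mult = mult ** alpha
            # intersubject variability in the effect itself
            mult = 1.0 + (mult - 1.0) * rng.normal(1.0, cfg.effect_jitter)
            p[key] = getattr(base, key) * mult
        stage_params[stage] = StageParams(
            mean_hr=float(np.clip(p["mean_hr"], 35, 160)),
            rsa_amp=float(max(p["rsa_amp"], 1e-3)),
            lf_amp=float(max(p["lf_amp"], 1e-3)),
            resp_rate=float(np.clip(p["resp_rate"], 0.08, 0.9)),
            noise_sd=cfg.noise_sd,
        )
    return SubjectProfile(subject_id=subject_id, stage_params=stage_params,
                          anomalous=anomalous)


def generate_cohort(n_subjects: int = 28, n_anomalous: int = 6,
                    config: CohortConfig | None = None, seed: int = 0,
                    level: str = "beats") -> list[SubjectData]:
    """Generate a synthetic hyperbaric cohort.

    ``level="beats"`` keeps beat times plus ground-truth respiration per
    stage (enough for the HRV / OSP / classification pipeline);
    ``level="ecg"`` additionally synthesizes the full 3-lead ECG record with
    stage annotations.  Anomalous subjects (the first ``n_anomalous`` ids,
    flagged in their profile) draw stage effects of opposed sign.
    """
    if n_anomalous >= n_subjects:
        raise ValueError("n_anomalous must be < n_subjects")
    cfg = config or CohortConfig()
    cfg = replace(cfg, n_subjects=n_subjects, n_anomalous=n_anomalous)
    root = np.random.default_rng(seed)
    anomalous_ids = set(range(1, n_anomalous + 1))
    out: list[SubjectData] = []
    for sid in range(1, n_subjects + 1):
        sub_seed = int(root.integers(2 ** 31 - 1))
        rng = np.random.default_rng(sub_seed)
        profile = _draw_profile(sid, sid in anomalous_ids, cfg, rng)
        truth: dict[str, GroundTruth] = {}
        beats: dict[str, np.ndarray] = {}
        for stage in STAGES:
            bt, gt = generate_beat_series(
                profile.stage_params[stage], cfg.stage_duration,
                seed=int(rng.integers(2 ** 31 - 1)), m_noise_sd=cfg.m_noise_sd)
            truth[stage] = gt
            beats[stage] = bt
        data = SubjectData(profile=profile, truth=truth, beats=beats)
        if level == "ecg":
            leads = []
            annotations = []
            for si, stage in enumerate(STAGES):
                gt = truth[stage]
                p = profile.stage_params[stage]

                def resp_fn(t, p=p):
                    phase, _ = respiration_phase(t, p.resp_rate,
                                                 p.resp_rate_drift)
                    return np.sin(phase)

                rec = generate_ecg(
                    beats[stage], resp_fn, fs=cfg.fs,
                    seed=int(rng.integers(2 ** 31 - 1)),
                    mod_depth=cfg.mod_depth, noise_sd=p.noise_sd,
                    duration=cfg.stage_duration)
                leads.append(rec.leads)
                annotations.append(StageAnnotation(
                    stage, si * cfg.stage_duration, (si + 1) * cfg.stage_duration))
            data.record = EcgRecord(leads=np.concatenate(leads, axis=1),
                                    fs=cfg.fs, stages=annotations,
                                    subject_id=sid)
        out.append(data)
    return out
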