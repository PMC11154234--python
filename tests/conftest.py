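import numpy as np
import pytest

from cardioresp import edr, ingest
from cardioresp.synth import (StageParams, generate_beat_series, generate_ecg,
                              noise_sd_for_snr, respiration_phase)


def make_record(rate=0.30, mean_hr=70.0, rsa_amp=0.06, lf_amp=0.03,
                duration=300.0, fs=500.0, seed=11, snr_db=None,
                mod_depth=0.10, m_noise_sd=0.0, **ecg_kwargs):
    """One synthetic single-stage record plus its ground truth."""
    params = StageParams(mean_hr=mean_hr, rsa_amp=rsa_amp, lf_amp=lf_amp,
                         resp_rate=rate)
    beat_times, truth = generate_beat_series(params, duration, seed=seed,
                                             m_noise_sd=m_noise_sd)
    noise_sd = 0.0 if snr_db is None else noise_sd_for_snr(snr_db, beat_times)

    def resp_fn(t):
        phase, _ = respiration_phase(t, rate)
        return np.sin(phase)

    record = generate_ecg(beat_times, resp_fn, fs=fs, seed=seed + 1,
                          mod_depth=mod_depth, noise_sd=noise_sd,
                          duration=duration, **ecg_kwargs)
    return record, beat_times, truth


@pytest.fixture(scope="session")
def clean_record():
    """Noiseless 5-min record, 0.30 Hz respiration, with ground truth."""
    record, beat_times, truth = make_record(seed=11)
    return record, beat_times, truth


@pytest.fixture(scope="session")
def clean_beats(clean_record):
    record, beat_times, _ = clean_record
    clean = ingest.remove_baseline(record)
    beats = ingest.detect_beats(clean.leads[1], record.fs)
    return clean, beats, beat_times


@pytest.fixture(scope="session")
def edr_signals(clean_beats):
    clean, beats, _ = clean_beats
    return edr.record_edr_signals(clean, beats)
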