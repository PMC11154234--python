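"""End-to-end glue: records or beat series -> per-stage feature tables.

Two entry points produce the same (subject, stage) x 9-parameter table:

* :func:`analyze_record` runs the full signal path on a 3-lead ECG record —
  baseline removal, beat detection on the second lead, ectopic correction,
  the nine EDR signals, fused respiratory-rate track, instantaneous HR and
  the OSP decomposition per stage;
* :func:`analyze_beats` starts from beat times plus a respiration trace
  (the synthetic generator's ground-truth level), sharing all code from the
  NN series onward.

Per-stage parameters are computed over the final four minutes of each
annotated stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify, edr, fusion, hrv, ingest, osp, stage_stats
from .records import STAGES, BeatAnnotations, EcgRecord
from .synth import SubjectData

__all__ = ["stage_window", "features_from_beats", "analyze_record",
           "analyze_beats", "cohort_feature_table", "cohort_ratio_table"]

#: analysis window: final four minutes of each stage
STAGE_WINDOW = 240.0

DETECTION_LEAD = 1  # second lead, 0-based


def stage_window(t_start: float, t_end: float,
                 window: float = STAGE_WINDOW) -> tuple[float, float]:
    return max(t_start, t_end - window), t_end


def _resp_rate_from_signal(x: np.ndarray, fs: float = 4.0) -> float:
    """Welch-argmax respiratory rate of a respiration trace (fallback path)."""
    from scipy import signal as sg
    nper = min(x.size, int(48 * fs))
    f, p = sg.welch(x - x.mean(), fs=fs, nperseg=nper, noverlap=nper // 2,
                    nfft=4096)
    band = (f >= 0.07) & (f <= 1.0)
    return float(f[band][np.argmax(p[band])])


def features_from_beats(beat_times: np.ndarray, resp: np.ndarray,
                        span: tuple[float, float], resp_t0: float = 0.0,
                        resp_fs: float = 4.0, f_r: float | None = None,
                        max_delay: int = 40) -> dict[str, float]:
    """The nine per-stage parameters from beats + a respiration trace.

    ``resp`` is an evenly sampled respiration surrogate (an EDR signal or
    the generator's ground truth) on a grid aligned with ``resp_t0``;
    ``f_r`` overrides the respiratory-rate feature when a fused track
    estimate is available.
    """
    lo, hi = stage_window(*span)
    beats = BeatAnnotations(r_times=np.asarray(beat_times, dtype=float))
    nn, nn_times, _ = ingest.correct_ectopics(beats)
    tp = hrv.time_params(nn, nn_times, window=(lo, hi))
    t, hr_t = hrv.instantaneous_hr(beat_times)
    hs = hrv.split_hrv(t, hr_t)
    m = (hs.t >= lo) & (hs.t <= hi)
    hrv_w = hs.hrv[m]
    idx = np.round((hs.t[m] - resp_t0) * resp_fs).astype(int)
    idx = np.clip(idx, 0, resp.size - 1)
    resp_w = np.asarray(resp, dtype=float)[idx]
    v = osp.build_resp_subspace(resp_w, max_delay=max_delay)
    fp = osp.component_powers(osp.project(hrv_w, v))
    if f_r is None:
        f_r = _resp_rate_from_signal(resp_w, resp_fs)
    return {"f_r": f_r, "nn_median": tp.nn_median, "nn_iqr": tp.nn_iqr,
            "rmssd": tp.rmssd, "pnn50": tp.pnn50, "p_r": fp.p_r,
            "p_perp": fp.p_perp, "p_lf_perp": fp.p_lf_perp,
            "p_hf_perp": fp.p_hf_perp}


def analyze_record(record: EcgRecord,
                   fusion_cfg: fusion.FusionConfig | None = None,
                   resp_edr: tuple[str, int] = ("Us", DETECTION_LEAD),
                   ) -> pd.DataFrame:
    """Full pipeline on one annotated multi-stage ECG record.

    Returns a DataFrame indexed by (subject, stage) with the nine per-stage
    parameters.  The respiration input to the OSP decomposition is the
    ``resp_edr`` EDR signal (default: up-slope series of the detection
    lead).
    """
    clean = ingest.remove_baseline(record)
    lead_idx = min(DETECTION_LEAD, clean.n_leads - 1)
    beats = ingest.detect_beats(clean.leads[lead_idx], clean.fs)
    if beats.n_beats < 10:
        raise ValueError("too few beats detected")
    edrs = edr.record_edr_signals(clean, beats)
    track = fusion.respiratory_rate_track(edrs, fusion_cfg)
    resp_sig = next(e for e in edrs
                    if e.kind == resp_edr[0] and e.lead == resp_edr[1])
    nn, nn_times, _ = ingest.correct_ectopics(beats)

    rows = {}
    for ann in record.stages:
        lo, hi = stage_window(ann.t_start, ann.t_end)
        in_stage = (beats.r_times >= ann.t_start) & (beats.r_times <= ann.t_end)
        bt = beats.r_times[in_stage]
        tp = hrv.time_params(nn, nn_times, window=(lo, hi))
        t, hr_t = hrv.instantaneous_hr(bt)
        hs = hrv.split_hrv(t, hr_t)
        m = (hs.t >= lo) & (hs.t <= hi)
        idx = np.round((hs.t[m] - resp_sig.t0) * resp_sig.fs).astype(int)
        idx = np.clip(idx, 0, resp_sig.samples.size - 1)
        v = osp.build_resp_subspace(resp_sig.samples[idx])
        fp = osp.component_powers(osp.project(hs.hrv[m], v))
        tm = (track.t >= lo) & (track.t <= hi)
        f_r = float(np.median(track.f_r[tm])) if tm.any() else np.nan
        rows[(record.subject_id, ann.stage)] = {
            "f_r": f_r, "nn_median": tp.nn_median, "nn_iqr": tp.nn_iqr,
            "rmssd": tp.rmssd, "pnn50": tp.pnn50, "p_r": fp.p_r,
            "p_perp": fp.p_perp, "p_lf_perp": fp.p_lf_perp,
            "p_hf_perp": fp.p_hf_perp}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["subject", "stage"])
    return df


def analyze_beats(subject: SubjectData) -> pd.DataFrame:
    """Per-stage features from a beat-level synthetic subject."""
    rows = {}
    for stage in STAGES:
        gt = subject.truth[stage]
        span = (0.0, subject.beats[stage][-1])
        rows[(subject.profile.subject_id, stage)] = features_from_beats(
            subject.beats[stage], gt.resp_signal, span, resp_fs=gt.m_fs)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["subject", "stage"])
    return df


def cohort_feature_table(cohort: list[SubjectData]) -> pd.DataFrame:
    """Stacked per-stage feature table for a beat-level cohort."""
    return pd.concat([analyze_beats(s) for s in cohort])


def cohort_ratio_table(cohort: list[SubjectData]) -> pd.DataFrame:
    """Baseline-referenced ratio features, columns in classifier order."""
    ratios = stage_stats.ratio_table(cohort_feature_table(cohort))
    return ratios[list(classify.FEATURES)]
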