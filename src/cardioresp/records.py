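"""Domain containers and plain-text record IO.

An :class:`EcgRecord` is a multi-lead sampled ECG with stage annotations
(hyperbaric protocol stages ``1D, 3D, 5, 3A, 1A``: the number is the pressure
in atmospheres, D/A marks descent/ascent).  Records round-trip through
delimited text: a wide table ``time, lead1..leadN`` plus a stage table
``stage, t_start, t_end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical protocol stage order
STAGES = ("1D", "3D", "5", "3A", "1A")
#: reference (baseline) stage for relative changes
BASELINE_STAGE = "1D"


@dataclass
class StageAnnotation:
    stage: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError(f"stage {self.stage}: t_end <= t_start")


@dataclass
class EcgRecord:
    """Multi-lead ECG sampled at ``fs`` Hz with protocol stage annotations."""

    leads: np.ndarray  # (n_leads, n_samples), mV
    fs: float
    stages: list[StageAnnotation] = field(default_factory=list)
    subject_id: int = 0

    def __post_init__(self) -> None:
        self.leads = np.atleast_2d(np.asarray(self.leads, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        spans = sorted((s.t_start, s.t_end) for s in self.stages)
        for (a0, a1), (b0, _) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("stage annotations overlap")

    @property
    def n_leads(self) -> int:
        return self.leads.shape[0]

    @property
    def n_samples(self) -> int:
        return self.leads.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def stage_span(self, stage: str) -> tuple[float, float]:
        for ann in self.stages:
            if ann.stage == stage:
                return ann.t_start, ann.t_end
        raise KeyError(f"stage {stage!r} not annotated")


@dataclass
class BeatAnnotations:
    """Per-beat fiducial points, in seconds from record start.

    ``validity`` distinguishes normal beats from ectopic/interpolated ones
    after correction ('N', 'E', 'I').
    """

    r_times: np.ndarray
    q_times: np.ndarray | None = None
    s_times: np.ndarray | None = None
    validity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        if self.r_times.size and np.any(np.diff(self.r_times) <= 0):
            raise ValueError("r_times must be strictly increasing")
        if self.q_times is not None:
            self.q_times = np.asarray(self.q_times, dtype=float)
        if self.s_times is not None:
            self.s_times = np.asarray(self.s_times, dtype=float)
        if self.validity is None:
            self.validity = np.full(self.r_times.shape, "N", dtype="<U1")

    @property
    def n_beats(self) -> int:
        return self.r_times.size


@dataclass
class EdrSignal:
    """Evenly sampled (4 Hz) ECG-derived respiration surrogate.

    ``kind`` is one of ``Us`` (R-wave up-slope, mV/ms), ``Ds`` (down-slope,
    mV/ms) or ``Ra`` (R-wave angle, rad); after conditioning the signal is
    band-limited to roughly 0.07-1 Hz.
    """

    kind: str
    lead: int
    samples: np.ndarray
    t0: float = 0.0
    fs: float = 4.0

    def __post_init__(self) -> None:
        if self.kind not in ("Us", "Ds", "Ra"):
            raise ValueError(f"unknown EDR kind {self.kind!r}")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


# ---------------------------------------------------------------------------
# delimited-text IO


def write_record(record: EcgRecord, signal_path: str | Path,
                 stage_path: str | Path | None = None) -> None:
    cols = {"time": record.time}
    for i in range(record.n_leads):
        cols[f"lead{i + 1}"] = record.leads[i]
    pd.DataFrame(cols).to_csv(signal_path, sep="\t", index=False,
                              float_format="%.6f")
    if stage_path is not None:
        pd.DataFrame(
            [(s.stage, s.t_start, s.t_end) for s in record.stages],
            columns=["stage", "t_start", "t_end"],
        ).to_csv(stage_path, sep="\t", index=False)


def read_record(signal_path: str | Path,
                stage_path: str | Path | None = None,
                subject_id: int = 0) -> EcgRecord:
    df = pd.read_csv(signal_path, sep=None, engine="python")
    t = df["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("record too short")
    fs = 1.0 / float(np.median(np.diff(t)))
    lead_cols = [c for c in df.columns if c != "time"]
    leads = df[lead_cols].to_numpy(dtype=float).T
    stages: list[StageAnnotation] = []
    if stage_path is not None:
        sdf = pd.read_csv(stage_path, sep=None, engine="python")
        stages = [StageAnnotation(str(r.stage), float(r.t_start), float(r.t_end))
                  for r in sdf.itertuples()]
    return EcgRecord(leads=leads, fs=fs, stages=stages, subject_id=subject_id)
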