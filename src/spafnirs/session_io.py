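"""Session data model, protocol layout and file I/O.

A session is one bedside recording of a preterm neonate during a 55-minute,
9-interval creative-music-therapy (CMT) protocol.  Cerebral tissue oximetry
(StO2, %) is recorded at 1 Hz at two optode sites — left auditory cortex (AC)
and right prefrontal cortex (PFC) — while the patient monitor provides
peripheral arterial saturation (SpO2, %) and pulse rate (PR, bpm) at 0.25 Hz.
A 3-axis accelerometer on the oximeter sensor captures movement.

On disk a session is a single CSV on the 1 Hz StO2 grid with columns
``time_s, sto2_ac, sto2_pfc, spo2, pr, accel_x, accel_y, accel_z``.  The
slower vital-sign channels are populated only on rows whose time stamp is a
sample instant of the 0.25 Hz grid; empty cells are missing values.  Cohort
metadata lives in a separate TSV keyed by ``subject_id``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectMetadata",
    "SessionRecording",
    "ProtocolInterval",
    "StudyProtocol",
    "SessionFormatError",
    "SessionValidationError",
    "ProtocolCoverageError",
    "default_protocol",
    "segment",
    "read_session",
    "write_session",
    "read_metadata_table",
    "write_metadata_table",
    "read_snirf_sto2",
    "SESSION_COLUMNS",
]

SESSION_COLUMNS = (
    "time_s",
    "sto2_ac",
    "sto2_pfc",
    "spo2",
    "pr",
    "accel_x",
    "accel_y",
    "accel_z",
)

PROTOCOL_MINUTES = 55.0


class SessionFormatError(ValueError):
    """Malformed session file (missing column, bad header...)."""


class SessionValidationError(ValueError):
    """Session contents violate an invariant (non-monotone time, range...)."""


class ProtocolCoverageError(ValueError):
    """Recording too short to cover the protocol; lists truncated intervals."""

    def __init__(self, truncated: Sequence[int]):
        self.truncated = tuple(truncated)
        super().__init__(
            "recording does not cover protocol intervals: "
            + ", ".join(str(i) for i in self.truncated)
        )


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SubjectMetadata:
    """Demographic and clinical covariates for one neonate.

    Units: gestational age in weeks, postnatal age in days, weights in g,
    lengths and head circumferences in cm, haematocrit as a volume fraction
    in (0, 1).  ``behavioural_state_mean``/``_std`` summarise bedside
    behavioural-state scores over the session.
    """

    subject_id: str
    sex: str  # "female" | "male"
    gestational_age: float
    postnatal_age: float
    birth_weight: float
    weight_at_measurement: float
    length_at_birth: float
    length_at_measurement: float
    head_circumference_at_birth: float
    head_circumference_at_measurement: float
    apgar_1min: int
    apgar_5min: int
    mode_of_delivery: str
    haematocrit: float
    behavioural_state_mean: float
    behavioural_state_std: float

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise SessionValidationError(f"sex must be female/male, got {self.sex!r}")
        if not 22.0 <= self.gestational_age <= 44.0:
            raise SessionValidationError(
                f"gestational_age {self.gestational_age} outside [22, 44] weeks"
            )
        if not 0.0 < self.haematocrit < 1.0:
            raise SessionValidationError(
                f"haematocrit {self.haematocrit} outside (0, 1)"
            )
        for name in ("apgar_1min", "apgar_5min"):
            v = getattr(self, name)
            if int(v) != v or not 0 <= v <= 10:
                raise SessionValidationError(f"{name}={v} not an integer in 0..10")
        for name in (
            "birth_weight",
            "weight_at_measurement",
            "length_at_birth",
            "length_at_measurement",
            "head_circumference_at_birth",
            "head_circumference_at_measurement",
        ):
            if getattr(self, name) <= 0:
                raise SessionValidationError(f"{name} must be > 0")
        if self.behavioural_state_std < 0:
            raise SessionValidationError("behavioural_state_std must be >= 0")


@dataclass
class SessionRecording:
    """Raw multi-rate signals for one session.

    ``sto2_ac``/``sto2_pfc`` are sampled at ``fs_sto2`` (1 Hz), ``spo2``/``pr``
    at ``fs_vitals`` (0.25 Hz) and the acceleration triplet at ``fs_accel``.
    Missing samples are NaN.  ``start_time`` is the offset in seconds of
    sample 0 relative to protocol start (0 when recording and protocol are
    aligned, the usual case).
    """

    subject_id: str
    sto2_ac: np.ndarray
    sto2_pfc: np.ndarray
    spo2: np.ndarray
    pr: np.ndarray
    accel: np.ndarray  # shape (3, n_accel)
    fs_sto2: float = 1.0
    fs_vitals: float = 0.25
    fs_accel: float = 1.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sto2_ac", "sto2_pfc", "spo2", "pr"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.accel = np.asarray(self.accel, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[0] != 3:
            raise SessionValidationError("accel must have shape (3, n)")
        ratio = self.fs_sto2 / self.fs_vitals
        if abs(ratio - round(ratio)) > 1e-9:
            raise SessionValidationError(
                "fs_sto2 must be an integer multiple of fs_vitals"
            )
        for name in ("sto2_ac", "sto2_pfc", "spo2"):
            v = getattr(self, name)
            bad = v[~np.isnan(v)]
            if bad.size and (bad.min() < 0.0 or bad.max() > 100.0):
                raise SessionValidationError(f"{name} values outside [0, 100]")
        prv = self.pr[~np.isnan(self.pr)]
        if prv.size and prv.min() <= 0:
            raise SessionValidationError("pr values must be > 0")

    @property
    def duration_s(self) -> float:
        return len(self.sto2_ac) / self.fs_sto2


@dataclass(frozen=True)
class ProtocolInterval:
    index: int  # 1-based
    label: str  # baseline | touch | singing | hold | rest
    start: float  # minutes
    end: float  # minutes

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class StudyProtocol:
    """Ordered, contiguous, half-open intervals partitioning the session."""

    intervals: tuple[ProtocolInterval, ...]

    def __post_init__(self) -> None:
        prev_end = 0.0
        for k, iv in enumerate(self.intervals, start=1):
            if iv.index != k:
                raise SessionValidationError("interval indices must be 1..n in order")
            if not math.isclose(iv.start, prev_end, abs_tol=1e-9):
                raise SessionValidationError("intervals must be contiguous")
            if iv.end <= iv.start:
                raise SessionValidationError("interval end must exceed start")
            prev_end = iv.end

    @property
    def duration_min(self) -> float:
        return self.intervals[-1].end

    def interval(self, index: int) -> ProtocolInterval:
        return self.intervals[index - 1]


def default_protocol() -> StudyProtocol:
    """The 9-interval, 55-minute CMT session layout.

    Only the first three boundaries (baseline 0-5, touch 5-10, singing 10-20)
    are fixed by the protocol description; the second half mirrors the first
    sequence with a 10-minute second singing interval at 35-45 min.  The
    layout is overridable through the pipeline config.
    """
    spec = [
        ("baseline", 0, 5),
        ("touch", 5, 10),
        ("singing", 10, 20),
        ("hold", 20, 25),
        ("rest", 25, 30),
        ("touch", 30, 35),
        ("singing", 35, 45),
        ("hold", 45, 50),
        ("rest", 50, 55),
    ]
    return StudyProtocol(
        tuple(
            ProtocolInterval(i + 1, label, float(a), float(b))
            for i, (label, a, b) in enumerate(spec)
        )
    )


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment(
    protocol: StudyProtocol, fs: float, n_samples: int
) -> dict[int, np.ndarray]:
    """Map every sample index inside the protocol to its interval.

    Sample ``k`` lives at time ``k / fs`` seconds; membership is half-open
    ``[start, end)`` so a sample exactly on a boundary belongs to the later
    interval.  Returns ``{interval_index: sample_indices}``.

    Raises :class:`ProtocolCoverageError` when the recording is shorter than
    the protocol, listing the truncated intervals.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    t = np.arange(n_samples) / fs  # seconds
    out: dict[int, np.ndarray] = {}
    truncated = []
    for iv in protocol.intervals:
        lo, hi = iv.start * 60.0, iv.end * 60.0
        idx = np.nonzero((t >= lo - 1e-12) & (t < hi - 1e-12))[0]
        expected = len(np.nonzero((np.arange(math.ceil(hi * fs)) / fs >= lo - 1e-12)
                                  & (np.arange(math.ceil(hi * fs)) / fs < hi - 1e-12))[0])
        if len(idx) < expected:
            truncated.append(iv.index)
        out[iv.index] = idx
    if truncated:
        raise ProtocolCoverageError(truncated)
    return out


# ---------------------------------------------------------------------------
# session CSV I/O
# ---------------------------------------------------------------------------

def write_session(rec: SessionRecording, path: str | Path) -> Path:
    """Write a session to the on-disk CSV dialect (1 Hz grid, empty=missing)."""
    path = Path(path)
    n = len(rec.sto2_ac)
    step = int(round(rec.fs_sto2 / rec.fs_vitals))
    cols: dict[str, np.ndarray] = {
        "time_s": np.arange(n) / rec.fs_sto2,
        "sto2_ac": rec.sto2_ac,
        "sto2_pfc": rec.sto2_pfc,
    }
    for name, series in (("spo2", rec.spo2), ("pr", rec.pr)):
        full = np.full(n, np.nan)
        m = min(len(series), math.ceil(n / step))
        full[: m * step : step] = series[:m]
        cols[name] = full
    for i, name in enumerate(("accel_x", "accel_y", "accel_z")):
        full = np.full(n, np.nan)
        m = min(rec.accel.shape[1], n)
        full[:m] = rec.accel[i, :m]
        cols[name] = full
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_session(
    path: str | Path,
    subject_id: str | None = None,
    fs_sto2: float = 1.0,
    fs_vitals: float = 0.25,
    fs_accel: float = 1.0,
) -> SessionRecording:
    """Read one session CSV into a validated :class:`SessionRecording`.

    Missing cells become NaN — rows are never dropped.  A missing column
    raises :class:`SessionFormatError` naming it; a non-monotone time column
    raises :class:`SessionValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in SESSION_COLUMNS:
        if col not in df.columns:
            raise SessionFormatError(f"session file {path.name} missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise SessionValidationError("time_s must be strictly increasing")
    step = int(round(fs_sto2 / fs_vitals))
    vit_rows = slice(0, None, step)
    return SessionRecording(
        subject_id=subject_id or path.stem,
        sto2_ac=df["sto2_ac"].to_numpy(float),
        sto2_pfc=df["sto2_pfc"].to_numpy(float),
        spo2=df["spo2"].to_numpy(float)[vit_rows],
        pr=df["pr"].to_numpy(float)[vit_rows],
        accel=np.vstack(
            [df[c].to_numpy(float) for c in ("accel_x", "accel_y", "accel_z")]
        ),
        fs_sto2=fs_sto2,
        fs_vitals=fs_vitals,
        fs_accel=fs_accel,
        start_time=float(t[0]),
    )


# ---------------------------------------------------------------------------
# cohort metadata TSV
# ---------------------------------------------------------------------------

def write_metadata_table(metas: Sequence[SubjectMetadata], path: str | Path) -> Path:
    path = Path(path)
    rows = [{f.name: getattr(m, f.name) for f in fields(SubjectMetadata)} for m in metas]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_metadata_table(path: str | Path) -> list[SubjectMetadata]:
    df = pd.read_csv(path, sep="\t")
    required = [f.name for f in fields(SubjectMetadata)]
    for col in required:
        if col not in df.columns:
            raise SessionFormatError(f"metadata table missing column {col!r}")
    out = []
    for _, row in df.iterrows():
        kw = {name: row[name] for name in required}
        kw["subject_id"] = str(kw["subject_id"])
        kw["apgar_1min"] = int(kw["apgar_1min"])
        kw["apgar_5min"] = int(kw["apgar_5min"])
        out.append(SubjectMetadata(**kw))
    return out


# ---------------------------------------------------------------------------
# optional SNIRF import
# ---------------------------------------------------------------------------

def read_snirf_sto2(path: str | Path, subject_id: str | None = None,
                    fs_vitals: float = 0.25) -> SessionRecording:
    """Read-only SNIRF (HDF5) import mapping the first two data channels to
    ``sto2_ac`` and ``sto2_pfc``.

    Vitals and acceleration are not part of SNIRF data blocks written by the
    oximeters this package targets; they come back as all-missing series on
    the matching grids.  Requires ``h5py``.
    """
    import h5py

    path = Path(path)
    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"], dtype=float)
        t = np.asarray(data["time"], dtype=float)
    if series.ndim != 2 or series.shape[1] < 2:
        raise SessionFormatError("SNIRF file must contain at least two channels")
    if len(t) >= 2:
        fs = 1.0 / float(np.median(np.diff(t)))
    else:
        fs = 1.0
    n = series.shape[0]
    n_vit = math.ceil(n * fs_vitals / fs)
    return SessionRecording(
        subject_id=subject_id or path.stem,
        sto2_ac=series[:, 0],
        sto2_pfc=series[:, 1],
        spo2=np.full(n_vit, np.nan),
        pr=np.full(n_vit, np.nan),
        accel=np.full((3, n), np.nan),
        fs_sto2=fs,
        fs_vitals=fs_vitals,
        fs_accel=fs,
    )
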