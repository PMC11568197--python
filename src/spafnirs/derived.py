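"""Derived measures: FTOE, per-interval medians, baseline normalization,
evoked-change deltas and subgroup block averages.

Fractional tissue oxygen extraction, FTOE = (SpO2 - StO2) / SpO2, indexes the
balance between oxygen delivery and consumption: if arterial saturation is
stable, a rise in tissue saturation implies a fall in extraction and vice
versa.  All evoked-change quantities are referenced to the second protocol
interval (first therapeutic touch, 5-10 min), the interval immediately
preceding the first singing period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import PreprocessedSession
from .session_io import StudyProtocol, default_protocol, segment

__all__ = [
    "SIGNALS",
    "IntervalSummary",
    "DeltaSet",
    "BlockAverageSet",
    "compute_ftoe",
    "attach_ftoe",
    "interval_medians",
    "normalize_to_interval2",
    "compute_deltas",
    "block_average",
]

SIGNALS = ("sto2_ac", "sto2_pfc", "spo2", "pr", "ftoe_ac", "ftoe_pfc")

BASELINE_INTERVAL = 2  # first therapeutic touch
RESPONSE_INTERVAL = 3  # first singing period


@dataclass
class IntervalSummary:
    """Per-interval medians and data-completeness fractions for one subject.

    ``medians`` and ``valid_fraction`` are DataFrames indexed by signal name
    with one column per interval (1..9).  An interval with less than
    ``min_valid_fraction`` non-missing samples gets a missing median.
    """

    subject_id: str
    medians: pd.DataFrame
    valid_fraction: pd.DataFrame

    def median(self, sig: str, interval: int) -> float:
        return float(self.medians.loc[sig, interval])


@dataclass
class DeltaSet:
    """Evoked changes: median(interval 3) - median(interval 2) per signal."""

    subject_id: str
    values: dict[str, float]

    def __getitem__(self, sig: str) -> float:
        return self.values[sig]


@dataclass
class BlockAverageSet:
    """Group time-course summaries after per-subject baseline normalization.

    ``curves[(subgroup, signal)]`` is a DataFrame with columns
    ``median, p25, p75`` on the common grid; ``n_subjects`` counts the
    subjects contributing to each subgroup.
    """

    curves: dict[tuple[int, str], pd.DataFrame]
    n_subjects: dict[int, int]


# ---------------------------------------------------------------------------

def compute_ftoe(spo2: np.ndarray, sto2: np.ndarray) -> np.ndarray:
    """Elementwise (SpO2 - StO2)/SpO2; missing where either input is missing
    or SpO2 is zero (never raises)."""
    spo2 = np.asarray(spo2, dtype=float)
    sto2 = np.asarray(sto2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (spo2 - sto2) / spo2
    out[~np.isfinite(out)] = np.nan
    return out


def attach_ftoe(pre: PreprocessedSession) -> PreprocessedSession:
    """Fill the FTOE channels of a preprocessed session in place."""
    pre.ftoe_ac = compute_ftoe(pre.spo2, pre.sto2_ac)
    pre.ftoe_pfc = compute_ftoe(pre.spo2, pre.sto2_pfc)
    n_zero = int(np.sum(pre.spo2 == 0.0))
    if n_zero:
        pre.quality["spo2_zero_count"] = n_zero
    return pre


def interval_medians(
    pre: PreprocessedSession,
    protocol: StudyProtocol | None = None,
    min_valid_fraction: float = 0.5,
) -> IntervalSummary:
    """Median of the non-missing samples of each signal in each interval.

    An interval whose non-missing fraction falls below ``min_valid_fraction``
    (artifact-dominated) yields a missing median rather than a value computed
    from a handful of surviving samples.
    """
    protocol = protocol or default_protocol()
    if pre.ftoe_ac is None:
        attach_ftoe(pre)
    seg = segment(protocol, pre.fs, len(pre.time))
    sigs = pre.signals()
    med = pd.DataFrame(index=list(SIGNALS), columns=sorted(seg), dtype=float)
    vf = pd.DataFrame(index=list(SIGNALS), columns=sorted(seg), dtype=float)
    for k, idx in seg.items():
        for name in SIGNALS:
            x = sigs[name][idx]
            frac = float(np.mean(~np.isnan(x))) if len(x) else 0.0
            vf.loc[name, k] = frac
            med.loc[name, k] = (
                float(np.nanmedian(x)) if frac >= min_valid_fraction else np.nan
            )
    return IntervalSummary(pre.subject_id, med, vf)


def normalize_to_interval2(
    pre: PreprocessedSession,
    summary: IntervalSummary | None = None,
    protocol: StudyProtocol | None = None,
    mode: str = "subtract",
) -> dict[str, np.ndarray]:
    """Reference each signal to its own first-touch (interval 2) median.

    Default is subtraction, giving delta-style curves through zero over the
    baseline interval; ``mode="divide"`` gives relative curves instead.
    Signals whose interval-2 median is missing come back as all-missing and
    are excluded from block averages downstream.
    """
    if summary is None:
        summary = interval_medians(pre, protocol)
    sigs = pre.signals()
    out: dict[str, np.ndarray] = {}
    for name in SIGNALS:
        m = summary.median(name, BASELINE_INTERVAL)
        x = sigs[name]
        if np.isnan(m) or (mode == "divide" and m == 0.0):
            out[name] = np.full_like(x, np.nan)
        elif mode == "divide":
            out[name] = x / m
        else:
            out[name] = x - m
    return out


def compute_deltas(summary: IntervalSummary) -> DeltaSet:
    """Evoked change per signal: interval-3 median minus interval-2 median."""
    vals = {
        name: summary.median(name, RESPONSE_INTERVAL)
        - summary.median(name, BASELINE_INTERVAL)
        for name in SIGNALS
    }
    return DeltaSet(summary.subject_id, vals)


def block_average(
    normalized: dict[str, dict[str, np.ndarray]],
    subgroups: dict[str, int],
) -> BlockAverageSet:
    """Pointwise median / 25th / 75th percentile curves across subjects.

    ``normalized`` maps subject_id -> signal -> normalized series;
    ``subgroups`` maps subject_id -> subgroup label (1 or 2; other labels are
    skipped).  Percentiles use linear interpolation between order statistics
    and ignore missing values pointwise.
    """
    curves: dict[tuple[int, str], pd.DataFrame] = {}
    n_subjects: dict[int, int] = {}
    for g in (1, 2):
        members = [sid for sid, lab in subgroups.items() if lab == g and sid in normalized]
        n_subjects[g] = len(members)
        if not members:
            import warnings

            warnings.warn(f"subgroup {g} empty; omitted from block averages")
            continue
        for name in SIGNALS:
            stack = np.vstack([normalized[sid][name] for sid in members])
            with np.errstate(all="ignore"):
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore", RuntimeWarning)
                    med = np.nanmedian(stack, axis=0)
                    p25 = np.nanpercentile(stack, 25, axis=0)
                    p75 = np.nanpercentile(stack, 75, axis=0)
            curves[(g, name)] = pd.DataFrame(
                {"median": med, "p25": p25, "p75": p75}
            )
    return BlockAverageSet(curves, n_subjects)


def deltas_to_frame(deltas: list[DeltaSet]) -> pd.DataFrame:
    """Tidy export: one row per subject x signal."""
    rows = [
        {"subject_id": d.subject_id, "signal": sig, "delta": val}
        for d in deltas
        for sig, val in d.values.items()
    ]
    return pd.DataFrame(rows)
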