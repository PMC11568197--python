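"""Signal conditioning: antialiased downsampling, Savitzky-Golay smoothing and
accelerometer-driven motion-artifact masking.

The cleaned session lives on a common 0.25 Hz grid: StO2 is FIR-low-pass
filtered (zero phase) and decimated from 1 Hz; SpO2 and PR are smoothed with
a 2nd-degree Savitzky-Golay filter over a ~32 s window; epochs whose summed
acceleration shows a moving standard deviation (50 s window) above a
threshold T are deleted (set to NaN) from every physiological channel.
T defaults to an automatic per-session choice, k x median of the moving SD,
because high-motion epochs vary strongly between bedside sessions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .session_io import SessionRecording, StudyProtocol, default_protocol, segment

__all__ = [
    "PreprocessCfg",
    "PreprocessedSession",
    "downsample_antialias",
    "smooth_savgol",
    "moving_sd",
    "motion_mask",
    "preprocess_session",
]


@dataclass
class PreprocessCfg:
    """Preprocessing settings.

    ``sg_window`` is in seconds; at the 0.25 Hz target rate 32 s spans 8
    samples, an even count, so the effective window is widened to the nearest
    odd width (9 samples = 36 s).  ``artifact_threshold`` is either a number
    (units of the moving SD of summed acceleration) or ``"auto"`` =
    ``auto_threshold_k`` x median moving SD.  ``accel_sum`` selects the
    literal x+y+z sum (default) or the vector norm.
    """

    target_fs: float = 0.25
    sg_order: int = 2
    sg_window: float = 32.0
    accel_sd_window: float = 50.0
    artifact_threshold: float | str = "auto"
    auto_threshold_k: float = 3.0
    accel_sum: str = "sum"  # "sum" | "norm"
    max_masked_fraction: float = 0.5  # per-interval quality flag level

    def __post_init__(self) -> None:
        if self.target_fs <= 0 or self.sg_window <= 0 or self.accel_sd_window <= 0:
            raise ValueError("rates and windows must be positive")
        if self.accel_sum not in ("sum", "norm"):
            raise ValueError("accel_sum must be 'sum' or 'norm'")


@dataclass
class PreprocessedSession:
    """Artifact-masked signals on the common grid, plus a quality report.

    ``artifact_mask`` is True where samples were removed; masked positions
    are NaN in every physiological series.  ``ftoe_ac``/``ftoe_pfc`` start
    empty and are filled by the derived-measures stage.
    """

    subject_id: str
    fs: float
    time: np.ndarray
    sto2_ac: np.ndarray
    sto2_pfc: np.ndarray
    spo2: np.ndarray
    pr: np.ndarray
    artifact_mask: np.ndarray
    ftoe_ac: np.ndarray | None = None
    ftoe_pfc: np.ndarray | None = None
    quality: dict = field(default_factory=dict)

    def signals(self) -> dict[str, np.ndarray]:
        out = {
            "sto2_ac": self.sto2_ac,
            "sto2_pfc": self.sto2_pfc,
            "spo2": self.spo2,
            "pr": self.pr,
        }
        if self.ftoe_ac is not None:
            out["ftoe_ac"] = self.ftoe_ac
        if self.ftoe_pfc is not None:
            out["ftoe_pfc"] = self.ftoe_pfc
        return out


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------

def _interp_nan(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linearly bridge interior NaN runs; returns (filled, was_nan)."""
    x = np.asarray(x, dtype=float)
    nanmask = np.isnan(x)
    if not nanmask.any():
        return x, nanmask
    filled = x.copy()
    idx = np.arange(len(x))
    good = ~nanmask
    if good.sum() == 0:
        return filled, nanmask
    filled[nanmask] = np.interp(idx[nanmask], idx[good], x[good])
    return filled, nanmask


def downsample_antialias(series: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Decimate a uniform series with a zero-phase FIR antialiasing filter.

    The rate ratio must be a positive integer.  The low-pass cutoff sits at
    0.8 x the output Nyquist; the filter is applied forward and reverse
    (filtfilt) so features keep their timing.  Samples that were missing in
    the input map to missing outputs (any NaN among the q source samples of
    an output point).
    """
    series = np.asarray(series, dtype=float)
    ratio = fs_in / fs_out
    q = int(round(ratio))
    if q < 1 or abs(ratio - q) > 1e-9:
        raise ValueError(f"unsupported rate ratio {fs_in}/{fs_out} (must be integer)")
    if q == 1:
        return series.copy()
    filled, nanmask = _interp_nan(series)
    cutoff = 0.8 * (fs_out / 2.0)
    numtaps = min(101, 2 * (len(filled) // 7) + 1)
    numtaps = max(numtaps, 5)
    if numtaps % 2 == 0:
        numtaps += 1
    taps = signal.firwin(numtaps, cutoff, fs=fs_in)
    if len(filled) <= 3 * numtaps:
        raise ValueError("series shorter than filter length")
    smoothed = signal.filtfilt(taps, [1.0], filled)
    out = smoothed[::q]
    # propagate missingness: output k draws on source samples k*q .. k*q+q-1
    n_out = len(out)
    pad = np.append(nanmask, [False] * ((-len(nanmask)) % q))
    src_nan = pad.reshape(-1, q).any(axis=1)[:n_out]
    out[src_nan] = np.nan
    return out


# ---------------------------------------------------------------------------
# Savitzky-Golay smoothing (missing-value aware)
# ---------------------------------------------------------------------------

def smooth_savgol(
    series: np.ndarray,
    order: int,
    window_s: float,
    fs: float,
    max_missing_fraction: float = 1.0 / 3.0,
) -> np.ndarray:
    """Savitzky-Golay smoothing with local polynomial edge handling.

    The window in samples is the nearest odd width to ``window_s * fs``.
    Windows containing missing values refit the polynomial on the present
    points; a window with more than ``max_missing_fraction`` missing yields a
    missing output.  Polynomials of degree <= ``order`` pass through
    unchanged (including at the edges, which use the first/last full window's
    polynomial, as in scipy's ``mode='interp'``).
    """
    series = np.asarray(series, dtype=float)
    w = int(round(window_s * fs))
    if w % 2 == 0:
        w += 1
    if w < order + 2:
        raise ValueError(
            f"SG window of {w} samples too short for polynomial order {order}"
        )
    if len(series) < w:
        raise ValueError("series shorter than SG window")
    nanmask = np.isnan(series)
    if not nanmask.any():
        return signal.savgol_filter(series, w, order, mode="interp")

    half = w // 2
    n = len(series)
    out = np.full(n, np.nan)
    for i in range(n):
        lo = i - half
        # edge windows are anchored inside the series (interp-style)
        lo = min(max(lo, 0), n - w)
        win = series[lo : lo + w]
        pos = ~np.isnan(win)
        if (~pos).sum() > max_missing_fraction * w:
            continue
        x = (np.arange(lo, lo + w) - i).astype(float)
        coef = np.polynomial.polynomial.polyfit(x[pos], win[pos], order)
        out[i] = coef[0]  # polynomial evaluated at the centre (x=0)
    out[nanmask] = np.nan
    return out


# ---------------------------------------------------------------------------
# motion-artifact masking
# ---------------------------------------------------------------------------

def moving_sd(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving sample SD; edge windows shrink rather than pad."""
    s = pd.Series(x)
    return (
        s.rolling(window=window, center=True, min_periods=2).std(ddof=1).to_numpy()
    )


def motion_mask(
    accel: np.ndarray,
    fs_accel: float,
    window_s: float,
    threshold: float | str,
    fs_out: float = 0.25,
    n_out: int | None = None,
    auto_k: float = 3.0,
    accel_sum: str = "sum",
) -> tuple[np.ndarray, float]:
    """Boolean artifact mask on the common output grid.

    The three acceleration axes are combined (literal x+y+z sum by default),
    a centered 50 s moving SD is computed, and accel samples where it
    strictly exceeds ``threshold`` are flagged.  ``threshold="auto"`` uses
    ``auto_k`` x the median moving SD.  The flag is carried to the coarser
    output grid by logical OR over the accel samples each output sample
    covers.  Returns ``(mask, chosen_T)``.
    """
    accel = np.asarray(accel, dtype=float)
    if accel.ndim != 2 or accel.shape[0] != 3:
        raise ValueError("accel must have shape (3, n)")
    n_acc = accel.shape[1]
    if n_out is None:
        n_out = math.ceil(n_acc * fs_out / fs_accel)
    if np.isnan(accel).all():
        warnings.warn("acceleration entirely missing; no artifact masking applied")
        return np.zeros(n_out, dtype=bool), float("nan")
    combined = (
        np.nansum(accel, axis=0)
        if accel_sum == "sum"
        else np.sqrt(np.nansum(accel**2, axis=0))
    )
    win = max(2, int(round(window_s * fs_accel)))
    sd = moving_sd(combined, win)
    if threshold == "auto":
        T = auto_k * float(np.nanmedian(sd))
    else:
        T = float(threshold)
        if T < 0:
            raise ValueError("threshold must be >= 0")
    accel_flag = np.where(np.isnan(sd), False, sd > T)
    # output sample j covers accel times in [j/fs_out, (j+1)/fs_out)
    src_grid = np.floor(np.arange(n_acc) * fs_out / fs_accel).astype(int)
    mask = np.zeros(n_out, dtype=bool)
    np.add.at(mask, src_grid[accel_flag & (src_grid < n_out)], True)
    return mask, T


# ---------------------------------------------------------------------------
# full session preprocessing
# ---------------------------------------------------------------------------

def preprocess_session(
    rec: SessionRecording,
    cfg: PreprocessCfg | None = None,
    protocol: StudyProtocol | None = None,
) -> PreprocessedSession:
    """Run the full conditioning chain on one session.

    StO2 is antialias-downsampled to ``cfg.target_fs``; SpO2 and PR are
    SG-smoothed; the motion mask removes flagged samples from all four
    channels simultaneously.  The quality report records the chosen
    threshold, the overall and per-interval masked fractions, and flags any
    interval losing more than half its samples (the session is retained).
    """
    cfg = cfg or PreprocessCfg()
    protocol = protocol or default_protocol()

    sto2_ac = downsample_antialias(rec.sto2_ac, rec.fs_sto2, cfg.target_fs)
    sto2_pfc = downsample_antialias(rec.sto2_pfc, rec.fs_sto2, cfg.target_fs)
    if abs(rec.fs_vitals - cfg.target_fs) > 1e-9:
        spo2 = downsample_antialias(rec.spo2, rec.fs_vitals, cfg.target_fs)
        pr = downsample_antialias(rec.pr, rec.fs_vitals, cfg.target_fs)
    else:
        spo2, pr = rec.spo2.copy(), rec.pr.copy()
    spo2 = smooth_savgol(spo2, cfg.sg_order, cfg.sg_window, cfg.target_fs)
    pr = smooth_savgol(pr, cfg.sg_order, cfg.sg_window, cfg.target_fs)

    n = min(len(sto2_ac), len(sto2_pfc), len(spo2), len(pr))
    sto2_ac, sto2_pfc, spo2, pr = (x[:n] for x in (sto2_ac, sto2_pfc, spo2, pr))

    mask, T = motion_mask(
        rec.accel,
        rec.fs_accel,
        cfg.accel_sd_window,
        cfg.artifact_threshold,
        fs_out=cfg.target_fs,
        n_out=n,
        auto_k=cfg.auto_threshold_k,
        accel_sum=cfg.accel_sum,
    )
    for x in (sto2_ac, sto2_pfc, spo2, pr):
        x[mask] = np.nan

    seg = segment(protocol, cfg.target_fs, n)
    per_interval = {
        k: float(mask[idx].mean()) if len(idx) else 0.0 for k, idx in seg.items()
    }
    flagged = [k for k, frac in per_interval.items() if frac > cfg.max_masked_fraction]
    if flagged:
        warnings.warn(
            f"session {rec.subject_id}: >{cfg.max_masked_fraction:.0%} of "
            f"interval(s) {flagged} masked as motion artifact"
        )
    quality = {
        "threshold_T": T,
        "masked_fraction": float(mask.mean()),
        "masked_fraction_per_interval": per_interval,
        "flagged_intervals": flagged,
    }
    return PreprocessedSession(
        subject_id=rec.subject_id,
        fs=cfg.target_fs,
        time=np.arange(n) / cfg.target_fs,
        sto2_ac=sto2_ac,
        sto2_pfc=sto2_pfc,
        spo2=spo2,
        pr=pr,
        artifact_mask=mask,
        quality=quality,
    )
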