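"""Physiology-based engagement labeling from ocular signals.

Ground truth for the classifier comes not from self-report but from two
ocular indices measured against a 90-s neutral baseline:

* pupillometry Z:  Z_p = (mu_baseline - mu_task) / sd_task, with the task
  mean and sd taken over the encoding window's pupil trace;
* blink-rate Z:    Z_b = (mu_baseline - rate_window) / sd_task_rates, with
  rates expressed in blinks per window duration.

Each window then receives two points — pupil +1 when Z_p <= 0 (pupil at
least as large as baseline), blink +1 when Z_b >= 0 (blinking no more than
baseline) and -1 otherwise — and the sign of the summed score gives the
class: positive = high engagement, negative = low, zero = unlabeled (the
two indices disagree; such windows are dropped from the corpus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .session import SessionRecording

__all__ = [
    "UndefinedZError",
    "EngagementIndex",
    "preprocess_eog",
    "detect_blinks",
    "engagement_zscore",
    "pupil_zscore",
    "blink_zscore",
    "score_window",
    "label_session",
]

BLINK_THRESHOLD_UV = 50.0
BLINK_REFRACTORY_S = 0.2
PUPIL_LOWPASS_HZ = 4.0
LONG_GAP_S = 0.5  # tracker gaps longer than this are excluded from means


class UndefinedZError(ValueError):
    """Z-score undefined: zero task standard deviation or an empty trace."""


@dataclass(frozen=True)
class EngagementIndex:
    z_pupil: float
    z_blink: float
    point_pupil: int
    point_blink: int

    @property
    def total_score(self) -> int:
        return self.point_pupil + self.point_blink


def preprocess_eog(x: np.ndarray, fs: float) -> np.ndarray:
    """Linear detrend followed by a zero-phase 0.1-20 Hz band-pass.

    The EOG's physiological content lives in 0.1-20 Hz; detrending first
    removes electrode baseline drift so the filter transient is small.
    """
    x = np.asarray(x, dtype=float)
    if fs < 100.0:
        raise ValueError("EOG sampling rate must be >= 100 Hz for a 20 Hz band edge")
    if len(x) < 10 * fs:
        raise ValueError("need at least 10 s of EOG signal")
    x = signal.detrend(x, type="linear")
    sos = signal.butter(4, [0.1, 20.0], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def detect_blinks(
    filtered_eog: np.ndarray,
    fs: float,
    threshold_uv: float = BLINK_THRESHOLD_UV,
    refractory_s: float = BLINK_REFRACTORY_S,
) -> np.ndarray:
    """Blink event times (s): local maxima above ``threshold_uv``.

    Peaks closer than the refractory separation are merged into the larger
    one, so a single biphasic transient is never counted twice.
    """
    x = np.asarray(filtered_eog, dtype=float)
    if x.size == 0:
        raise ValueError("empty EOG signal")
    peaks, _ = signal.find_peaks(
        x, height=threshold_uv, distance=max(1, int(round(refractory_s * fs)))
    )
    return peaks / fs


def engagement_zscore(mu_baseline: float, mu_task: float, sd_task: float) -> float:
    """The labeling Z statistic: (baseline mean - task mean) / task sd.

    Note the asymmetry — the numerator is baseline-referenced but the
    denominator is the task-period sd; this is implemented verbatim.
    """
    if not np.isfinite(sd_task) or sd_task <= 0:
        raise UndefinedZError(f"task sd must be finite and > 0, got {sd_task}")
    return (mu_baseline - mu_task) / sd_task


def _interpolate_gaps(trace: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear-fill NaN gaps; returns (filled trace, long-gap mask)."""
    x = np.asarray(trace, dtype=float).copy()
    nan = ~np.isfinite(x)
    if nan.all():
        raise UndefinedZError("pupil trace is entirely missing")
    if nan.any():
        idx = np.arange(len(x))
        x[nan] = np.interp(idx[nan], idx[~nan], x[~nan])
    return x, nan


def _long_gap_mask(nan: np.ndarray, fs: float) -> np.ndarray:
    """True where a missing run exceeds LONG_GAP_S."""
    mask = np.zeros(len(nan), dtype=bool)
    limit = int(round(LONG_GAP_S * fs))
    i = 0
    while i < len(nan):
        if nan[i]:
            j = i
            while j < len(nan) and nan[j]:
                j += 1
            if j - i > limit:
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


def _clean_pupil(trace: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate tracker gaps, 4 Hz low-pass; returns (trace, keep-mask)."""
    filled, nan = _interpolate_gaps(trace)
    if fs > 2 * PUPIL_LOWPASS_HZ and len(filled) > 30:
        sos = signal.butter(4, PUPIL_LOWPASS_HZ, btype="lowpass", fs=fs, output="sos")
        filled = signal.sosfiltfilt(sos, filled)
    keep = ~_long_gap_mask(nan, fs)
    if not keep.any():
        raise UndefinedZError("pupil trace is one long tracker gap")
    return filled, keep


def pupil_zscore(
    baseline_trace: np.ndarray, task_trace: np.ndarray, fs: float
) -> float:
    """Per-window pupillometry Z against the neutral baseline.

    Both traces may contain NaN tracker gaps (blinks); short gaps are
    linearly interpolated, runs longer than 500 ms are excluded from the
    means. A 4 Hz low-pass denoises the trace first — pupil dynamics are
    below ~2 Hz.
    """
    base, keep_b = _clean_pupil(np.asarray(baseline_trace, float), fs)
    task, keep_t = _clean_pupil(np.asarray(task_trace, float), fs)
    mu_baseline = float(base[keep_b].mean())
    mu_task = float(task[keep_t].mean())
    sd_task = float(task[keep_t].std(ddof=1)) if keep_t.sum() > 1 else 0.0
    return engagement_zscore(mu_baseline, mu_task, sd_task)


def blink_zscore(
    baseline_rate: float, task_rates_per_window: np.ndarray
) -> np.ndarray:
    """Per-window blink-rate Z values.

    ``baseline_rate`` and the task rates are blinks per window duration.
    The scale is the across-window sd of the task rates — a single window's
    blink count has no internal spread to standardize by.
    """
    rates = np.asarray(task_rates_per_window, dtype=float)
    if rates.size < 2:
        raise UndefinedZError("need >= 2 task windows for a blink-rate sd")
    sd = float(rates.std(ddof=1))
    if sd <= 0:
        raise UndefinedZError("blink-rate sd across windows is zero")
    return (baseline_rate - rates) / sd


def score_window(z_pupil: float, z_blink: float) -> tuple[int, int, int, str]:
    """Apply the two-index scoring table.

    Returns (point_pupil, point_blink, total_score, class). Pupil scores +1
    when Z <= 0 (dilated or unchanged relative to baseline), blinking +1
    when Z >= 0 (reduced or unchanged); boundary zeros sit in the +1 row.
    """
    if not (np.isfinite(z_pupil) and np.isfinite(z_blink)):
        raise UndefinedZError("scores require finite Z values")
    point_pupil = 1 if z_pupil <= 0 else -1
    point_blink = 1 if z_blink >= 0 else -1
    total = point_pupil + point_blink
    cls = "high" if total > 0 else ("low" if total < 0 else "unlabeled")
    return point_pupil, point_blink, total, cls


def label_session(session: SessionRecording) -> pd.DataFrame:
    """Label every encoding window of a session from its EOG and pupil trace.

    Baseline statistics are computed once per participant from the 90-s
    neutral segment. Returns a frame with one row per encoding window:
    window_id, z_pupil, z_blink, point_pupil, point_blink, score, class.
    """
    eog = session.streams["eog"]
    pupil = session.streams["pupil"]
    base = session.baseline_window
    windows = session.encoding_windows

    filt = preprocess_eog(eog.samples, eog.fs)
    blink_times = detect_blinks(filt, eog.fs)

    def count_in(w):
        return int(np.sum((blink_times >= w.start_s) & (blink_times < w.end_s)))

    window_s = windows[0].duration_s
    # baseline blink rate expressed per window duration
    base_rate = count_in(base) * window_s / base.duration_s
    task_counts = np.array([count_in(w) for w in windows], dtype=float)
    z_blink = blink_zscore(base_rate, task_counts)

    base_trace = session.slice("pupil", base.start_s, base.end_s)
    z_pupil = np.array(
        [
            pupil_zscore(
                base_trace,
                session.slice("pupil", w.start_s, w.end_s),
                pupil.fs,
            )
            for w in windows
        ]
    )

    rows = []
    for i, w in enumerate(windows):
        pp, pb, score, cls = score_window(z_pupil[i], z_blink[i])
        rows.append(
            dict(
                window_id=i,
                z_pupil=z_pupil[i],
                z_blink=z_blink[i],
                point_pupil=pp,
                point_blink=pb,
                score=score,
                label=cls,
            )
        )
    return pd.DataFrame(rows)
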