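"""Calcium transient event metrics and the group-comparison statistics.

Event detection works per ROI on an extracted fluorescence trace: the
baseline is a low percentile of the trace (10th by default), noise is the
median absolute deviation about that baseline scaled by 0.6745, candidate
peaks are local maxima clearing baseline + k*sigma (k = 3 by default) with
prominence of at least k*sigma — so noise ripples riding on a transient's
tail do not fragment it into spurious events — and a minimum separation of
2 frames; each event's duration is the width of
its peak at 5% of the peak height above baseline, with crossings located by
linear interpolation between frames. Overlapping peaks are split at the
inter-peak minimum; widths clipped by the trace ends are flagged censored.

Measured this way the duration is invariant to affine transforms of the
trace: gain rescales peak height and level together, offsets move baseline
and level together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .detect import DONOHO_FACTOR
from .io import CalciumRecording


@dataclass
class GroupComparison:
    groups: list
    values: dict                 # condition -> 1-D array
    f_statistic: float
    anova_p: float
    pairwise: dict               # (cond_a, cond_b) -> Tukey-adjusted p


def _bounds_at_level(x: np.ndarray, peaks: np.ndarray, k: int,
                     level: float) -> tuple[float, float, bool]:
    """Left/right crossing positions (fractional frames) of peak k at
    *level*, bounded by the inter-peak minima (overlap split) and the trace
    ends (censoring)."""
    p = peaks[k]
    lo_lim = 0 if k == 0 else int(peaks[k - 1] + np.argmin(
        x[peaks[k - 1]:p + 1]))
    hi_lim = x.size - 1 if k == peaks.size - 1 else int(p + np.argmin(
        x[p:peaks[k + 1] + 1]))
    censored = False

    i = p
    while i > lo_lim and x[i - 1] >= level:
        i -= 1
    if i > lo_lim:                         # crossing between i-1 and i
        left = (i - 1) + (level - x[i - 1]) / (x[i] - x[i - 1])
    else:                                  # hit the split point / trace start
        left = float(i)
        censored = censored or i == 0

    j = p
    while j < hi_lim and x[j + 1] >= level:
        j += 1
    if j < hi_lim:
        right = j + (x[j] - level) / (x[j] - x[j + 1])
    else:
        right = float(j)
        censored = censored or j == x.size - 1
    return left, right, censored


def detect_calcium_events(recording: CalciumRecording,
                          threshold_k: float = 3.0,
                          baseline_percentile: float = 10.0,
                          min_separation: int = 2,
                          width_fraction: float = 0.05) -> pd.DataFrame:
    """Detect transients on every ROI; return the event table.

    Columns: roi, peak_time_s, peak_height, duration_s, censored, condition.
    """
    rows = []
    for r, roi in enumerate(recording.roi_ids):
        x = recording.traces[r]
        if x.size < 10:
            raise ValueError("need at least 10 frames per ROI")
        baseline = float(np.percentile(x, baseline_percentile))
        sigma = float(np.median(np.abs(x - baseline)) / DONOHO_FACTOR)
        height = baseline + threshold_k * sigma
        peaks, _ = signal.find_peaks(x, height=height,
                                     prominence=threshold_k * sigma,
                                     distance=max(min_separation, 1))
        for k, p in enumerate(peaks):
            level = baseline + width_fraction * (x[p] - baseline)
            left, right, censored = _bounds_at_level(x, peaks, k, level)
            duration = (right - left) * recording.frame_interval
            rows.append({
                "roi": roi,
                "peak_time_s": p * recording.frame_interval,
                "peak_height": float(x[p] - baseline),
                "duration_s": float(duration),
                "censored": bool(censored),
                "condition": recording.condition_label,
            })
    return pd.DataFrame(rows, columns=["roi", "peak_time_s", "peak_height",
                                       "duration_s", "censored", "condition"])


def event_frequency(events: pd.DataFrame, recording_duration: float,
                    roi_ids: list | None = None) -> pd.Series:
    """Events per minute per ROI; ROIs without events report 0."""
    if recording_duration <= 0:
        raise ValueError("recording_duration must be > 0")
    counts = events.groupby("roi").size() if len(events) else pd.Series(dtype=int)
    if roi_ids is not None:
        counts = counts.reindex(roi_ids, fill_value=0)
    return counts / recording_duration * 60.0


def compare_groups(values_by_condition: dict) -> GroupComparison:
    """One-way fixed-effects ANOVA followed by Tukey's HSD on all pairs."""
    if len(values_by_condition) < 2:
        raise ValueError("need at least 2 groups")
    labels = list(values_by_condition)
    arrays = [np.asarray(values_by_condition[g], dtype=float) for g in labels]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        f, p = 0.0, 1.0
        pairwise = {(a, b): 1.0 for i, a in enumerate(labels)
                    for b in labels[i + 1:]}
        return GroupComparison(labels, dict(zip(labels, arrays)), f, p, pairwise)
    f, p = stats.f_oneway(*arrays)
    res = stats.tukey_hsd(*arrays)
    pairwise = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            pairwise[(a, labels[j])] = float(res.pvalue[i, j])
    return GroupComparison(labels, dict(zip(labels, arrays)),
                           float(f), float(p), pairwise)
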