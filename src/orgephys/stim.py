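"""Stimulus-response metrics on spike trains.

Per channel: firing rates in the baseline and stimulation windows, the
activity criterion (>= 5 spikes/min across the stimulation period), and the
responder criterion (|rate change| >= 10% of baseline) evaluated on active
channels. Per organoid: mean rates across active channels and the responding
percentage. Population event traces binarize each active channel's spikes on
a 1 ms grid, sum across channels and smooth with a unit-mass 100 ms kernel.
The paired baseline-vs-stimulation comparison is an exact two-sided Wilcoxon
signed-rank test (full sign enumeration) at the small sample sizes these
experiments have.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import AnalysisConfig
from .detect import SpikeTrain
from .io import StimulationProtocol

#: tolerance for >= comparisons against rate criteria, so that a count that
#: meets a criterion exactly (e.g. 50 spikes in 600 s vs 5/min) is not lost
#: to float rounding of 5/60.
_REL_TOL = 1e-9


@dataclass
class ChannelSummary:
    channel_id: object
    baseline_rate: float        # Hz
    stim_rate: float            # Hz
    active: bool
    responder: bool
    relative_change: float      # (stim - baseline)/baseline; NaN if undefined


@dataclass
class OrganoidResult:
    organoid_id: object
    mean_rate_baseline: float   # mean over active channels (Hz); NaN if none
    mean_rate_stim: float
    n_active: int
    n_responding: int
    percent_responding: float   # 100 * n_responding / n_active; NaN if none


@dataclass
class PopulationEventTrace:
    times: np.ndarray           # bin centers on the 1 ms grid (s)
    values: np.ndarray          # smoothed summed binarized counts


def _rate(train: SpikeTrain, window: tuple) -> float:
    t0, t1 = window
    dur = t1 - t0
    if dur <= 0:
        raise ValueError("zero-length analysis window")
    return train.count_in(window) / dur


def classify_channels(trains: list[SpikeTrain],
                      protocol: StimulationProtocol,
                      config: AnalysisConfig) -> list[ChannelSummary]:
    """Rates, activity and responder status for every channel.

    Activity is tested on the stimulation window. Responders are active
    channels whose rate changed by at least `responder_fraction` of baseline
    in either direction; a channel silent at baseline but spiking under
    stimulation is a responder with undefined (NaN) relative change.
    """
    out = []
    for tr in trains:
        b = _rate(tr, protocol.baseline_window)
        s = _rate(tr, protocol.stimulation_window)
        active = s >= config.active_rate_min * (1 - _REL_TOL)
        if b > 0:
            change = (s - b) / b
            responder = active and abs(change) >= config.responder_fraction * (
                1 - _REL_TOL)
        else:
            change = np.nan
            responder = active and s > 0
        out.append(ChannelSummary(tr.channel_id, b, s, bool(active),
                                  bool(responder), change))
    return out


def summarize_organoid(summaries: list[ChannelSummary],
                       organoid_id: object = "organoid") -> OrganoidResult:
    """Aggregate one organoid: rate means and responder percentage over its
    active channels. With no active channel the means and percentage are NaN
    sentinels, never 0."""
    act = [s for s in summaries if s.active]
    n_resp = sum(s.responder for s in act)
    if act:
        mb = float(np.mean([s.baseline_rate for s in act]))
        ms = float(np.mean([s.stim_rate for s in act]))
        pct = 100.0 * n_resp / len(act)
    else:
        mb = ms = pct = float("nan")
    return OrganoidResult(organoid_id, mb, ms, len(act), int(n_resp), pct)


def organoid_rate_pair(summaries: list[ChannelSummary],
                       normalize: str = "per-channel") -> tuple[float, float]:
    """Per-organoid (baseline, stimulation) values for the paired test.

    "per-channel": each active channel's rates are divided by its own
    baseline rate before averaging (baseline value ~= 1); channels silent at
    baseline are excluded. "none": plain means in Hz.
    """
    act = [s for s in summaries if s.active]
    if not act:
        return float("nan"), float("nan")
    if normalize == "per-channel":
        act_nz = [s for s in act if s.baseline_rate > 0]
        if not act_nz:
            return float("nan"), float("nan")
        b = float(np.mean([1.0 for _ in act_nz]))
        s = float(np.mean([x.stim_rate / x.baseline_rate for x in act_nz]))
        return b, s
    if normalize == "none":
        return (float(np.mean([x.baseline_rate for x in act])),
                float(np.mean([x.stim_rate for x in act])))
    raise ValueError("normalize must be 'per-channel' or 'none'")


# ---------------------------------------------------------------------------
# population event trace
# ---------------------------------------------------------------------------

def population_event_trace(trains: list[SpikeTrain], config: AnalysisConfig,
                           t_start: float = 0.0,
                           t_stop: float | None = None) -> PopulationEventTrace:
    """Binarize spikes per channel on the bin grid, sum across channels,
    smooth with a unit-mass kernel spanning `kernel_width` (101 bins at the
    defaults). Kernel mass 1 conserves the total count of occupied
    (channel, bin) pairs, up to mass lost off the trace ends."""
    bw = config.bin_width
    if t_stop is None:
        t_stop = max((tr.times[-1] for tr in trains if tr.n_spikes), default=0.0)
    n_bins = max(int(np.ceil((t_stop - t_start) / bw)), 1)
    summed = np.zeros(n_bins)
    for tr in trains:
        idx = np.floor((tr.times - t_start) / bw).astype(np.int64)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        binar = np.zeros(n_bins, dtype=bool)
        binar[idx] = True                      # binarized per channel
        summed += binar
    half = int(round(config.kernel_width / bw / 2))
    if config.kernel_shape == "boxcar":
        kernel = np.ones(2 * half + 1)
    else:
        xx = np.arange(-half, half + 1)
        kernel = np.exp(-0.5 * (xx / (half / 2.0)) ** 2)
    kernel /= kernel.sum()
    values = np.convolve(summed, kernel, mode="same")
    times = t_start + (np.arange(n_bins) + 0.5) * bw
    return PopulationEventTrace(times, values)


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _exact_two_sided_p(w_plus: float, doubled_ranks: np.ndarray) -> float:
    """P-value from the exact null distribution of W+ over all 2^n sign
    assignments, computed by convolving one two-point distribution per rank
    (each sign vector contributes exactly once)."""
    total = int(doubled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        nxt = dist.copy()
        nxt[r:] += dist[:total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    p_lo = dist[:w2 + 1].sum()
    p_hi = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def paired_wilcoxon(baseline, stim, exact_max_n: int = 25
                    ) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped before ranking; tied |differences| get
    mid-ranks. For n <= exact_max_n the p-value is exact over all 2^n sign
    assignments; above that a normal approximation with tie correction is
    used. Returns (statistic, p) with statistic = min(W+, W-).
    """
    baseline = np.asarray(baseline, dtype=float)
    stim = np.asarray(stim, dtype=float)
    if baseline.shape != stim.shape:
        raise ValueError("paired samples must have equal length")
    d = stim - baseline
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))          # mid-ranks on ties
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)
    if n <= exact_max_n:
        doubled = np.rint(2 * ranks).astype(np.int64)  # mid-ranks -> integers
        p = _exact_two_sided_p(w_plus, doubled)
    else:
        mn = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (counts ** 3 - counts).sum() / 48.0)
        z = (w_plus - mn) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return statistic, p
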