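"""Independent brute-force reference implementations used only by tests.

These stay deliberately literal (per-sample scans, explicit enumeration) so
they share no code path with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def oracle_detect(x: np.ndarray, sigma: float, threshold_k: float,
                  refractory: float, amplitude_gate: float,
                  sampling_rate: float) -> list[int]:
    """Literal spike detection: scan samples for suprathreshold excursions of
    |x|, timestamp each at its extremum (first max on ties, edges dropped),
    gate on |extremum|, then a keep-first refractory scan."""
    det = np.abs(np.asarray(x, dtype=float))
    thr = threshold_k * sigma
    n = det.size
    candidates = []
    i = 0
    while i < n:
        if det[i] > thr:
            j = i
            best, best_v = i, det[i]
            while j < n and det[j] > thr:
                if det[j] > best_v:
                    best, best_v = j, det[j]
                j += 1
            if 0 < best < n - 1:
                candidates.append(best)
            i = j
        else:
            i += 1
    gated = [s for s in candidates if det[s] >= amplitude_gate]
    accepted: list[int] = []
    last = -np.inf
    for s in gated:
        t = s / sampling_rate
        if t - last >= refractory:
            accepted.append(s)
            last = t
    return accepted


def oracle_wilcoxon_two_sided(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p by explicit enumeration of all 2^n sign
    assignments (mid-ranks on tied |d|). Feasible for n <= ~14."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    dist = []
    for signs in itertools.product([0, 1], repeat=n):
        dist.append(sum(r for s, r in zip(signs, ranks) if s))
    dist = np.asarray(dist)
    p_lo = np.mean(dist <= w_plus + 1e-12)
    p_hi = np.mean(dist >= w_plus - 1e-12)
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def oracle_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    """Forward keep-first scan, one event at a time."""
    out = []
    last = -np.inf
    for t in times:
        if t - last >= refractory:
            out.append(t)
            last = t
    return np.asarray(out)
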