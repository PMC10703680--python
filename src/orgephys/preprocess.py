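"""Channel quality control and signal conditioning before spike detection.

The conditioning order is fixed: QC on the raw signal, then bandpass, then
common median reference. Swapping the (nonlinear) median reference with the
filter changes results and is not offered on the default path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import RecordingSession


@dataclass
class PreprocessReport:
    """Outcome of channel QC plus the filter specification applied."""

    channel_sd: dict            # channel_id -> raw s.d. (uV), pre-removal
    median_sd: float            # median of channel_sd over all channels
    removed_channels: list      # channel_ids with sd > factor x median
    filter_spec: dict = field(default_factory=dict)


def reject_bad_channels(session: RecordingSession,
                        factor: float = 2.0
                        ) -> tuple[RecordingSession, PreprocessReport]:
    """Remove channels whose raw s.d. exceeds *factor* times the median s.d.

    The comparison is strict (> factor x median); the median is taken over
    all channels before any removal. Requires at least two channels.
    """
    if session.n_channels < 2:
        raise ValueError("channel QC requires at least 2 channels")
    sds = session.samples.std(axis=1)
    med = float(np.median(sds))
    keep = [i for i, sd in enumerate(sds) if not sd > factor * med]
    removed = [session.channel_ids[i] for i in range(session.n_channels)
               if i not in keep]
    report = PreprocessReport(
        channel_sd={cid: float(sd) for cid, sd in zip(session.channel_ids, sds)},
        median_sd=med,
        removed_channels=removed,
    )
    return session.select_channels(keep), report


def butter_sos(low: float, high: float, order: int,
               sampling_rate: float) -> np.ndarray:
    """Design the bandpass as second-order sections; checks Nyquist."""
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= sampling_rate / 2:
        raise ValueError(
            f"band edge {high} Hz violates Nyquist ({sampling_rate / 2} Hz)")
    return signal.butter(order, [low, high], btype="band",
                         fs=sampling_rate, output="sos")


def bandpass(session: RecordingSession, low: float = 300.0,
             high: float = 3000.0, order: int = 4) -> RecordingSession:
    """Zero-phase Butterworth bandpass, applied forward-backward per channel.

    The forward-backward application leaves spike timestamps unshifted; the
    effective magnitude response is that of twice the design order.
    """
    sos = butter_sos(low, high, order, session.sampling_rate)
    filtered = signal.sosfiltfilt(sos, session.samples, axis=-1)
    return RecordingSession(filtered, session.sampling_rate,
                            list(session.channel_ids), session.geometry)


def common_median_reference(session: RecordingSession) -> RecordingSession:
    """Subtract the across-channel median from every channel at each sample."""
    if session.n_channels < 2:
        raise ValueError("common median reference requires >= 2 channels")
    med = np.median(session.samples, axis=0, keepdims=True)
    return RecordingSession(session.samples - med, session.sampling_rate,
                            list(session.channel_ids), session.geometry)


def preprocess(session: RecordingSession, low: float = 300.0,
               high: float = 3000.0, order: int = 4,
               bad_channel_factor: float = 2.0
               ) -> tuple[RecordingSession, PreprocessReport]:
    """Default conditioning chain: QC -> bandpass -> common median reference."""
    kept, report = reject_bad_channels(session, bad_channel_factor)
    out = common_median_reference(bandpass(kept, low, high, order))
    report.filter_spec = {"band": (low, high), "order": order,
                          "phase": "zero (forward-backward)"}
    return out, report
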