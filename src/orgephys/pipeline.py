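"""Streaming detection pipeline for recordings too large to hold as floats.

Stages mirror the in-memory path exactly — QC on raw s.d., zero-phase
Butterworth bandpass, common median reference, Donoho noise floor, then the
threshold/refractory/gate detection chain — but operate on a disk-backed
int16 recording in time chunks:

1. one cheap pass accumulates per-channel raw mean/power for the QC s.d.;
2. one pass filters retained channels per chunk (forward-backward, with
   real-data margins absorbing the filter transient), subtracts the
   across-channel median, and stores the conditioned signal as int16 at
   0.01 uV/LSB in a scratch memmap (channel-major);
3. per channel, sigma = median(|x|)/0.6745 over the full conditioned trace,
   then spike detection on the full trace.

With a chunk no shorter than the recording the filtering reduces to a single
sosfiltfilt call, i.e. the in-memory path.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
from scipy import signal

from .config import AnalysisConfig
from .detect import SpikeTrain, detect_spikes, estimate_noise_sigma
from .io import read_sidecar
from .preprocess import PreprocessReport, butter_sos

STORE_UV_PER_LSB = 0.01   # scratch quantization; ~3 orders below thresholds


def _filtfilt_chunk(sos: np.ndarray, block: np.ndarray,
                    at_edge: bool) -> np.ndarray:
    """Zero-phase filtering of a chunk that carries real-data margins.

    Chunks touching a recording edge go through sosfiltfilt so the edge
    handling (odd-extension padding, matched initial conditions) is the one
    the in-memory path uses; interior chunks use a plain forward-backward
    pass whose start-up transients die inside the margins.
    """
    if at_edge:
        return signal.sosfiltfilt(sos, block, axis=-1)
    y = signal.sosfilt(sos, block, axis=-1)[..., ::-1]
    y = signal.sosfilt(sos, y, axis=-1)[..., ::-1]
    return y


def run_file_pipeline(binary_path: str | Path, sidecar_path: str | Path,
                      config: AnalysisConfig, chunk_s: float = 30.0,
                      margin_s: float = 0.5,
                      scratch_dir: str | Path | None = None
                      ) -> tuple[list[SpikeTrain], PreprocessReport]:
    """QC + condition + detect on a flat int16 recording, chunk by chunk.

    Returns per-retained-channel spike trains (timestamps on the recording
    clock) and the preprocess report.
    """
    meta = read_sidecar(sidecar_path)
    n_ch = int(meta["n_channels"])
    fs = float(meta["sampling_rate"])
    scale = float(meta["uv_per_lsb"])
    channel_ids = meta.get("channel_ids", list(range(n_ch)))
    raw = np.memmap(binary_path, dtype="<i2", mode="r").reshape(-1, n_ch)
    n_samples = raw.shape[0]
    step = max(int(round(chunk_s * fs)), 1)
    margin = int(round(margin_s * fs))

    # --- pass 1: raw per-channel s.d. for QC -----------------------------
    acc_sum = np.zeros(n_ch)
    acc_sq = np.zeros(n_ch)
    for start in range(0, n_samples, step):
        blk = raw[start:start + step].astype(np.float32)
        acc_sum += blk.sum(axis=0, dtype=np.float64)
        acc_sq += np.einsum("ij,ij->j", blk, blk, dtype=np.float64)
    mean = acc_sum / n_samples
    sds = np.sqrt(np.maximum(acc_sq / n_samples - mean ** 2, 0.0)) * scale
    med = float(np.median(sds))
    keep = [i for i in range(n_ch) if not sds[i] > config.bad_channel_factor * med]
    removed = [channel_ids[i] for i in range(n_ch) if i not in keep]
    report = PreprocessReport(
        channel_sd={channel_ids[i]: float(sds[i]) for i in range(n_ch)},
        median_sd=med, removed_channels=removed,
        filter_spec={"band": (config.band_low, config.band_high),
                     "order": config.filter_order,
                     "phase": "zero (forward-backward)"})
    if len(keep) < 2:
        raise ValueError("fewer than 2 channels survive QC")

    # --- pass 2: filter + CMR -> scratch int16 ---------------------------
    sos = butter_sos(config.band_low, config.band_high, config.filter_order,
                     fs).astype(np.float32)
    tmp = tempfile.NamedTemporaryFile(dir=scratch_dir, suffix=".filt.i2",
                                      delete=False)
    tmp.close()
    cond = np.memmap(tmp.name, dtype=np.int16, mode="w+",
                     shape=(len(keep), n_samples))
    inv = np.float32(scale / STORE_UV_PER_LSB)
    for start in range(0, n_samples, step):
        stop = min(start + step, n_samples)
        a = max(start - margin, 0)
        b = min(stop + margin, n_samples)
        blk = np.ascontiguousarray(raw[a:b, keep].T).astype(np.float32)
        y = _filtfilt_chunk(sos, blk, at_edge=(a == 0 or b == n_samples))
        y = y[:, start - a:y.shape[1] - (b - stop)]
        y -= np.median(y, axis=0, keepdims=True)
        y *= inv
        np.rint(y, out=y)
        np.clip(y, -32768, 32767, out=y)
        cond[:, start:stop] = y.astype(np.int16)
    cond.flush()

    # --- pass 3: sigma + detection per retained channel ------------------
    trains = []
    for row, i in enumerate(keep):
        x = cond[row].astype(np.float32) * np.float32(STORE_UV_PER_LSB)
        sigma = estimate_noise_sigma(x)
        trains.append(detect_spikes(x, sigma, config, fs,
                                    channel_id=channel_ids[i]))
    del cond
    Path(tmp.name).unlink(missing_ok=True)
    return trains, report
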