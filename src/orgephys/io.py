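"""Core data containers and file formats.

On-disk raw format: flat binary of integer samples in channel-interleaved
frames (frame = one sample per channel), described by a JSON sidecar carrying
the channel count, sampling rate, sample dtype, byte order and uV scaling.
All internal times are seconds (float) and all voltages uV; the conversion
from raw integer units happens exactly once, at read time.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig, ConfigError


class FormatError(ValueError):
    """Raised when an on-disk payload does not match its declared layout."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RecordingSession:
    """A multichannel extracellular recording held in memory.

    samples : (n_channels, n_samples) float array, uV.
    geometry : optional per-channel (shank, site) indices.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_ids: list
    geometry: list | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError("channel_ids length must match sample rows")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if self.geometry is not None and len(self.geometry) != self.samples.shape[0]:
            raise ValueError("geometry length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def select_channels(self, keep: Sequence[int]) -> "RecordingSession":
        """Return a session restricted to the channel row indices in *keep*."""
        keep = list(keep)
        geom = [self.geometry[i] for i in keep] if self.geometry is not None else None
        return RecordingSession(
            samples=self.samples[keep],
            sampling_rate=self.sampling_rate,
            channel_ids=[self.channel_ids[i] for i in keep],
            geometry=geom,
        )


@dataclass
class StimulationProtocol:
    """Optogenetic pulse protocol plus the analysis windows.

    The published protocol is 500 ms pulses every 10 s for 10 min, following
    a 10 min baseline recording.
    """

    pulse_onsets: np.ndarray
    pulse_duration: float
    baseline_window: tuple
    stimulation_window: tuple

    def __post_init__(self) -> None:
        self.pulse_onsets = np.asarray(self.pulse_onsets, dtype=float)
        if self.pulse_duration < 0:
            raise ValueError("pulse_duration must be >= 0")
        if np.any(np.diff(self.pulse_onsets) < self.pulse_duration):
            raise ValueError("pulses overlap: onsets closer than pulse_duration")
        b0, b1 = self.baseline_window
        s0, s1 = self.stimulation_window
        if not (b1 > b0 and s1 > s0):
            raise ValueError("windows must have positive length")
        if max(b0, s0) < min(b1, s1):
            raise ValueError("baseline and stimulation windows overlap")
        if self.pulse_onsets.size and (
                self.pulse_onsets[0] < s0
                or self.pulse_onsets[-1] + self.pulse_duration > s1):
            raise ValueError("pulses must lie within the stimulation window")

    @classmethod
    def periodic(cls, baseline_duration: float = 600.0,
                 stimulation_duration: float = 600.0,
                 period: float = 10.0,
                 pulse_duration: float = 0.5) -> "StimulationProtocol":
        """The standard protocol: pulses every *period* seconds during the
        stimulation epoch that directly follows the baseline epoch."""
        s0 = baseline_duration
        onsets = np.arange(s0, s0 + stimulation_duration - pulse_duration + 1e-9,
                           period)
        return cls(onsets, pulse_duration, (0.0, baseline_duration),
                   (s0, s0 + stimulation_duration))

    def pulse_intervals(self) -> np.ndarray:
        """(n_pulses, 2) array of [onset, offset] times in seconds."""
        return np.column_stack([self.pulse_onsets,
                                self.pulse_onsets + self.pulse_duration])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pulse_onsets": self.pulse_onsets.tolist(),
            "pulse_duration": self.pulse_duration,
            "baseline_window": list(self.baseline_window),
            "stimulation_window": list(self.stimulation_window),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulationProtocol":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["pulse_onsets"]), d["pulse_duration"],
                   tuple(d["baseline_window"]), tuple(d["stimulation_window"]))


@dataclass
class CalciumRecording:
    """Extracted per-ROI fluorescence traces (arbitrary units)."""

    traces: np.ndarray              # (n_rois, n_frames)
    frame_interval: float           # seconds per frame
    roi_ids: list
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if len(self.roi_ids) != self.traces.shape[0]:
            raise ValueError("roi_ids length must match trace rows")

    @property
    def n_rois(self) -> int:
        return self.traces.shape[0]

    @property
    def duration(self) -> float:
        return self.traces.shape[1] * self.frame_interval


# ---------------------------------------------------------------------------
# raw binary + sidecar
# ---------------------------------------------------------------------------

_REQUIRED_SIDECAR_KEYS = ("n_channels", "sampling_rate", "dtype",
                          "uv_per_lsb", "byte_order")


def read_sidecar(sidecar_path: str | Path) -> dict:
    meta = json.loads(Path(sidecar_path).read_text())
    missing = [k for k in _REQUIRED_SIDECAR_KEYS if k not in meta]
    if missing:
        raise ConfigError(f"sidecar missing required key(s): {', '.join(missing)}")
    return meta


def _sample_dtype(meta: dict) -> np.dtype:
    order = {"little": "<", "big": ">"}.get(meta["byte_order"])
    if order is None:
        raise ConfigError("byte_order must be 'little' or 'big'")
    try:
        return np.dtype(order + np.dtype(meta["dtype"]).char)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(f"unsupported sample dtype {meta['dtype']!r}") from exc


def read_recording(binary_path: str | Path,
                   sidecar_path: str | Path) -> RecordingSession:
    """Read a flat channel-interleaved binary recording into uV.

    Raises ConfigError for an incomplete sidecar and FormatError when the
    payload length is not a whole number of frames.
    """
    meta = read_sidecar(sidecar_path)
    n_ch = int(meta["n_channels"])
    dt = _sample_dtype(meta)
    raw = np.fromfile(binary_path, dtype=dt)
    if raw.size % n_ch:
        raise FormatError(
            f"payload of {raw.size} samples is not divisible by "
            f"{n_ch} channels (truncated or mislabelled file)")
    frames = raw.reshape(-1, n_ch)              # frame-major on disk
    samples = frames.T.astype(np.float64) * float(meta["uv_per_lsb"])
    geometry = meta.get("geometry")
    if geometry is not None:
        geometry = [tuple(g) for g in geometry]
    channel_ids = meta.get("channel_ids", list(range(n_ch)))
    return RecordingSession(samples, float(meta["sampling_rate"]),
                            channel_ids, geometry)


def write_recording(session: RecordingSession,
                    binary_path: str | Path,
                    sidecar_path: str | Path,
                    uv_per_lsb: float = 0.195) -> None:
    """Write a session as interleaved little-endian int16 plus JSON sidecar.

    Integer payloads read with the same scale round-trip bit-exactly.
    """
    q = np.rint(session.samples / uv_per_lsb)
    if np.any(np.abs(q) > np.iinfo(np.int16).max):
        raise FormatError("voltage exceeds int16 range at this uv_per_lsb")
    q.astype("<i2").T.tofile(binary_path)        # back to frame-major
    meta = {
        "n_channels": session.n_channels,
        "sampling_rate": session.sampling_rate,
        "dtype": "int16",
        "uv_per_lsb": uv_per_lsb,
        "byte_order": "little",
        "channel_ids": list(session.channel_ids),
    }
    if session.geometry is not None:
        meta["geometry"] = [list(g) for g in session.geometry]
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# trace tables and result tables
# ---------------------------------------------------------------------------

def read_traces_csv(path: str | Path, condition_label: str = "") -> CalciumRecording:
    """Read a trace table: a `time_s` column plus one column per ROI."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError("trace table must contain a 'time_s' column")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise FormatError("trace table needs at least two frames")
    dt = float(np.median(np.diff(t)))
    rois = [c for c in df.columns if c != "time_s"]
    return CalciumRecording(df[rois].to_numpy(float).T, dt, rois, condition_label)


def write_traces_csv(recording: CalciumRecording, path: str | Path) -> None:
    t = np.arange(recording.traces.shape[1]) * recording.frame_interval
    df = pd.DataFrame({"time_s": t})
    for i, roi in enumerate(recording.roi_ids):
        df[str(roi)] = recording.traces[i]
    df.to_csv(path, index=False)


def write_tables(out_dir: str | Path,
                 config: AnalysisConfig,
                 seed: int,
                 spikes: Sequence | None = None,
                 summaries: Sequence | None = None,
                 events: pd.DataFrame | None = None) -> dict:
    """Write delimited result tables plus a JSON manifest.

    spikes : iterable of SpikeTrain -> spikes.csv (channel, time_s, amplitude_uV)
    summaries : iterable of ChannelSummary -> channel_summary.csv
    events : calcium event DataFrame -> calcium_events.csv
    Returns the manifest dict (also written to manifest.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    if spikes is not None:
        rows = [(tr.channel_id, f"{t:.6f}", f"{a:.3f}")
                for tr in spikes for t, a in zip(tr.times, tr.amplitudes)]
        df = pd.DataFrame(rows, columns=["channel", "time_s", "amplitude_uV"])
        df.to_csv(out / "spikes.csv", index=False)
        written.append("spikes.csv")
    if summaries is not None:
        df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
        df.to_csv(out / "channel_summary.csv", index=False)
        written.append("channel_summary.csv")
    if events is not None:
        events.to_csv(out / "calcium_events.csv", index=False)
        written.append("calcium_events.csv")

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": int(seed),
        "files": written,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
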