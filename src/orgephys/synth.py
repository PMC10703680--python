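"""Ground-truthed synthetic recordings.

Two generators, both fully seeded:

* extracellular voltage: per-unit Poisson spike trains (2 ms refractory by
  thinning), a biphasic negative-leading template per spike, per-channel
  Gaussian noise, constructed bad channels with inflated noise, and
  stimulus-locked rate modulation on designated responder channels;
* GCaMP-like fluorescence: per-ROI Poisson event times convolved with a
  double-exponential kernel A*(exp(-t/tau_d) - exp(-t/tau_r)) on a
  nonnegative baseline, plus Gaussian noise, sampled at the 65 ms frame
  interval of the emulated acquisition.

Responder modulation defaults to the "window" extent: unit rates on
responder channels are multiplied across the whole stimulation window,
emulating the sustained network-level rate elevation seen in the tissue;
"pulse" restricts the elevation to the light pulses themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .io import CalciumRecording, RecordingSession, StimulationProtocol

# ---------------------------------------------------------------------------
# spike template
# ---------------------------------------------------------------------------

TEMPLATE_SPAN = (-0.5e-3, 1.0e-3)   # seconds around the trough; 1.5 ms support
TROUGH_TO_PEAK = 3.0


def spike_template(sampling_rate: float) -> tuple[np.ndarray, int]:
    """Biphasic difference-of-Gaussians waveform, trough normalized to -1.

    Returns (waveform, trough_index). The trough leads; the late positive
    lobe is 1/3 of the trough by construction.
    """
    t = np.arange(round(TEMPLATE_SPAN[0] * sampling_rate),
                  round(TEMPLATE_SPAN[1] * sampling_rate) + 1) / sampling_rate
    g1 = np.exp(-0.5 * (t / 0.12e-3) ** 2)
    g2 = np.exp(-0.5 * ((t - 0.45e-3) / 0.20e-3) ** 2)
    r = 1.0 / TROUGH_TO_PEAK
    for _ in range(40):  # fixed point: peak/|trough| -> 1/3
        w = -g1 + r * g2
        r *= (-w.min() / TROUGH_TO_PEAK) / w.max()
    w = -g1 + r * g2
    w /= -w.min()
    return w, int(np.argmin(w))


# ---------------------------------------------------------------------------
# spike-train layer
# ---------------------------------------------------------------------------

@dataclass
class EphysGroundTruth:
    """Exactly what the voltage generator inserted."""

    unit_spike_times: list            # per-unit sorted seconds
    unit_channel_map: np.ndarray      # unit -> channel index
    unit_amplitudes: np.ndarray       # uV (trough depth)
    responder_channels: set
    rate_multiplier: float
    noise_sigma: np.ndarray           # per-channel uV
    bad_channels: set
    sampling_rate: float = 30000.0

    def channel_spike_times(self, channel: int) -> np.ndarray:
        parts = [t for t, c in zip(self.unit_spike_times, self.unit_channel_map)
                 if c == channel]
        return np.sort(np.concatenate(parts)) if parts else np.empty(0)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "unit_spike_times": [t.tolist() for t in self.unit_spike_times],
            "unit_channel_map": self.unit_channel_map.tolist(),
            "unit_amplitudes": self.unit_amplitudes.tolist(),
            "responder_channels": sorted(self.responder_channels),
            "rate_multiplier": self.rate_multiplier,
            "noise_sigma": self.noise_sigma.tolist(),
            "bad_channels": sorted(self.bad_channels),
            "sampling_rate": self.sampling_rate,
        }
        Path(path).write_text(json.dumps(payload))


def _rate_segments(duration: float, protocol: StimulationProtocol | None,
                   base_rate: float, multiplier: float,
                   modulated: bool, modulation: str) -> list[tuple]:
    """(t0, t1, rate) pieces covering [0, duration)."""
    if not modulated or protocol is None or multiplier == 1.0:
        return [(0.0, duration, base_rate)]
    if modulation == "window":
        s0, s1 = protocol.stimulation_window
        segs = [(0.0, s0, base_rate), (s0, s1, base_rate * multiplier),
                (s1, duration, base_rate)]
    elif modulation == "pulse":
        segs, prev = [], 0.0
        for a, b in protocol.pulse_intervals():
            segs.append((prev, a, base_rate))
            segs.append((a, b, base_rate * multiplier))
            prev = b
        segs.append((prev, duration, base_rate))
    else:
        raise ValueError("modulation must be 'window' or 'pulse'")
    return [(a, b, r) for a, b, r in segs if b > a]


def thin_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    """Keep-first refractory thinning of sorted times.

    Iteratively deletes the second event of the first violation in every run
    of consecutive violations; equivalent to a forward keep-first scan
    (property-tested against the one-event-at-a-time reference)."""
    while times.size > 1:
        bad = np.flatnonzero(np.diff(times) < refractory)
        if bad.size == 0:
            break
        run_starts = np.flatnonzero(np.diff(bad) > 1) + 1
        first_of_run = bad[np.concatenate([[0], run_starts])]
        times = np.delete(times, first_of_run + 1)
    return times


def poisson_train(rng: np.random.Generator, segments: list[tuple],
                  refractory: float = 0.002) -> np.ndarray:
    """Piecewise-homogeneous Poisson times, thinned to the refractory period
    (delete any event closer than *refractory* after an accepted one)."""
    parts = []
    for t0, t1, rate in segments:
        if rate < 0:
            raise ValueError("negative rate")
        n = rng.poisson(rate * (t1 - t0))
        parts.append(rng.uniform(t0, t1, size=n))
    times = np.sort(np.concatenate(parts)) if parts else np.empty(0)
    if refractory > 0:
        times = thin_refractory(times, refractory)
    return times


def simulate_spike_trains(n_channels: int, duration: float,
                          protocol: StimulationProtocol | None,
                          units_per_channel: int = 1,
                          base_rate: float = 2.0,
                          rate_multiplier: float = 1.0,
                          responder_channels: set | None = None,
                          amplitude_range: tuple = (80.0, 150.0),
                          noise_sigma: float = 5.0,
                          bad_channels: set | None = None,
                          bad_noise_factor: float = 5.0,
                          sampling_rate: float = 30000.0,
                          modulation: str = "window",
                          seed: int = 0) -> EphysGroundTruth:
    """Draw the ground truth (no voltage synthesis)."""
    if base_rate < 0:
        raise ValueError("base_rate must be >= 0")
    if protocol is not None:
        for w in (protocol.baseline_window, protocol.stimulation_window):
            if w[1] > duration + 1e-9:
                raise ValueError("analysis windows exceed the recording duration")
    responder_channels = set(responder_channels or ())
    bad_channels = set(bad_channels or ())
    rng = np.random.default_rng(seed)

    unit_times, unit_chan, unit_amp = [], [], []
    for ch in range(n_channels):
        segs = _rate_segments(duration, protocol, base_rate, rate_multiplier,
                              ch in responder_channels, modulation)
        for _ in range(units_per_channel):
            unit_times.append(poisson_train(rng, segs))
            unit_chan.append(ch)
            unit_amp.append(rng.uniform(*amplitude_range))

    sig = np.full(n_channels, float(noise_sigma))
    for ch in bad_channels:
        sig[ch] = noise_sigma * bad_noise_factor
    return EphysGroundTruth(unit_times, np.asarray(unit_chan),
                            np.asarray(unit_amp), responder_channels,
                            rate_multiplier, sig, bad_channels, sampling_rate)


# ---------------------------------------------------------------------------
# voltage synthesis
# ---------------------------------------------------------------------------

def _insert_spikes(block: np.ndarray, start: int, truth: EphysGroundTruth,
                   template: np.ndarray, trough: int) -> None:
    """Add templates whose support intersects sample range
    [start, start + block.shape[1]) in place."""
    n = block.shape[1]
    L = template.size
    for times, ch, amp in zip(truth.unit_spike_times, truth.unit_channel_map,
                              truth.unit_amplitudes):
        if times.size == 0:
            continue
        s0 = np.rint(times * truth.sampling_rate).astype(np.int64) - trough
        lo, hi = start - L, start + n
        for s in s0[(s0 > lo) & (s0 < hi)]:
            a = max(s, start)
            b = min(s + L, start + n)
            block[ch, a - start:b - start] += amp * template[a - s:b - s]


def synthesize_chunks(truth: EphysGroundTruth, duration: float,
                      chunk_s: float = 30.0):
    """Yield (start_sample, float32 block) chunks of the voltage recording.

    Noise streams are per-channel, so the synthesized voltage is independent
    of the chunk size. The noise seed derives from the ground-truth arrays'
    generator chain stored on `truth._noise_rngs` (set by simulate_ephys*).
    """
    fs = truth.sampling_rate
    n_samples = int(round(duration * fs))
    template, trough = spike_template(fs)
    rngs = truth.__dict__.get("_noise_rngs")
    if rngs is None:
        raise ValueError("ground truth lacks noise generators; "
                         "use the simulate_ephys entry points")
    step = int(round(chunk_s * fs))
    for start in range(0, n_samples, step):
        n = min(step, n_samples - start)
        block = np.empty((len(truth.noise_sigma), n), dtype=np.float32)
        for c, rng in enumerate(rngs):
            block[c] = rng.standard_normal(n, dtype=np.float32)
            block[c] *= np.float32(truth.noise_sigma[c])
        _insert_spikes(block, start, truth, template, trough)
        yield start, block


def simulate_ephys(n_channels: int, duration: float,
                   protocol: StimulationProtocol | None = None,
                   seed: int = 0, **kwargs
                   ) -> tuple[RecordingSession, EphysGroundTruth]:
    """In-memory voltage synthesis; see simulate_spike_trains for knobs."""
    truth = simulate_spike_trains(n_channels, duration, protocol,
                                  seed=seed, **kwargs)
    truth.__dict__["_noise_rngs"] = np.random.default_rng(
        (seed, 1)).spawn(n_channels)
    fs = truth.sampling_rate
    n_samples = int(round(duration * fs))
    samples = np.empty((n_channels, n_samples), dtype=np.float32)
    for start, block in synthesize_chunks(truth, duration):
        samples[:, start:start + block.shape[1]] = block
    session = RecordingSession(samples, fs, list(range(n_channels)))
    return session, truth


def simulate_ephys_to_file(binary_path: str | Path, sidecar_path: str | Path,
                           n_channels: int, duration: float,
                           protocol: StimulationProtocol | None = None,
                           seed: int = 0, uv_per_lsb: float = 0.195,
                           chunk_s: float = 30.0, **kwargs) -> EphysGroundTruth:
    """Stream the synthesized recording straight to the flat-binary format.

    Identical ground truth and noise streams as simulate_ephys at the same
    seed; memory use stays at one chunk.
    """
    truth = simulate_spike_trains(n_channels, duration, protocol,
                                  seed=seed, **kwargs)
    truth.__dict__["_noise_rngs"] = np.random.default_rng(
        (seed, 1)).spawn(n_channels)
    with open(binary_path, "wb") as fh:
        for _, block in synthesize_chunks(truth, duration, chunk_s):
            q = np.rint(block / uv_per_lsb)
            np.clip(q, -32768, 32767, out=q)
            fh.write(q.astype("<i2").T.tobytes())   # frame-major
    meta = {
        "n_channels": n_channels,
        "sampling_rate": truth.sampling_rate,
        "dtype": "int16",
        "uv_per_lsb": uv_per_lsb,
        "byte_order": "little",
        "channel_ids": list(range(n_channels)),
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))
    return truth


# ---------------------------------------------------------------------------
# calcium traces
# ---------------------------------------------------------------------------

def double_exp_kernel(t: np.ndarray, tau_rise: float,
                      tau_decay: float) -> np.ndarray:
    """exp(-t/tau_decay) - exp(-t/tau_rise) for t >= 0, else 0."""
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0,
                   np.exp(-np.clip(t, 0, None) / tau_decay)
                   - np.exp(-np.clip(t, 0, None) / tau_rise), 0.0)
    return out


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Closed-form maximum location of the double-exponential kernel."""
    return np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (
        tau_decay - tau_rise)


def kernel_width_at_fraction(tau_rise: float, tau_decay: float,
                             fraction: float = 0.05) -> float:
    """Analytic width of the kernel at *fraction* of its peak (root-finding
    on the closed form; the kernel is unimodal)."""
    tp = kernel_peak_time(tau_rise, tau_decay)
    peak = double_exp_kernel(np.array(tp), tau_rise, tau_decay).item()
    level = fraction * peak

    def f(t):
        return double_exp_kernel(np.array(t), tau_rise, tau_decay).item() - level

    left = brentq(f, 1e-12, tp)
    hi = tp
    while f(hi) > 0:
        hi *= 2
    right = brentq(f, tp, hi)
    return right - left


@dataclass
class CalciumGroundTruth:
    """Inserted calcium events plus the analytic kernel width."""

    event_times: list                 # per-ROI sorted seconds
    kernel_rise: float
    kernel_decay: float
    amplitudes: list                  # per-ROI arrays (kernel coefficient)
    noise_sigma: float
    true_duration: float              # analytic width at 5% of the kernel peak
    baseline: float = 0.0


def simulate_calcium(n_rois: int, duration: float = 390.0,
                     frame_interval: float = 0.065,
                     event_rate: float = 3.0,
                     kernel_rise: float = 0.2, kernel_decay: float = 1.5,
                     amplitude: float = 1.0, noise_sigma: float = 0.05,
                     baseline: float = 1.0, width_fraction: float = 0.05,
                     seed: int = 0,
                     condition_label: str = ""
                     ) -> tuple[CalciumRecording, CalciumGroundTruth]:
    """GCaMP-like traces: Poisson events (rate in events/min) convolved with
    the double-exponential kernel, plus baseline and Gaussian noise."""
    if kernel_rise >= kernel_decay:
        raise ValueError("kernel_rise must be < kernel_decay")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / frame_interval))
    t = np.arange(n_frames) * frame_interval
    traces = np.full((n_rois, n_frames), float(baseline))
    ev_times, ev_amps = [], []
    for r in range(n_rois):
        n_ev = rng.poisson(event_rate / 60.0 * duration)
        times = np.sort(rng.uniform(0, duration, size=n_ev))
        amps = np.full(n_ev, float(amplitude))
        for t0, a in zip(times, amps):
            traces[r] += a * double_exp_kernel(t - t0, kernel_rise, kernel_decay)
        ev_times.append(times)
        ev_amps.append(amps)
    if noise_sigma > 0:
        traces += rng.normal(0, noise_sigma, size=traces.shape)
    rec = CalciumRecording(traces, frame_interval,
                           [f"roi{r}" for r in range(n_rois)], condition_label)
    truth = CalciumGroundTruth(
        ev_times, kernel_rise, kernel_decay, ev_amps, noise_sigma,
        kernel_width_at_fraction(kernel_rise, kernel_decay, width_fraction),
        baseline)
    return rec, truth
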