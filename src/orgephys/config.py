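"""Analysis configuration: every tunable constant of the pipeline in one place.

The defaults are the published analysis constants of the recording pipeline
this package reimplements: a 300-3,000 Hz fourth-order Butterworth band,
spike threshold at 5 noise s.d., 2 ms refractory period, 40 uV amplitude
gate, 5 spikes/min activity criterion, 10% responder criterion, 1 ms binning
with a 100 ms smoothing kernel, 2x median-s.d. channel rejection, and the
5%-height width level for calcium events.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    """Raised for unknown configuration keys or violated invariants."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Immutable bundle of every analysis constant.

    Units: frequencies in Hz, times in seconds, voltages in uV.
    """

    band_low: float = 300.0          # bandpass low edge (Hz)
    band_high: float = 3000.0        # bandpass high edge (Hz)
    filter_order: int = 4            # Butterworth design order
    threshold_k: float = 5.0         # spike threshold, multiples of noise s.d.
    refractory: float = 0.002        # minimum spike separation (s); 0 disables
    amplitude_gate: float = 40.0     # minimum spike extremum magnitude (uV)
    active_rate_min: float = 5.0 / 60.0   # activity criterion (Hz) = 5 spikes/min
    responder_fraction: float = 0.10      # |rate change|/baseline for responders
    bin_width: float = 0.001         # population-trace bin (s)
    kernel_width: float = 0.100      # population-trace smoothing kernel (s)
    bad_channel_factor: float = 2.0  # reject channels with SD > factor x median
    peak_width_fraction: float = 0.05  # calcium width level (fraction of peak)
    polarity: str = "abs"            # spike detection polarity: "abs" or "neg"
    kernel_shape: str = "boxcar"     # population kernel: "boxcar" or "gaussian"
    normalize: str = "per-channel"   # organoid rate normalization mode
    ca_threshold_k: float = 3.0      # calcium peak threshold (noise s.d.)
    ca_baseline_percentile: float = 10.0  # calcium baseline percentile
    ca_min_separation: int = 2       # calcium minimum peak separation (frames)
    seed: int = 0

    def validate(self) -> "AnalysisConfig":
        """Check invariants; return self. Raises ConfigError naming the key."""
        if not self.band_low > 0:
            raise ConfigError("band_low must be > 0")
        if not self.band_high > self.band_low:
            raise ConfigError("band_high must exceed band_low")
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")
        for key in ("threshold_k", "amplitude_gate", "active_rate_min",
                    "responder_fraction", "refractory"):
            if getattr(self, key) < 0:
                raise ConfigError(f"{key} must be >= 0")
        for key in ("bin_width", "kernel_width", "bad_channel_factor"):
            if not getattr(self, key) > 0:
                raise ConfigError(f"{key} must be > 0")
        if not 0 < self.peak_width_fraction < 1:
            raise ConfigError("peak_width_fraction must lie in (0, 1)")
        if self.polarity not in ("abs", "neg"):
            raise ConfigError("polarity must be 'abs' or 'neg'")
        if self.kernel_shape not in ("boxcar", "gaussian"):
            raise ConfigError("kernel_shape must be 'boxcar' or 'gaussian'")
        if self.normalize not in ("per-channel", "none"):
            raise ConfigError("normalize must be 'per-channel' or 'none'")
        if self.ca_min_separation < 1:
            raise ConfigError("ca_min_separation must be >= 1")
        if not 0 <= self.ca_baseline_percentile < 50:
            raise ConfigError("ca_baseline_percentile must lie in [0, 50)")
        return self

    def with_overrides(self, **overrides: Any) -> "AnalysisConfig":
        known = {f.name for f in fields(self)}
        unknown = sorted(set(overrides) - known)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
        return replace(self, **overrides).validate()

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Stable hash of the full effective configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> AnalysisConfig:
    """Load an AnalysisConfig from a flat YAML mapping, applying overrides.

    Unspecified keys take the published defaults; unknown keys raise
    ConfigError (no silent typo tolerance). An empty or missing-content file
    yields the full default configuration.
    """
    values: dict[str, Any] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration file must be a flat key-value mapping")
        values.update(raw)
    if overrides:
        values.update(overrides)
    return AnalysisConfig().with_overrides(**values)
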