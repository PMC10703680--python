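# Methods

This note documents the models, rules and numerical choices behind
`orgephys`: a pipeline for establishing functional connectivity from
optogenetic stimulus-response experiments in fused-organoid (assembloid)
tissue, recorded with multishank silicon probes, and for quantifying calcium
transients in extracted fluorescence traces.

## Extracellular pipeline

### Signal model and conditioning

A recording is a channels x samples voltage matrix in microvolts, sampled at
30 kHz (64 channels on a 4-shank x 16-site probe in the emulated setup).
Conditioning runs in a fixed order:

1. **Channel QC.** The standard deviation of each channel's *raw* signal is
   computed over the whole recording; channels strictly exceeding twice the
   median of these SDs are removed. The median is taken over all channels
   before any removal, and the factor (default 2) is configurable
   (`bad_channel_factor`). QC precedes filtering because a saturated or
   floating channel is identified by its broadband power.
2. **Bandpass.** A 4th-order Butterworth design, 300-3,000 Hz, applied
   forward-backward per channel (`scipy.signal.sosfiltfilt`). Zero net phase
   means spike timestamps are not shifted by filtering; the price is that
   the effective magnitude response is that of an 8th-order filter. The
   Nyquist constraint is checked at filter time, not config-load time,
   because it depends on the recording.
3. **Common median reference.** At each sample the across-channel median is
   subtracted from every channel, removing shared artifacts. For even
   channel counts the median is the mean of the two central order
   statistics; for odd counts the post-CMR across-channel median is exactly
   zero at every sample (property-tested).

Swapping CMR and filtering would change results (the median is nonlinear)
and is not offered on the default path.

### Spike detection

Per conditioned channel:

- **Noise floor.** sigma = median(|x|) / 0.6745, the MAD-about-zero rule
  for a high-pass signal. It is consistent for Gaussian noise and barely
  inflated by sparse spikes.
- **Threshold.** Contiguous excursions of |x| above `threshold_k` x sigma
  (default 5). Detection uses both polarities by default because the
  amplitude criterion is phrased as deviation from the noise floor;
  `polarity: neg` restricts to negative-going events, the classical
  extracellular convention.
- **Timestamping.** One timestamp per excursion at its absolute extremum,
  sample-aligned (index / sampling rate, no sub-sample interpolation). An
  extremum at the first or last sample of the trace is an unresolvable peak
  and is discarded.
- **Amplitude gate.** Events with |extremum| below `amplitude_gate`
  (default 40 uV) are discarded. The gate is measured from zero of the
  conditioned signal: fluorescence-style baseline offsets do not exist
  after a 300 Hz high-pass, and "from the noise floor" is read as "clear of
  the noise floor", the interpretation that keeps the criterion a fixed
  voltage.
- **Refractory.** A forward scan over the gated spikes discards any
  timestamp closer than `refractory` (default 2 ms) to the last accepted
  one (keep-first, deterministic).

The gate is applied *before* the refractory scan. This ordering matters:
zero-phase filtering gives every biphasic spike small side-lobe excursions
within a millisecond of its trough. If sub-gate candidates entered the
refractory scan they would absorb the genuine spike under keep-first and
the gate would then delete them, collapsing recall; with gate-first, the
refractory rule does what it is for — de-duplicating events that already
qualify as spikes. Detection is scale-equivariant (scaling signal and gate
together leaves timestamps unchanged) and monotone (raising the threshold
or gate never adds spikes); both are property-tested, and the whole chain
is tested for exact agreement with a literal per-sample brute-force
implementation on random traces.

### Streaming pipeline for large recordings

A 64-channel, 20-minute, 30 kHz recording is 2.3e9 samples — too large to
hold as floats in ordinary memory. `run_file_pipeline` therefore processes
the flat int16 recording in time chunks: one cheap pass accumulates raw
mean/power per channel for QC; one pass filters retained channels per chunk
and applies CMR, storing the conditioned signal to a scratch memmap as
int16 at 0.01 uV per bit (three orders of magnitude below any detection
threshold); a final per-channel pass computes sigma over the full
conditioned trace and detects spikes. Interior chunks are filtered with a
plain forward-backward pass whose start-up transients die inside 0.5 s
real-data margins; chunks touching a recording edge use `sosfiltfilt` so
edge handling matches the in-memory path. With a chunk at least as long as
the recording the pipeline reduces to the in-memory path exactly, and
chunked versus single-chunk runs are tested to yield identical spike times.

### Stimulus-response metrics

The stimulation protocol is 500 ms light pulses every 10 s for 10 min,
following a 10 min baseline. Per channel, firing rates are spike counts
divided by window length in the baseline and stimulation windows.

- **Active**: stimulation-window rate >= 5 spikes/min (0.083 Hz). The
  comparison carries a 1e-9 relative tolerance so that a count meeting the
  criterion exactly (50 spikes in 600 s) is not lost to float rounding of
  5/60.
- **Responder**: an active channel with |stim - baseline| / baseline >=
  10%. The criterion is two-sided by default (the direction is recorded in
  the summary); a channel silent at baseline but spiking under stimulation
  is a responder with undefined (NaN) relative change.
- **Per organoid**: mean rates across active channels, responding
  percentage, and a (baseline, stimulation) value pair for the paired test.
  Because the original axis is ambiguous between plain Hz means and
  baseline-normalized rates, both modes exist (`normalize: per-channel`
  divides each channel by its own baseline mean, so the baseline value is
  ~1; `none` averages raw Hz). With no active channels all means are NaN
  sentinels, never zero.
- **Population event trace**: each active channel's spikes are binarized
  onto a 1 ms grid (a bin is occupied or not, per channel), summed across
  channels, and convolved with a unit-mass 100 ms boxcar (101 bins,
  same-length output); a Gaussian kernel of the same span is available.
  Unit kernel mass conserves total event mass (exactly, for spikes clear of
  the trace ends); the trace is a visualization object, not an inferential
  one.

### Paired statistics

The baseline-versus-stimulation comparison across organoids uses a
two-sided Wilcoxon signed-rank test, exact at small n: zero differences are
dropped, tied |differences| receive mid-ranks, and the null distribution of
W+ is computed over all 2^n sign assignments (as a convolution over doubled
mid-ranks, algebraically identical to explicit enumeration and feasible to
n = 25). The two-sided p is twice the smaller tail, capped at 1. Above
n = 25 a normal approximation with tie correction is used. At n = 7 with
all-positive differences the exact p is 2/128 = 0.015625; at n = 8 with
negative-rank sum 3 it is 10/256 = 0.0390625.

## Calcium pipeline

Input is a per-ROI fluorescence trace table (arbitrary units) with a frame
interval, emulating 65 ms/frame acquisition for up to 6.5 min; source
extraction (e.g. CaImAn) is upstream of this package's contract.

Per ROI: baseline = 10th percentile of the trace; noise sigma =
median(|x - baseline|) / 0.6745; candidate events are local maxima at least
`ca_threshold_k` x sigma above baseline (default 3), with prominence at
least the same k x sigma and separation >= 2 frames. The prominence
requirement exists because a slow transient's tail can stay above the
height threshold for seconds, and without it noise ripples on the tail
fragment one transient into many short events. **Event duration** is the
width of the peak at 5% of its height above baseline, with crossings
located by linear interpolation between frames; overlapping peaks are split
at the inter-peak minimum, and widths clipped by the trace ends are flagged
censored rather than dropped. Measuring the 5% level above the local
baseline makes the duration invariant to gain and offset of the trace
(property-tested). **Event frequency** is events per minute, reported per
ROI (zero-event ROIs report 0) and as a pooled rate.

Group comparisons (e.g. control / chronic / withdrawal conditions) use
one-way fixed-effects ANOVA followed by Tukey's HSD via the studentized
range distribution (`scipy.stats.f_oneway`, `scipy.stats.tukey_hsd`).

## Synthetic data generator

The generator provides ground-truthed stand-ins for the study's raw data,
at the study's conditions: 30 kHz, 64 channels, 10 min baseline + 10 min
stimulation with 500 ms pulses every 10 s; 65 ms frames for up to 6.5 min
of fluorescence.

**Voltage.** Each channel carries one or more units whose spike times are
piecewise-homogeneous Poisson processes thinned to a 2 ms refractory
(keep-first, matching the detection-side convention; thinning removes <1%
of events at rates <= 5 Hz). Each spike inserts a biphasic negative-leading
difference-of-Gaussians template with 1.5 ms support and a 3:1
trough-to-peak ratio, scaled to a per-unit amplitude drawn from 80-150 uV
by default (high SNR against 5 uV channel noise). Noise is Gaussian, white,
per-channel, from per-channel seeded streams (so synthesis is independent
of chunk size). Constructed bad channels receive 5x the nominal noise,
which guarantees they violate the 2x median-SD QC rule. Responder channels
multiply their unit rates by `rate_multiplier`; the default modulation
extent is the whole stimulation window, emulating the sustained
network-level rate elevation that distinguishes trans-synaptic drive from a
pulse-locked artifact — the observed rasters show elevation across the
stimulation epoch, and with 500 ms pulses at 5% duty cycle a pulse-locked
doubling would move the window-average rate by only ~5%, below the 10%
responder criterion. `modulation: pulse` restricts the elevation to the
pulses for pulse-locked analyses. No response latency or adaptation is
modeled; the modulation is an assumption of the generator, not an inference
from tissue.

**Fluorescence.** Events are homogeneous Poisson per ROI (default 3
events/min); each adds A * (exp(-t/tau_d) - exp(-t/tau_r)) with
tau_r = 0.2 s and tau_d = 1.5 s, representative of a slow indicator
(GCaMP6s-like); traces sit on a nonnegative baseline with Gaussian noise.
The analytic width of this kernel at 5% of its peak (by root-finding on the
closed form; the peak is at ln(tau_d/tau_r) * tau_d tau_r / (tau_d - tau_r))
is stored as ground truth, so measured durations have an exact reference.

What the generator does **not** emulate: spike waveform diversity and
overlap, electrode drift, line noise, pulse artifacts (the original
pipeline's treatment of photoelectric artifacts is unknown; none are
simulated or blanked), bursting statistics, calcium indicator saturation,
photobleaching, or motion. Passing recovery tests therefore demonstrates
the correctness of the analysis rules, not robustness to every property of
real tissue recordings.

## Validation experiments and problem sizes

- **Oracle equivalence**: 100 random 10 s traces (2 kHz grid for the
  per-sample reference scan) — detection matches the brute force exactly.
- **Full-scale recovery**: one 64-channel, 20-minute, 30 kHz recording
  (2.3e9 samples) through the streaming pipeline: recall and precision
  >= 95% at +-1 ms, exact bad-channel rejection, all modulated channels
  classified responders. The scripted acceptance run uses a 16-channel,
  10-minute version of the same experiment to keep its runtime modest.
- **Null calibration**: 200 simulated experiments of 8 organoids x 16
  channels at the spike-train level (the test statistic depends only on
  window rates, so voltage synthesis adds nothing); the exact Wilcoxon at
  n = 8 has achievable level 0.039, and the measured rejection rate at
  alpha = 0.05 falls within 5% +/- 2%. Calcium false events on 100 flat
  noisy ROIs stay below 0.05/min.
- **Closed forms**: triangular peaks give exactly 0.95 x base width at the
  5% level (linear interpolation is exact on linear flanks); the
  double-exponential transient's measured duration matches root-finding on
  the kernel within one 65 ms frame; population-trace mass conservation is
  exact for integer spike counts.

## Known limitations

- Multi-unit only: no spike sorting, no waveform clustering, no drift
  correction.
- The 40 uV gate interpretation (from zero rather than offset by the
  sigma-scaled floor) is one of two defensible readings; it is configurable
  and flagged for sensitivity analysis.
- The exact Wilcoxon's discreteness means the achievable test level at
  small n is below nominal alpha; calibration checks account for this.
- The streaming pipeline's scratch quantization (0.01 uV) can shift a
  channel's sigma estimate by up to ~0.5% relative to the in-memory path;
  spike sets are unaffected at realistic SNR.
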