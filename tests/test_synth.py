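import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from orgephys import (StimulationProtocol, double_exp_kernel,
                      kernel_peak_time, simulate_calcium, simulate_ephys,
                      simulate_spike_trains)
from orgephys.synth import spike_template, thin_refractory

from .oracles import oracle_refractory


class TestTemplate:
    def test_biphasic_negative_leading(self):
        w, trough = spike_template(30000.0)
        assert w[trough] == -1.0
        assert np.argmax(w) > trough            # positive lobe follows
        assert w.max() == pytest.approx(1 / 3, rel=1e-6)
        assert w.size == pytest.approx(0.0015 * 30000, abs=2)


class TestSpikeTrains:
    def test_zero_rate_zero_spikes(self, short_protocol):
        sess, truth = simulate_ephys(4, 20.0, short_protocol, seed=0,
                                     base_rate=0.0, noise_sigma=5.0)
        assert all(t.size == 0 for t in truth.unit_spike_times)
        # pure noise: sd close to the requested level
        assert sess.samples.std() == pytest.approx(5.0, rel=0.05)

    def test_generation_refractory_respected(self, short_protocol):
        truth = simulate_spike_trains(4, 20.0, short_protocol, seed=1,
                                      base_rate=40.0)
        for t in truth.unit_spike_times:
            if t.size > 1:
                assert np.diff(t).min() >= 0.002

    def test_null_multiplier_rates_match(self):
        """With multiplier 1 the pulse-window rate equals the baseline rate
        up to Poisson error (binomial test on pooled counts over 50 seeds)."""
        proto = StimulationProtocol.periodic(60.0, 60.0)
        in_pulse = out_pulse = 0
        pulses = proto.pulse_intervals()
        pulse_time = (pulses[:, 1] - pulses[:, 0]).sum()
        for seed in range(50):
            truth = simulate_spike_trains(2, 120.0, proto, seed=seed,
                                          base_rate=5.0, rate_multiplier=1.0,
                                          responder_channels={0, 1})
            for t in truth.unit_spike_times:
                t = t[(t >= 60.0) & (t < 120.0)]
                mask = np.zeros(t.size, dtype=bool)
                for a, b in pulses:
                    mask |= (t >= a) & (t < b)
                in_pulse += int(mask.sum())
                out_pulse += int((~mask).sum())
        frac = pulse_time / 60.0
        res = stats.binomtest(in_pulse, in_pulse + out_pulse, frac)
        assert res.pvalue > 0.01

    def test_baseline_count_poisson_tail(self):
        """600 s at 2 Hz: counts stay within 3*sqrt(1200) of 1200."""
        proto = StimulationProtocol.periodic(600.0, 10.0)
        for seed in range(20):
            truth = simulate_spike_trains(1, 610.0, proto, seed=seed,
                                          base_rate=2.0)
            n = ((truth.unit_spike_times[0] >= 0)
                 & (truth.unit_spike_times[0] < 600.0)).sum()
            assert abs(n - 1200) <= 3 * np.sqrt(1200)

    def test_window_modulation_raises_stim_rate(self, short_protocol):
        truth = simulate_spike_trains(2, 20.0, short_protocol, seed=3,
                                      base_rate=20.0, rate_multiplier=2.0,
                                      responder_channels={0})
        t0 = truth.channel_spike_times(0)
        t1 = truth.channel_spike_times(1)
        stim = lambda t: ((t >= 10) & (t < 20)).sum()
        base = lambda t: (t < 10).sum()
        assert stim(t0) > 1.5 * base(t0)
        assert stim(t1) < 1.5 * base(t1)

    def test_pulse_modulation_confined_to_pulses(self, short_protocol):
        truth = simulate_spike_trains(1, 20.0, short_protocol, seed=4,
                                      base_rate=50.0, rate_multiplier=4.0,
                                      responder_channels={0},
                                      modulation="pulse")
        t = truth.channel_spike_times(0)
        pulses = short_protocol.pulse_intervals()
        in_mask = np.zeros(t.size, dtype=bool)
        for a, b in pulses:
            in_mask |= (t >= a) & (t < b)
        pulse_time = (pulses[:, 1] - pulses[:, 0]).sum()
        in_rate = in_mask.sum() / pulse_time
        out_rate = ((t >= 10) & ~in_mask).sum() / (10.0 - pulse_time)
        assert in_rate > 2 * out_rate

    def test_windows_exceeding_duration_rejected(self, short_protocol):
        with pytest.raises(ValueError):
            simulate_spike_trains(2, 15.0, short_protocol)

    def test_negative_rate_rejected(self, short_protocol):
        with pytest.raises(ValueError):
            simulate_spike_trains(2, 20.0, short_protocol, base_rate=-1.0)

    def test_determinism(self, short_protocol):
        a, ta = simulate_ephys(3, 20.0, short_protocol, seed=9)
        b, tb = simulate_ephys(3, 20.0, short_protocol, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)
        for x, y in zip(ta.unit_spike_times, tb.unit_spike_times):
            np.testing.assert_array_equal(x, y)


@given(st.integers(0, 500))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_thinning_equals_forward_scan(seed):
    """Vectorized refractory thinning reproduces the event-by-event scan."""
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(0, 0.1, size=rng.integers(0, 60)))
    got = thin_refractory(times.copy(), 0.002)
    np.testing.assert_array_equal(got, oracle_refractory(times, 0.002))


class TestCalcium:
    def test_zero_event_rate_flat(self):
        rec, truth = simulate_calcium(3, 60.0, event_rate=0.0, seed=0)
        assert all(t.size == 0 for t in truth.event_times)
        assert rec.traces.std() == pytest.approx(0.05, rel=0.1)

    def test_peak_time_closed_form(self):
        """Noiseless single event peaks at ln(td/tr)*td*tr/(td-tr)."""
        tr, td = 0.2, 1.5
        tstar = kernel_peak_time(tr, td)
        assert tstar == pytest.approx(np.log(td / tr) * td * tr / (td - tr))
        t = np.linspace(0, 10, 200001)
        k = double_exp_kernel(t, tr, td)
        assert t[np.argmax(k)] == pytest.approx(tstar, abs=1e-3)

    def test_rise_slower_than_decay_rejected(self):
        with pytest.raises(ValueError):
            simulate_calcium(1, 10.0, kernel_rise=2.0, kernel_decay=1.0)

    def test_determinism(self):
        a, _ = simulate_calcium(2, 30.0, seed=7)
        b, _ = simulate_calcium(2, 30.0, seed=7)
        np.testing.assert_array_equal(a.traces, b.traces)

    def test_frame_interval_default(self):
        rec, _ = simulate_calcium(1, 13.0)
        assert rec.frame_interval == 0.065
        assert rec.traces.shape[1] == 200


class TestFileGenerator:
    def test_file_matches_in_memory(self, tmp_path, short_protocol):
        from orgephys import read_recording, simulate_ephys_to_file
        sess, _ = simulate_ephys(3, 20.0, short_protocol, seed=2)
        truth = simulate_ephys_to_file(tmp_path / "r.bin", tmp_path / "r.json",
                                       3, 20.0, short_protocol, seed=2)
        back = read_recording(tmp_path / "r.bin", tmp_path / "r.json")
        # same noise streams and spikes; file path quantizes at 0.195 uV
        np.testing.assert_allclose(back.samples, sess.samples, atol=0.0976)
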