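import numpy as np
import pytest
from scipy import stats

from orgephys import (AnalysisConfig, ChannelSummary, classify_channels,
                      paired_wilcoxon, population_event_trace,
                      simulate_spike_trains, summarize_organoid)
from orgephys.detect import SpikeTrain
from orgephys.io import StimulationProtocol
from orgephys.stim import organoid_rate_pair

from .oracles import oracle_wilcoxon_two_sided


def _train(cid, times):
    times = np.asarray(times, dtype=float)
    return SpikeTrain(cid, times, np.full(times.size, 50.0), 2.0)


def _uniform_times(n, t0, t1):
    return np.linspace(t0, t1, n, endpoint=False) + (t1 - t0) / (2 * n)


@pytest.fixture
def protocol():
    return StimulationProtocol.periodic()   # 600 s + 600 s


class TestClassifyChannels:
    def test_activity_boundary_inclusive(self, protocol, config):
        """50 spikes across the 600 s stimulation window is exactly
        5 spikes/min and counts as active; 49 does not."""
        t50 = _train(0, _uniform_times(50, 600, 1200))
        t49 = _train(1, _uniform_times(49, 600, 1200))
        s = classify_channels([t50, t49], protocol, config)
        assert s[0].active and not s[1].active

    def test_responder_boundary_inclusive(self, protocol, config):
        """Baseline 1.00 Hz -> stim 1.10 Hz is exactly a 10% change."""
        tr = _train(0, np.concatenate([_uniform_times(600, 0, 600),
                                       _uniform_times(660, 600, 1200)]))
        s = classify_channels([tr], protocol, config)[0]
        assert s.active and s.responder
        assert s.relative_change == pytest.approx(0.10)

    def test_sub_threshold_change_not_responder(self, protocol, config):
        tr = _train(0, np.concatenate([_uniform_times(600, 0, 600),
                                       _uniform_times(630, 600, 1200)]))
        s = classify_channels([tr], protocol, config)[0]
        assert s.active and not s.responder

    def test_decrease_counts_as_response(self, protocol, config):
        tr = _train(0, np.concatenate([_uniform_times(600, 0, 600),
                                       _uniform_times(300, 600, 1200)]))
        s = classify_channels([tr], protocol, config)[0]
        assert s.responder and s.relative_change == pytest.approx(-0.5)

    def test_silent_baseline_active_stim_is_responder(self, protocol, config):
        tr = _train(0, _uniform_times(100, 600, 1200))
        s = classify_channels([tr], protocol, config)[0]
        assert s.responder and np.isnan(s.relative_change)

    def test_zero_length_window_rejected(self, config):
        with pytest.raises(ValueError):
            StimulationProtocol([], 0.5, (0, 0), (0, 10))


class TestSummarizeOrganoid:
    @staticmethod
    def _summary(active, responding):
        out = []
        for i in range(active):
            out.append(ChannelSummary(i, 1.0, 2.0, True, i < responding, 1.0))
        out.append(ChannelSummary("inactive", 0.0, 0.0, False, False, np.nan))
        return out

    def test_printed_counts_give_746_percent(self):
        """235 responding of 315 active -> 74.6%."""
        res = summarize_organoid(self._summary(315, 235))
        assert res.percent_responding == pytest.approx(74.6, abs=0.05)
        assert res.n_active == 315 and res.n_responding == 235

    def test_single_active_channel_means(self):
        s = [ChannelSummary(0, 0.7, 1.3, True, True, 0.857)]
        res = summarize_organoid(s)
        assert res.mean_rate_baseline == pytest.approx(0.7)
        assert res.mean_rate_stim == pytest.approx(1.3)

    def test_no_active_channels_nan_sentinels(self):
        s = [ChannelSummary(0, 0.0, 0.0, False, False, np.nan)]
        res = summarize_organoid(s)
        assert res.n_active == 0
        assert np.isnan(res.mean_rate_baseline)
        assert np.isnan(res.percent_responding)

    def test_percentage_invariant_to_order_and_inactive_content(self):
        base = self._summary(10, 4)
        shuffled = list(reversed(base))
        assert (summarize_organoid(base).percent_responding
                == summarize_organoid(shuffled).percent_responding)

    def test_recovery_of_known_responder_fraction(self):
        """Half the channels modulated 3x: recovered responding percentage
        lands within 10 points of 50% across 20 seeds."""
        proto = StimulationProtocol.periodic()
        cfg = AnalysisConfig()
        pcts = []
        for seed in range(20):
            truth = simulate_spike_trains(16, 1200.0, proto, seed=seed,
                                          base_rate=2.0, rate_multiplier=3.0,
                                          responder_channels=set(range(8)))
            trains = [_train(c, truth.channel_spike_times(c))
                      for c in range(16)]
            res = summarize_organoid(classify_channels(trains, proto, cfg))
            pcts.append(res.percent_responding)
        assert abs(np.mean(pcts) - 50.0) < 10.0

    def test_power_at_twofold_modulation(self):
        """At 2x window modulation, at least 74% of truly modulated channels
        classify as responders."""
        proto = StimulationProtocol.periodic()
        cfg = AnalysisConfig()
        hits = total = 0
        for seed in range(5):
            truth = simulate_spike_trains(16, 1200.0, proto, seed=100 + seed,
                                          base_rate=2.0, rate_multiplier=2.0,
                                          responder_channels=set(range(8)))
            trains = [_train(c, truth.channel_spike_times(c))
                      for c in range(16)]
            summ = classify_channels(trains, proto, cfg)
            hits += sum(s.responder for s in summ[:8])
            total += 8
        assert hits / total >= 0.74


class TestPopulationTrace:
    def test_no_spikes_zero_trace(self, config):
        tr = population_event_trace([_train(0, [])], config, 0.0, 1.0)
        assert np.all(tr.values == 0)
        assert tr.times[1] - tr.times[0] == pytest.approx(config.bin_width)

    def test_single_spike_mass_one(self, config):
        tr = population_event_trace([_train(0, [0.5])], config, 0.0, 1.0)
        assert tr.values.sum() == pytest.approx(1.0)

    def test_matches_dense_convolution_oracle(self, config):
        rng = np.random.default_rng(3)
        trains = [_train(c, np.sort(rng.uniform(0, 2.0, size=40)))
                  for c in range(5)]
        got = population_event_trace(trains, config, 0.0, 2.0)
        # oracle: dense binarized raster, then full convolution trimmed
        n = got.values.size
        raster = np.zeros((5, n))
        for c, tr in enumerate(trains):
            idx = np.floor(tr.times / config.bin_width).astype(int)
            raster[c, idx[idx < n]] = 1.0
        kernel = np.ones(101) / 101.0
        dense = np.convolve(raster.sum(axis=0), kernel, mode="same")
        np.testing.assert_allclose(got.values, dense, atol=1e-12)

    def test_mass_conservation_counts_occupied_bins(self, config):
        """Total smoothed mass equals the number of occupied (channel, bin)
        pairs for spikes away from the trace edges."""
        trains = [_train(0, [0.3002, 0.3007, 0.5005]), _train(1, [0.3002])]
        tr = population_event_trace(trains, config, 0.0, 1.0)
        # the two 0.300x spikes share one bin on channel 0 -> 3 occupied pairs
        assert tr.values.sum() == pytest.approx(3.0)


class TestPairedWilcoxon:
    def test_all_positive_n7(self):
        stat, p = paired_wilcoxon(np.zeros(7), np.arange(1.0, 8.0))
        assert (stat, p) == (0.0, pytest.approx(2 / 128))

    def test_wminus_three_n8(self):
        d = np.array([1, 2, 4, 5, 6, 7, 8, -3.0])
        stat, p = paired_wilcoxon(np.zeros(8), d)
        assert stat == 3.0
        assert p == pytest.approx(10 / 256)

    def test_antisymmetric_p_one(self):
        d = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        _, p = paired_wilcoxon(np.zeros(6), d)
        assert p == pytest.approx(oracle_wilcoxon_two_sided(d))
        assert p == 1.0

    def test_all_zero_differences_warns_p_one(self):
        with pytest.warns(UserWarning):
            stat, p = paired_wilcoxon(np.ones(5), np.ones(5))
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(-4, 5, size=rng.integers(3, 11)).astype(float)
        d = d[d != 0]
        if d.size == 0:
            return
        _, p = paired_wilcoxon(np.zeros(d.size), d)
        assert p == pytest.approx(oracle_wilcoxon_two_sided(d))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_exact_without_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = rng.normal(0.3, 1.0, size=12)
        _, p = paired_wilcoxon(np.zeros(12), d)
        ref = stats.wilcoxon(d, mode="exact")
        assert p == pytest.approx(ref.pvalue)

    def test_large_n_normal_approximation(self):
        rng = np.random.default_rng(42)
        d = rng.normal(0.2, 1.0, size=40)
        _, p = paired_wilcoxon(np.zeros(40), d)
        ref = stats.wilcoxon(d, mode="approx", correction=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_wilcoxon([1.0, 2.0], [1.0])


class TestOrganoidRatePair:
    def test_per_channel_normalization_baseline_one(self):
        s = [ChannelSummary(0, 1.0, 2.0, True, True, 1.0),
             ChannelSummary(1, 2.0, 2.0, True, False, 0.0)]
        b, st_ = organoid_rate_pair(s, "per-channel")
        assert b == 1.0
        assert st_ == pytest.approx((2.0 + 1.0) / 2)

    def test_plain_means(self):
        s = [ChannelSummary(0, 1.0, 2.0, True, True, 1.0),
             ChannelSummary(1, 3.0, 4.0, True, False, 0.33)]
        b, st_ = organoid_rate_pair(s, "none")
        assert (b, st_) == (2.0, 3.0)
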