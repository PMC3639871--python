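"""Two-sided impulse-response estimation and feedback classification."""

import numpy as np
import pytest

from clgfnet.cohort import CohortSpec, GroundTruthTopology, synthesize_signals
from clgfnet.feedback import (consistent_network, estimate_ir,
                              infer_pair, surrogate_null)
from clgfnet.network import FeedbackEdge
from clgfnet.signals import SignalSet


def coupled_pair_signals(seed, duration=4.0, coupling=2.0, lag=21.0,
                         noise=0.5):
    """Four channels, one reciprocal positive feedback between ch000 and
    ch002 (distinct regions, physiological lag), the rest uncoupled."""
    names = [f"ch{i:03d}" for i in range(4)]
    rmap = {n: ("temporal-L" if i < 2 else "parietal-R")
            for i, n in enumerate(names)}
    topo = GroundTruthTopology(names, rmap, [
        FeedbackEdge("ch000", "ch002", +1, causal_lag_ms=lag,
                     noncausal_lag_ms=-1.0, scope="global")])
    spec = CohortSpec(n_subjects_per_group=(2, 2), n_channels=4,
                      duration=duration, coupling_strength=coupling,
                      noise_sd=noise, input_noise_sd=0.3)
    return synthesize_signals(topo, spec, np.random.default_rng(seed))


class TestEstimateIR:
    def test_pure_delay_peaks_at_positive_lag(self, rng):
        x = rng.standard_normal(4000)
        d = 9
        y = np.roll(x, d) + 0.1 * rng.standard_normal(4000)
        ir = estimate_ir(x, y, 25, fs=1000.0)
        lag, h = ir.peak("causal")
        assert lag == pytest.approx(d, abs=0.5)
        assert h > 0
        assert abs(h) > 3 * abs(ir.peak("noncausal")[1])

    def test_zero_lag_copy_peaks_at_zero_symmetrically(self, rng):
        x = rng.standard_normal(4000)
        ir = estimate_ir(x, x + 0.05 * rng.standard_normal(4000), 20, 1000.0)
        assert np.argmax(np.abs(ir.h)) == ir.max_lag  # tau = 0
        left, right = ir.side("noncausal")[1], ir.side("causal")[1]
        assert np.abs(left[::-1] - right).max() < 0.05

    def test_independent_noise_stays_below_null(self, rng):
        hits = 0
        for i in range(20):
            x = rng.standard_normal(3000)
            y = rng.standard_normal(3000)
            if infer_pair(x, y, 25, 1000.0, rng) is not None:
                hits += 1
        # joint two-sided exceedance at the 95% level is ~0.0025 per pair
        assert hits <= 1

    def test_too_short_series_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_ir(rng.standard_normal(300), rng.standard_normal(300),
                        40, 1000.0)

    def test_deterministic_given_inputs(self, rng):
        x = rng.standard_normal(2000)
        y = np.roll(x, 5)
        h1 = estimate_ir(x, y, 15, 1000.0).h
        h2 = estimate_ir(x, y, 15, 1000.0).h
        assert np.array_equal(h1, h2)


class TestClassifyFeedback:
    def test_reciprocal_wilson_cowan_coupling_is_positive_feedback(self):
        sig = coupled_pair_signals(seed=7)
        edge = infer_pair(sig.data[0], sig.data[2], 35, 1000.0,
                          np.random.default_rng(1), "ch000", "ch002")
        assert edge is not None
        assert edge.sign == +1
        # dominant lags reflect the 21 ms conduction delay plus the driven
        # oscillator's rise time
        assert 10.0 <= edge.causal_lag_ms <= 40.0
        assert -40.0 <= edge.noncausal_lag_ms <= -10.0

    def test_unidirectional_drive_is_not_feedback(self, rng):
        x = rng.standard_normal(4000)
        y = 0.8 * np.roll(x, 15) + rng.standard_normal(4000)
        edge = infer_pair(x, y, 30, 1000.0, rng)
        assert edge is None

    def test_uncoupled_oscillators_are_not_feedback(self):
        sig = coupled_pair_signals(seed=8)
        edge = infer_pair(sig.data[1], sig.data[3], 35, 1000.0,
                          np.random.default_rng(2), "ch001", "ch003")
        assert edge is None

    def test_argument_order_invariance(self):
        sig = coupled_pair_signals(seed=9)
        rng_a = np.random.default_rng(3)
        rng_b = np.random.default_rng(3)
        e1 = infer_pair(sig.data[0], sig.data[2], 35, 1000.0, rng_a,
                        "ch000", "ch002")
        e2 = infer_pair(sig.data[2], sig.data[0], 35, 1000.0, rng_b,
                        "ch002", "ch000")
        assert e1 is not None and e2 is not None
        assert e1.key == e2.key

    def test_surrogate_count_floor(self, rng):
        x = rng.standard_normal(2000)
        with pytest.raises(ValueError):
            surrogate_null(x, x, 10, n_surrogates=10, rng=rng)


class TestConsistentNetwork:
    def test_stationary_coupling_survives_all_windows(self):
        sig = coupled_pair_signals(seed=11, duration=8.0)
        net = consistent_network(sig, n_windows=4, max_lag_ms=35,
                                 rng=np.random.default_rng(5))
        keys = {e.key for e in net.edges}
        assert ("ch000", "ch002", 1) in keys

    def test_edge_present_in_three_windows_is_excluded(self):
        # coupling only during the first three quarters of the record
        coupled = coupled_pair_signals(seed=12, duration=8.0)
        uncoupled = coupled_pair_signals(seed=13, duration=8.0, coupling=0.0)
        data = coupled.data.copy()
        data[:, 6000:] = uncoupled.data[:, 6000:]
        sig = SignalSet(data, 1000.0, coupled.channel_names)
        net = consistent_network(sig, n_windows=4, max_lag_ms=35,
                                 rng=np.random.default_rng(6))
        assert ("ch000", "ch002", 1) not in {e.key for e in net.edges}

    def test_all_noise_record_yields_empty_network(self, rng):
        sig = SignalSet(rng.standard_normal((4, 8000)), 1000.0)
        net = consistent_network(sig, n_windows=4, max_lag_ms=25,
                                 rng=np.random.default_rng(7))
        assert len(net.edges) == 0

    def test_record_too_short_rejected(self, rng):
        sig = SignalSet(rng.standard_normal((2, 3000)), 1000.0)
        with pytest.raises(ValueError):
            consistent_network(sig, n_windows=4, window_len=2.0)
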