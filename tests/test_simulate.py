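"""Event-driven simulator: exactness, estimators, replica routing.

The single-neuron Poisson-driven configuration doubles as the master
oracle for the whole package: there the RMF description is exact, so the
simulator and the analytical engine must agree to Monte-Carlo error.
"""

import math

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid
from scipy.stats import kstest

from rmfnet.network import NetworkSpec, NeuronParams, make_bistable_network
from rmfnet.rmf import rate_transfer
from rmfnet.simulate import (
    empirical_correlations,
    empirical_moments,
    estimate_rates,
    simulate,
    simulate_replica,
    StateTrace,
)

DRIVE_1KHZ = [(0, 1000.0, 1.0)]   # 1 kHz excitatory input, weight 1


class TestSingleNeuron:
    def test_isolated_neuron_fires_at_base_rate_with_frozen_x(self, single_neuron_net):
        rec, trace = simulate(single_neuron_net, n_events=2000, seed=1,
                              trace_dt=0.01)
        rate = rec.n_events / rec.total_time
        assert rate == pytest.approx(1.0, abs=3 * 1.0 / math.sqrt(2000))
        assert np.all(trace.x == 0.0)

    def test_same_seed_reproduces_run_exactly(self, single_neuron_net):
        a = simulate(single_neuron_net, n_events=200, seed=42, external=DRIVE_1KHZ)[0]
        b = simulate(single_neuron_net, n_events=200, seed=42, external=DRIVE_1KHZ)[0]
        assert np.array_equal(a.times, b.times)
        assert a.total_time == b.total_time

    def test_spike_times_strictly_increasing(self, single_neuron_net):
        rec, _ = simulate(single_neuron_net, n_events=500, seed=5,
                          external=DRIVE_1KHZ)
        assert np.all(np.diff(rec.times) > 0)

    def test_interspike_distribution_matches_exact_hazard(self, single_neuron_net):
        """Thinning correctness: first-passage times from x0 follow the
        analytic hazard h exp(a x0 e^(-t/tau))."""
        h, a, tau, x0 = 1.0, 0.1, 0.01, 20.0
        net = NetworkSpec(params=[NeuronParams(h=h, a=a, tau=tau)],
                          weights=np.zeros((1, 1)))
        draws = np.array([
            simulate(net, n_events=1, seed=2_000 + k, x0=np.array([x0]))[0].times[0]
            for k in range(10_000)])
        t = np.linspace(0, 60.0, 200_001)
        lam = h * np.exp(a * x0 * np.exp(-t / tau))
        F = 1.0 - np.exp(-cumulative_trapezoid(lam, t, initial=0.0))
        cdf = lambda s: np.interp(s, t, F)
        assert kstest(draws, cdf).pvalue > 0.01

    def test_rate_conservation_h_L_a_equals_beta(self, single_neuron_net):
        """h E[e^{a x}] = beta: the defining self-consistency, empirically."""
        rec, trace = simulate(single_neuron_net, n_events=8000, seed=3,
                              external=DRIVE_1KHZ, trace_dt=1e-3)
        rate = rec.n_events / rec.total_time
        hL = np.mean(1.0 * np.exp(0.1 * trace.x))
        assert hL == pytest.approx(rate, rel=0.05)

    def test_simulation_matches_rmf_for_poisson_driven_neuron(
            self, single_neuron_net, neuron, exc_drive):
        """Master oracle: the RMF calculation is exact here."""
        est = estimate_rates(single_neuron_net, 2000, 8, seed=11,
                             external=DRIVE_1KHZ)
        r = rate_transfer(exc_drive, neuron)
        sem = est.std[0] / math.sqrt(est.n_repeats)
        assert abs(est.mean[0] - r.beta) < 3 * sem

    def test_inhibited_neuron_trace_is_bounded_and_stationary(self, neuron):
        net = NetworkSpec(params=[neuron], weights=np.zeros((1, 1)))
        rec, trace = simulate(net, duration=200.0, seed=7,
                              external=[(0, 1000.0, -1.0)], trace_dt=1e-2)
        x = trace.x[0]
        burn = len(x) // 5
        assert np.max(np.abs(x)) < 1e3
        first, second = x[burn:(len(x) + burn) // 2], x[(len(x) + burn) // 2:]
        pooled = x[burn:].std()
        assert abs(first.mean() - second.mean()) < 0.2 * pooled + 0.05


class TestEstimateRates:
    def test_deterministic_under_seed(self, single_neuron_net):
        a = estimate_rates(single_neuron_net, 100, 4, seed=9, external=DRIVE_1KHZ)
        b = estimate_rates(single_neuron_net, 100, 4, seed=9, external=DRIVE_1KHZ)
        assert np.array_equal(a.mean, b.mean) and np.array_equal(a.std, b.std)

    def test_isolated_neuron_mean_within_three_std(self, single_neuron_net):
        est = estimate_rates(single_neuron_net, 400, 32, seed=13)
        assert abs(est.mean[0] - 1.0) < 3 * est.std[0]

    def test_rejects_empty_protocol(self, single_neuron_net):
        with pytest.raises(ValueError):
            estimate_rates(single_neuron_net, 0, 4, seed=0)

    def test_input_count_per_repeat_matches_long_run_rate(self, single_neuron_net):
        """Mean external events per 400-spike repeat equals the input rate
        times the expected repeat duration from an independent long run."""
        est = estimate_rates(single_neuron_net, 400, 16, seed=19,
                             external=DRIVE_1KHZ)
        rec, _ = simulate(single_neuron_net, n_events=20_000, seed=20,
                          external=DRIVE_1KHZ)
        long_rate = rec.n_events / rec.total_time
        expected = 1000.0 * 400 / long_rate
        assert est.mean_external_events == pytest.approx(expected, rel=0.05)


class TestReplica:
    def test_single_replica_matches_direct_simulation_law(self):
        # mutually exciting pair; R=1 routing must reproduce the original law
        W = np.array([[0.0, 2.0], [2.0, 0.0]])
        net = NetworkSpec(params=[NeuronParams(h=5.0)] * 2, weights=W)
        rec1 = simulate_replica(net, 1, n_events=4000, seed=21)
        rec0, _ = simulate(net, n_events=4000, seed=22)
        r1 = rec1.n_events / rec1.total_time
        r0 = rec0.n_events / rec0.total_time
        assert r1 == pytest.approx(r0, rel=0.1)

    def test_transitions_rarer_with_more_replicas(self):
        """Metastable switching slows down as replicas decorrelate the
        network (transition rates vanish with the number of replicas)."""
        net = make_bistable_network(10, 1.4, -4.0, 1500.0)
        counts = {}
        for R in (1, 2, 4):
            rec = simulate_replica(net, R, duration=8.0, seed=31, mu_bg=0.5)
            counts[R] = self._hysteresis_switches(rec, n=10, T=8.0)
        assert counts[1] > counts[2] >= counts[4]

    @staticmethod
    def _hysteresis_switches(rec, n, T, w=0.1):
        """Count dominance switches between the two excitatory groups from
        binned spike counts with a hysteretic threshold."""
        e1 = rec.neurons < n
        e2 = (rec.neurons >= 2 * n) & (rec.neurons < 3 * n)
        bins = np.arange(0.0, T, w)
        c1, _ = np.histogram(rec.times[e1], bins)
        c2, _ = np.histogram(rec.times[e2], bins)
        z = c1.astype(float) - c2
        th = 0.3 * np.abs(z).max()
        state, count = 0, 0
        for v in z:
            if v > th and state <= 0:
                count += state < 0
                state = 1
            elif v < -th and state >= 0:
                count += state > 0
                state = -1
        return count

    def test_pooled_deliveries_to_one_unit_are_poissonian(self):
        """Fano factor of the cross-replica input stream ~ 1 (dispersion test)."""
        W = np.array([[0.0, 2.0], [2.0, 0.0]])
        net = NetworkSpec(params=[NeuronParams(h=20.0)] * 2, weights=W)
        rec = simulate_replica(net, 64, duration=40.0, seed=41,
                               track_unit=(0, 0))
        t = rec.deliveries
        assert t is not None and len(t) > 200
        bins = np.arange(0.0, 40.0, 0.25)
        counts, _ = np.histogram(t, bins)
        fano = counts.var(ddof=1) / counts.mean()
        n = len(counts)
        assert abs(fano - 1.0) < 3 * math.sqrt(2.0 / (n - 1))


class TestTraceStatistics:
    def test_constant_zero_trace(self):
        tr = StateTrace(t0=0.0, dt=0.01, x=np.zeros((2, 100)), seed=0)
        m = empirical_moments(tr)
        assert np.all(m[1:] == 0.0) and np.all(m[0] == 1.0)
        with pytest.raises(ValueError):
            empirical_correlations(tr)

    def test_identical_rows_fully_correlated(self):
        rng = np.random.default_rng(0)
        row = rng.standard_normal(500)
        tr = StateTrace(t0=0.0, dt=0.01, x=np.stack([row, row]), seed=0)
        corr = empirical_correlations(tr)
        assert corr[0, 1] == pytest.approx(1.0)

    def test_too_short_trace_rejected(self):
        tr = StateTrace(t0=0.0, dt=0.01, x=np.zeros((2, 1)), seed=0)
        with pytest.raises(ValueError):
            empirical_moments(tr)
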