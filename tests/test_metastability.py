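"""Bifurcation observable, HMM segmentation, Kramers prediction, and the
correlation structure of the bistable circuit."""

import math

import numpy as np
import pytest

from rmfnet.metastability import (
    bifurcation_observable,
    cluster_observable,
    detect_states,
    predict_transition_time,
)
from rmfnet.network import bistable_clusters, make_bistable_network
from rmfnet.simulate import empirical_correlations, simulate
from rmfnet.solver import RateSolution


def _sol(beta):
    return RateSolution(beta=np.asarray(beta, float), residual=0.0,
                        converged=True, n_iter=1)


class TestBifurcationObservable:
    def test_formula_value(self):
        # (10+8-2-1)/(10+8+2+1)
        assert bifurcation_observable(_sol([10.0, 8.0, 2.0, 1.0])) == \
            pytest.approx(15.0 / 21.0)

    def test_identical_states_give_zero(self):
        assert bifurcation_observable(_sol([5.0, 3.0, 5.0, 3.0])) == 0.0

    def test_silenced_down_state_approaches_one(self):
        d = bifurcation_observable(_sol([50.0, 40.0, 1e-6, 1e-6]))
        assert d == pytest.approx(1.0, abs=1e-6)

    def test_bounded_between_zero_and_one(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            b = rng.uniform(0.0, 100.0, 4)
            assert 0.0 <= bifurcation_observable(_sol(b)) <= 1.0

    def test_mirror_invariance(self):
        b = [10.0, 8.0, 2.0, 1.0]
        assert bifurcation_observable(_sol(b)) == \
            bifurcation_observable(_sol(b[2:] + b[:2]))


class TestDetectStates:
    @staticmethod
    def _telegraph(rate, means, sd, n, dt, seed):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, dtype=int)
        state = 0
        p = rate * dt
        for i in range(1, n):
            if rng.random() < p:
                state = 1 - state
            labels[i] = state
        y = np.where(labels == 1, means[1], means[0]) \
            + sd * rng.standard_normal(n)
        return labels, y

    def test_recovers_telegraph_labels_and_dwell_times(self):
        rate, dt, n = 2.0, 1e-3, 60_000
        labels, y = self._telegraph(rate, (-2.0, 2.0), 0.5, n, dt, seed=8)
        st = detect_states(y, dt=dt, seed=0, tau=0.01)
        assert st.bistable
        agree = max(np.mean(st.labels == labels), np.mean(st.labels != labels))
        assert agree >= 0.95
        true_dwell = 1.0 / rate
        est_dwell = np.mean(np.concatenate([st.durations_up,
                                            st.durations_down]))
        assert est_dwell == pytest.approx(true_dwell, rel=0.25)

    def test_single_state_series_reported_monostable(self):
        rng = np.random.default_rng(1)
        y = 0.3 * rng.standard_normal(20_000)
        st = detect_states(y, dt=1e-3, seed=0, tau=0.01)
        assert not st.bistable

    def test_transition_count_consistent_with_labels(self):
        _, y = self._telegraph(2.0, (-2.0, 2.0), 0.4, 40_000, 1e-3, seed=9)
        st = detect_states(y, dt=1e-3, seed=0, tau=0.01)
        assert st.n_transitions == np.count_nonzero(np.diff(st.labels))
        assert st.mean_transition_time == pytest.approx(
            st.total_time / st.n_transitions)


class TestKramers:
    def test_symmetric_wells_give_equal_times(self):
        p = predict_transition_time((2.0, 0.5), (-2.0, 0.5), tau=0.01)
        assert p.time_up_to_down == pytest.approx(p.time_down_to_up, rel=1e-6)

    def test_time_grows_with_well_separation(self):
        times = [predict_transition_time((m, 0.5), (-2.0, 0.5), tau=0.01).time
                 for m in (1.5, 2.5, 3.5)]
        assert times[0] < times[1] < times[2]

    def test_merged_wells_rejected(self):
        with pytest.raises(ValueError, match="merged|barrier"):
            predict_transition_time((0.2, 0.5), (-0.2, 0.5), tau=0.01)

    def test_scales_linearly_with_relaxation_time(self):
        t1 = predict_transition_time((2.0, 0.5), (-2.0, 0.5), tau=0.01).time
        t2 = predict_transition_time((2.0, 0.5), (-2.0, 0.5), tau=0.02).time
        assert t2 == pytest.approx(2 * t1, rel=1e-9)


class TestPhaseDiagram:
    def test_monostable_and_bistable_cells(self):
        """No excitation cannot engage the cross-inhibition loop (Delta=0);
        at mu_e=1.7 the cell is deep in the bistable phase."""
        from rmfnet.metastability import phase_diagram

        grid = phase_diagram(10, [0.0, 1.7], [4.0], tmf_drive=1500.0, seed=0)
        assert grid.delta.shape == (1, 2)
        assert grid.n_solutions[0, 0] == 1
        assert grid.delta[0, 0] == pytest.approx(0.0, abs=0.01)
        assert grid.n_solutions[0, 1] == 2
        assert grid.delta[0, 1] > 0.9
        assert np.all(grid.mu_i <= 0)


class TestCorrelationStructure:
    def test_within_group_positive_cross_group_negative(self):
        """Stochastic switching correlates neurons within a group and
        anti-correlates the two groups."""
        net = make_bistable_network(10, 1.5, -4.0, 1500.0)
        _, trace = simulate(net, duration=8.0, seed=17, trace_dt=1e-3)
        corr = empirical_correlations(trace)
        e1, i1, e2, i2 = bistable_clusters(10)
        within = corr[np.ix_(e1, e1)][~np.eye(10, dtype=bool)]
        cross = corr[np.ix_(e1, e2)].ravel()
        assert within.mean() > 0.1
        assert cross.mean() < -0.1

    def test_up_state_decorrelates_down_state_correlates(self):
        """Conditioned on the dominance state, up-state neurons are nearly
        independent while down-state neurons share their inhibitory drive."""
        net = make_bistable_network(10, 1.5, -4.0, 1500.0)
        _, trace = simulate(net, duration=12.0, seed=23, trace_dt=1e-3)
        e1 = bistable_clusters(10)[0]
        obs = cluster_observable(trace, e1)
        st = detect_states(obs, dt=1e-3, seed=0, tau=0.01)
        assert st.bistable
        off = ~np.eye(10, dtype=bool)
        up = empirical_correlations(trace, mask=st.labels == 1)
        down = empirical_correlations(trace, mask=st.labels == 0)
        up_mean = up[np.ix_(e1, e1)][off].mean()
        down_mean = down[np.ix_(e1, e1)][off].mean()
        assert down_mean > up_mean
        assert down_mean > 0.2
        assert abs(up_mean) < 0.25
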