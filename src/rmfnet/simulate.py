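"""Exact event-driven Monte-Carlo simulation of finite LER networks.

Spikes are sampled by Ogata thinning with the piecewise-constant bound
Lambda_bar = sum_i h_i exp(a_i max(x_i, 0)) + (total external rate), which
dominates the true total intensity until the next accepted event because
|x_i| decays monotonically between events.  On a spike of neuron j the
spiking neuron resets first (x_j = 0), then every other neuron k receives
the jump mu_kj; the recorded post-spike value of x_j is 0.

The per-neuron mean background drive c_i is realized as a discrete Poisson
stream of weak excitatory jumps (size ``mu_bg``, default 0.1) at rate
c_i / mu_bg, emulating a dense cloud of weak synapses.

The inner loops are numba-compiled; all randomness flows through numba's
RNG seeded once per chunk from the caller's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .network import NetworkSpec

__all__ = [
    "SpikeRecord",
    "StateTrace",
    "RateEstimate",
    "simulate",
    "simulate_replica",
    "estimate_rates",
    "empirical_moments",
    "empirical_correlations",
]

DEFAULT_MU_BG = 0.1


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class SpikeRecord:
    """Ordered spike events of one simulation run."""

    times: np.ndarray            # strictly increasing, seconds
    neurons: np.ndarray          # neuron index per event
    replicas: np.ndarray | None  # replica index per event (None: single copy)
    total_time: float            # seconds of simulated time
    seed: int
    n_external: int = 0          # number of external/background deliveries
    deliveries: np.ndarray | None = None  # times of deliveries to a tracked unit

    @property
    def n_events(self) -> int:
        return len(self.times)

    def counts(self, K: int) -> np.ndarray:
        return np.bincount(self.neurons, minlength=K)


@dataclass
class StateTrace:
    """Internal variables sampled on a uniform grid."""

    t0: float
    dt: float
    x: np.ndarray                # (K, T)
    seed: int

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.x.shape[1])


@dataclass
class RateEstimate:
    """Rate estimate over independent repeats (per-repeat count protocol)."""

    mean: np.ndarray             # Hz per neuron
    std: np.ndarray              # Hz per neuron, over repeats
    n_repeats: int
    n_events_per_repeat: int
    mean_external_events: float = 0.0


# ---------------------------------------------------------------------------
# numba cores
# ---------------------------------------------------------------------------

@njit(cache=True)
def _core_single(h, a, tau, W, ext_t, ext_r, ext_j, x, t0, t_stop, n_spk_target,
                 spk_t, spk_i, trace_dt, trace_buf, next_sample, seed):
    """One chunk of thinning simulation; returns (n_sp, n_tr, t, n_ext, status).

    status: 0 done (target reached), 1 spike buffer full, 2 trace buffer full.
    """
    np.random.seed(seed)
    K = x.shape[0]
    n_ext_ch = ext_t.shape[0]
    ext_total = 0.0
    for e in range(n_ext_ch):
        ext_total += ext_r[e]
    t = t0
    n_sp = 0
    n_tr = 0
    n_ext = 0
    cap_sp = spk_t.shape[0]
    cap_tr = trace_buf.shape[1] if trace_dt > 0.0 else 0
    while True:
        bound = ext_total
        for i in range(K):
            xi = x[i]
            if xi > 0.0:
                bound += h[i] * math.exp(a[i] * xi)
            else:
                bound += h[i]
        dt = np.random.exponential(1.0 / bound)
        t_new = t + dt
        if t_new > t_stop:
            # advance sampling to t_stop and finish
            if trace_dt > 0.0:
                while next_sample <= t_stop and n_tr < cap_tr:
                    for i in range(K):
                        trace_buf[i, n_tr] = x[i] * math.exp(-(next_sample - t) / tau[i])
                    n_tr += 1
                    next_sample += trace_dt
            for i in range(K):
                x[i] = x[i] * math.exp(-(t_stop - t) / tau[i])
            return n_sp, n_tr, t_stop, n_ext, 0, next_sample
        # sample the trace on the way
        if trace_dt > 0.0:
            while next_sample <= t_new:
                if n_tr >= cap_tr:
                    for i in range(K):
                        x[i] = x[i] * math.exp(-(t_new - t) / tau[i])
                    return n_sp, n_tr, t_new, n_ext, 2, next_sample
                for i in range(K):
                    trace_buf[i, n_tr] = x[i] * math.exp(-(next_sample - t) / tau[i])
                n_tr += 1
                next_sample += trace_dt
        for i in range(K):
            x[i] = x[i] * math.exp(-dt / tau[i])
        t = t_new
        u = np.random.random() * bound
        if u < ext_total:
            # external/background delivery
            acc = 0.0
            e_sel = n_ext_ch - 1
            for e in range(n_ext_ch):
                acc += ext_r[e]
                if u < acc:
                    e_sel = e
                    break
            x[ext_t[e_sel]] += ext_j[e_sel]
            n_ext += 1
        else:
            v = u - ext_total
            acc = 0.0
            spiked = -1
            for i in range(K):
                lam = h[i] * math.exp(a[i] * x[i])
                acc += lam
                if v < acc:
                    spiked = i
                    break
            if spiked >= 0:
                x[spiked] = 0.0
                for k in range(K):
                    if k != spiked:
                        x[k] += W[k, spiked]
                spk_t[n_sp] = t
                spk_i[n_sp] = spiked
                n_sp += 1
                if n_sp >= n_spk_target:
                    return n_sp, n_tr, t, n_ext, 0, next_sample
                if n_sp >= cap_sp:
                    return n_sp, n_tr, t, n_ext, 1, next_sample
            # else: thinning rejection, continue


@njit(cache=True)
def _core_replica(h, a, tau, W, ext_t, ext_r, ext_j, x, t0, t_stop, n_spk_target,
                  spk_t, spk_i, spk_r, track_i, track_r, deliv_t, seed):
    """Replica-model chunk: x has shape (R, K); routing is uniform per target type.

    External channels are duplicated across replicas.  Deliveries to unit
    (track_i, track_r) are recorded in deliv_t if track_i >= 0.
    """
    np.random.seed(seed)
    R, K = x.shape
    n_ext_ch = ext_t.shape[0]
    ext_total = 0.0
    for e in range(n_ext_ch):
        ext_total += ext_r[e]
    ext_total *= R
    t = t0
    n_sp = 0
    n_del = 0
    cap_sp = spk_t.shape[0]
    cap_del = deliv_t.shape[0]
    while True:
        bound = ext_total
        for r in range(R):
            for i in range(K):
                xi = x[r, i]
                if xi > 0.0:
                    bound += h[i] * math.exp(a[i] * xi)
                else:
                    bound += h[i]
        dt = np.random.exponential(1.0 / bound)
        t_new = t + dt
        if t_new > t_stop:
            for r in range(R):
                for i in range(K):
                    x[r, i] *= math.exp(-(t_stop - t) / tau[i])
            return n_sp, n_del, t_stop, 0
        for r in range(R):
            for i in range(K):
                x[r, i] *= math.exp(-dt / tau[i])
        t = t_new
        u = np.random.random() * bound
        if u < ext_total:
            e_all = int(u / (ext_total / (R * n_ext_ch))) if n_ext_ch else 0
            # uniform choice over (replica, channel); rates equal per replica
            acc = 0.0
            sel_e = n_ext_ch - 1
            sel_r = R - 1
            done = False
            for r in range(R):
                for e in range(n_ext_ch):
                    acc += ext_r[e]
                    if u < acc:
                        sel_e = e
                        sel_r = r
                        done = True
                        break
                if done:
                    break
            x[sel_r, ext_t[sel_e]] += ext_j[sel_e]
        else:
            v = u - ext_total
            acc = 0.0
            sp_i = -1
            sp_r = -1
            done = False
            for r in range(R):
                for i in range(K):
                    acc += h[i] * math.exp(a[i] * x[r, i])
                    if v < acc:
                        sp_i = i
                        sp_r = r
                        done = True
                        break
                if done:
                    break
            if sp_i >= 0:
                x[sp_r, sp_i] = 0.0
                for k in range(K):
                    if k != sp_i and W[k, sp_i] != 0.0:
                        q = np.random.randint(0, R)
                        x[q, k] += W[k, sp_i]
                        if k == track_i and q == track_r and n_del < cap_del:
                            deliv_t[n_del] = t
                            n_del += 1
                spk_t[n_sp] = t
                spk_i[n_sp] = sp_i
                spk_r[n_sp] = sp_r
                n_sp += 1
                if n_sp >= n_spk_target or n_sp >= cap_sp:
                    return n_sp, n_del, t, 0 if n_sp >= n_spk_target else 1


# ---------------------------------------------------------------------------
# wrappers
# ---------------------------------------------------------------------------

def _ext_channels(network: NetworkSpec, external, mu_bg: float):
    """Flatten background drive + user channels into target/rate/jump arrays."""
    tgt, rate, jump = [], [], []
    for i, c in enumerate(network.background):
        if c > 0:
            tgt.append(i)
            rate.append(c / mu_bg)
            jump.append(mu_bg)
    for (i, b, m) in external:
        if b > 0:
            tgt.append(int(i))
            rate.append(float(b))
            jump.append(float(m))
    return (np.array(tgt, dtype=np.int64), np.array(rate, dtype=float),
            np.array(jump, dtype=float))


def _chunk_seeds(seed: int, start: int = 0):
    """Deterministic stream of sub-seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    k = start
    while True:
        yield int(np.random.SeedSequence((seed, k)).generate_state(1)[0] % (2**31 - 1))
        k += 1


def simulate(
    network: NetworkSpec,
    *,
    n_events: int | None = None,
    duration: float | None = None,
    seed: int = 0,
    trace_dt: float | None = None,
    x0: np.ndarray | None = None,
    external=(),
    mu_bg: float = DEFAULT_MU_BG,
) -> tuple[SpikeRecord, StateTrace | None]:
    """Exact simulation of a finite LER network.

    Stops after ``n_events`` network-wide spikes, after ``duration``
    seconds, or whichever comes first if both are given.  ``external`` is
    an iterable of (neuron, rate_hz, jump) Poisson input channels on top
    of the network's own weights and background drive.  ``trace_dt``
    enables sampling of all internal variables on a uniform grid.
    """
    if n_events is None and duration is None:
        raise ValueError("need a stopping rule: n_events and/or duration")
    if n_events is not None and n_events < 1:
        raise ValueError("n_events must be >= 1")
    if duration is not None and duration <= 0:
        raise ValueError("duration must be > 0")
    K = network.K
    h, a, tau = network.h(), network.a(), network.tau()
    W = np.ascontiguousarray(network.weights)
    ext_t, ext_r, ext_j = _ext_channels(network, external, mu_bg)
    x = np.zeros(K) if x0 is None else np.array(x0, dtype=float)
    t_stop = duration if duration is not None else np.inf
    target = n_events if n_events is not None else np.iinfo(np.int64).max
    tdt = trace_dt if trace_dt is not None else 0.0

    seeds = _chunk_seeds(seed)
    all_t, all_i, traces = [], [], []
    t = 0.0
    next_sample = 0.0
    n_total = 0
    n_ext_total = 0
    chunk_sp = int(min(target, 500_000))
    chunk_tr = int(min(t_stop / tdt + 2, 2_000_000)) if tdt > 0 else 1
    while True:
        spk_t = np.empty(chunk_sp)
        spk_i = np.empty(chunk_sp, dtype=np.int64)
        trace_buf = np.empty((K, chunk_tr if tdt > 0 else 0))
        n_sp, n_tr, t, n_ext, status, next_sample = _core_single(
            h, a, tau, W, ext_t, ext_r, ext_j, x, t, t_stop,
            target - n_total, spk_t, spk_i, tdt, trace_buf, next_sample,
            next(seeds))
        all_t.append(spk_t[:n_sp].copy())
        all_i.append(spk_i[:n_sp].copy())
        if tdt > 0 and n_tr:
            traces.append(trace_buf[:, :n_tr].copy())
        n_total += n_sp
        n_ext_total += n_ext
        if status == 0:
            break
    times = np.concatenate(all_t) if all_t else np.empty(0)
    ids = np.concatenate(all_i) if all_i else np.empty(0, dtype=np.int64)
    rec = SpikeRecord(times=times, neurons=ids, replicas=None, total_time=t,
                      seed=seed, n_external=n_ext_total)
    trace = None
    if tdt > 0:
        xs = np.concatenate(traces, axis=1) if traces else np.empty((K, 0))
        trace = StateTrace(t0=0.0, dt=tdt, x=xs, seed=seed)
    return rec, trace


def simulate_replica(
    network: NetworkSpec,
    R: int,
    *,
    n_events: int | None = None,
    duration: float | None = None,
    seed: int = 0,
    track_unit: tuple[int, int] | None = None,
    mu_bg: float = DEFAULT_MU_BG,
    external=(),
) -> SpikeRecord:
    """Simulation of the R-replica model with randomized routing.

    On a spike of (j, r) each postsynaptic type i != j receives the jump
    mu_ij in an independently, uniformly drawn replica; the spiking neuron
    resets within its own replica.  With R = 1 the law coincides with
    ``simulate``.  ``track_unit=(i, r)`` records delivery times to that
    unit (for input-stream statistics).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if n_events is None and duration is None:
        raise ValueError("need a stopping rule")
    K = network.K
    h, a, tau = network.h(), network.a(), network.tau()
    W = np.ascontiguousarray(network.weights)
    ext_t, ext_r, ext_j = _ext_channels(network, external, mu_bg)
    x = np.zeros((R, K))
    t_stop = duration if duration is not None else np.inf
    target = n_events if n_events is not None else np.iinfo(np.int64).max
    ti, tr = track_unit if track_unit is not None else (-1, -1)
    cap_del = 2_000_000 if track_unit is not None else 1

    seeds = _chunk_seeds(seed)
    all_t, all_i, all_r, all_d = [], [], [], []
    t = 0.0
    n_total = 0
    chunk_sp = int(min(target, 500_000))
    while True:
        spk_t = np.empty(chunk_sp)
        spk_i = np.empty(chunk_sp, dtype=np.int64)
        spk_r = np.empty(chunk_sp, dtype=np.int64)
        deliv = np.empty(cap_del)
        n_sp, n_del, t, status = _core_replica(
            h, a, tau, W, ext_t, ext_r, ext_j, x, t, t_stop,
            target - n_total, spk_t, spk_i, spk_r, ti, tr, deliv, next(seeds))
        all_t.append(spk_t[:n_sp].copy())
        all_i.append(spk_i[:n_sp].copy())
        all_r.append(spk_r[:n_sp].copy())
        all_d.append(deliv[:n_del].copy())
        n_total += n_sp
        if status == 0:
            break
    rec = SpikeRecord(
        times=np.concatenate(all_t), neurons=np.concatenate(all_i),
        replicas=np.concatenate(all_r), total_time=t, seed=seed,
        deliveries=np.concatenate(all_d) if track_unit is not None else None)
    return rec


def estimate_rates(
    network: NetworkSpec,
    n_events_per_repeat: int,
    n_repeats: int,
    seed: int = 0,
    external=(),
    mu_bg: float = DEFAULT_MU_BG,
) -> RateEstimate:
    """Repeat-count rate estimator.

    Each repeat runs an independent simulation until the network-wide spike
    count reaches ``n_events_per_repeat`` over total time T_k; per-neuron
    rates are S_ik / T_k, averaged over repeats, with the sample standard
    deviation over repeats.
    """
    if n_events_per_repeat < 1:
        raise ValueError("n_events_per_repeat must be >= 1")
    K = network.K
    rates = np.empty((n_repeats, K))
    n_ext = 0
    sub = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31 - 1)
    for k in range(n_repeats):
        rec, _ = simulate(network, n_events=n_events_per_repeat,
                          seed=int(sub[k]), external=external, mu_bg=mu_bg)
        rates[k] = rec.counts(K) / rec.total_time
        n_ext += rec.n_external
    return RateEstimate(
        mean=rates.mean(axis=0),
        std=rates.std(axis=0, ddof=1) if n_repeats > 1 else np.zeros(K),
        n_repeats=n_repeats, n_events_per_repeat=n_events_per_repeat,
        mean_external_events=n_ext / n_repeats)


# ---------------------------------------------------------------------------
# trace statistics
# ---------------------------------------------------------------------------

def empirical_moments(trace: StateTrace, n_max: int = 2,
                      mask: np.ndarray | None = None) -> np.ndarray:
    """Time-averaged moments of x per neuron: (n_max+1, K) array, row n = E[x^n]."""
    x = trace.x if mask is None else trace.x[:, mask]
    if x.shape[1] < 2:
        raise ValueError("trace too short for moment estimation")
    return np.stack([np.mean(x ** n, axis=1) for n in range(n_max + 1)])


def empirical_correlations(trace: StateTrace,
                           mask: np.ndarray | None = None) -> np.ndarray:
    """K x K Pearson correlation matrix of the sampled internal variables."""
    x = trace.x if mask is None else trace.x[:, mask]
    if x.shape[1] < 2:
        raise ValueError("trace too short for correlation estimation")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant trace component: correlation undefined")
    return np.corrcoef(x)
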