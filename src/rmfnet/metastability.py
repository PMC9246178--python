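"""Bistability analysis: bifurcation observable, phase diagrams, critical
scaling, HMM state segmentation, and Eyring-Kramers transition-time
prediction.

The two-group cross-inhibition circuit (see
:func:`rmfnet.network.make_bistable_network`) switches stochastically
between two pseudo-equilibria in which one group is active ("up") and the
other silenced ("down").  In the RMF limit the switch appears as a
pitchfork bifurcation: above a critical excitatory weight the
self-consistent rate system acquires two mirror-symmetric stable
solutions.  The normalized rate contrast

    Delta = (b_Exc^u + b_Inh^u - b_Exc^d - b_Inh^d)
          / (b_Exc^u + b_Inh^u + b_Exc^d + b_Inh^d)

quantifies the splitting (0 when monostable, -> 1 at strong silencing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import make_bistable_network
from .simulate import StateTrace
from .solver import ClusterReduction, RateSolution, find_solutions, reduce_clusters

__all__ = [
    "bifurcation_observable",
    "phase_diagram",
    "critical_weight_scaling",
    "detect_states",
    "predict_transition_time",
    "StateStats",
    "PhaseGrid",
    "KramersPrediction",
]


# ---------------------------------------------------------------------------
# bifurcation observable and phase diagram
# ---------------------------------------------------------------------------

def bifurcation_observable(solutions: list[RateSolution] | RateSolution) -> float:
    """Normalized up/down rate contrast Delta of the two-group circuit.

    Expects cluster-level solutions ordered (Exc1, Inh1, Exc2, Inh2).  A
    single symmetric solution (or a mirror pair) carries both states: the
    dominant group supplies the up rates, the other the down rates; for a
    monostable solution the two coincide and Delta = 0.
    """
    sol = solutions[0] if isinstance(solutions, list) else solutions
    b = np.asarray(sol.beta, dtype=float)
    if b.shape != (4,):
        raise ValueError("need cluster-level rates (Exc1, Inh1, Exc2, Inh2)")
    g1, g2 = b[0] + b[1], b[2] + b[3]
    up, dn = (b[:2], b[2:]) if g1 >= g2 else (b[2:], b[:2])
    num = up.sum() - dn.sum()
    den = up.sum() + dn.sum()
    return float(num / den)


@dataclass
class PhaseGrid:
    """Bifurcation observable on a grid of synaptic strengths."""

    mu_e: np.ndarray
    mu_i: np.ndarray                 # signed (<= 0)
    delta: np.ndarray                # (len(mu_i), len(mu_e)); nan = solver failure
    n_solutions: np.ndarray          # same shape, int
    cluster_size: int
    tmf_drive: float


def phase_diagram(
    cluster_size: int,
    mu_e_grid: np.ndarray,
    mu_i_grid: np.ndarray,
    tmf_drive: float = 1500.0,
    seed: int = 0,
    n_starts: int = 2,
    **net_kw,
) -> PhaseGrid:
    """Delta over a (mu_e, mu_i) grid for the two-group circuit.

    ``mu_i_grid`` entries may be given as magnitudes; they are negated
    internally.  Failed cells are marked nan and skipped.
    """
    mu_e_grid = np.asarray(mu_e_grid, dtype=float)
    mu_i_grid = -np.abs(np.asarray(mu_i_grid, dtype=float))
    delta = np.full((len(mu_i_grid), len(mu_e_grid)), np.nan)
    nsol = np.zeros_like(delta, dtype=int)
    for r, mi in enumerate(mu_i_grid):
        for c, me in enumerate(mu_e_grid):
            net = make_bistable_network(cluster_size, me, mi, tmf_drive, **net_kw)
            red = reduce_clusters(net)
            try:
                sols = find_solutions(net, n_starts=n_starts, seed=seed,
                                      reduction=red)
            except RuntimeError:
                continue
            nsol[r, c] = len(sols)
            delta[r, c] = max(bifurcation_observable(s) for s in sols)
    return PhaseGrid(mu_e=mu_e_grid, mu_i=mu_i_grid, delta=delta,
                     n_solutions=nsol, cluster_size=cluster_size,
                     tmf_drive=tmf_drive)


@dataclass
class ScalingResult:
    """Critical excitatory weight vs network size and its log-log slope."""

    K: np.ndarray
    mu_e_star: np.ndarray
    slope: float
    intercept: float


def critical_weight_scaling(
    K_list,
    ratio_e_over_i: float = 0.2,
    ratio_e_over_tmf: float = 10.0,
    delta_threshold: float = 0.01,
    bracket: tuple[float, float] = (0.2, 2.0),
    rel_tol: float = 0.02,
    seed: int = 0,
    n_tmf_synapses: float = 1000.0,
    tmf_rate: float = 15.0,
    h: float = 1.0,
    a: float = math.log(100.0) / 20.0,
    tau: float = 0.01,
    max_iter: int = 300,
) -> ScalingResult:
    """Critical mu_e at the onset of bistability across network sizes K.

    For each K (total neurons, a multiple of 4) the inhibitory weight and
    the background drive co-vary with mu_e at fixed ratios
    mu_e/|mu_i| = ``ratio_e_over_i`` and mu_e/mu_TMF = ``ratio_e_over_tmf``
    (the background drive is n_TMF-synapses x rate x mu_TMF).  The onset
    mu_e* is located by bisection on the indicator Delta > threshold; the
    result includes the least-squares slope of log mu_e* vs log K
    (balanced-regime scaling predicts about -1/2).
    """
    K_arr = np.asarray(K_list, dtype=int)
    stars = np.empty(len(K_arr), dtype=float)

    def is_bistable(K: int, mu_e: float) -> bool:
        mu_i = -mu_e / ratio_e_over_i
        c = n_tmf_synapses * tmf_rate * (mu_e / ratio_e_over_tmf)
        net = make_bistable_network(K // 4, mu_e, mu_i, c, h=h, a=a, tau=tau)
        red = reduce_clusters(net)
        try:
            sols = find_solutions(net, n_starts=1, seed=seed, reduction=red,
                                  max_iter=max_iter)
        except RuntimeError:
            return False
        return max(bifurcation_observable(s) for s in sols) > delta_threshold

    guess = None
    for idx, K in enumerate(K_arr):
        if K < 8 or K % 4:
            raise ValueError("K must be a multiple of 4 and >= 8")
        lo, hi = bracket
        if guess is not None:
            # warm start from the previous K assuming ~1/sqrt(K)
            center = guess * math.sqrt(K_arr[idx - 1] / K)
            lo = max(bracket[0] / 2.0, center / 2.0)
            hi = min(bracket[1], center * 2.0)
        # scan a geometric grid upward for the first bistable point; the
        # bistable band is an interval in mu_e (its top shrinks with K as
        # up-state drives leave the resummable regime), so probing beyond
        # the band must not escalate further upward
        n_scan = max(int(math.ceil(math.log(hi / lo) / math.log(1.22))), 2)
        grid = np.geomspace(lo, hi, n_scan + 1)
        hit = None
        for g_prev, g in zip(grid[:-1], grid[1:]):
            if is_bistable(K, g):
                lo, hi, hit = g_prev, g, g
                break
        if hit is None:
            raise RuntimeError(
                f"no bistability found for K={K} in mu_e range "
                f"[{grid[0]:.3g}, {grid[-1]:.3g}]")
        while (hi - lo) > rel_tol * hi:
            mid = math.sqrt(lo * hi)
            if is_bistable(K, mid):
                hi = mid
            else:
                lo = mid
        stars[idx] = math.sqrt(lo * hi)
        guess = stars[idx]
    slope, intercept = np.polyfit(np.log(K_arr.astype(float)), np.log(stars), 1)
    return ScalingResult(K=K_arr, mu_e_star=stars, slope=float(slope),
                         intercept=float(intercept))


def rmf_cluster_moments(reduction: ClusterReduction, beta: np.ndarray,
                        n_max: int = 2, **kw):
    """Stationary x-moments of each cluster at a rate solution.

    Returns one :class:`rmfnet.rmf.MomentSet` per cluster, computed from
    the cluster's aggregated Poisson drive at the self-consistent rates.
    """
    from .rmf import moments

    out = []
    for c in range(reduction.n_clusters):
        drive = reduction.drive_for(c, beta)
        rep = reduction.representative(c)
        out.append(moments(drive, reduction.network.params[rep],
                           n_max=n_max, **kw))
    return out


# ---------------------------------------------------------------------------
# HMM state segmentation
# ---------------------------------------------------------------------------

@dataclass
class StateStats:
    """Up/down segmentation of a bistable observable."""

    labels: np.ndarray               # 0 = down, 1 = up, per trace sample
    means: np.ndarray                # conditional mean of the observable, [down, up]
    stds: np.ndarray                 # conditional std, [down, up]
    durations_up: np.ndarray         # dominance periods, s
    durations_down: np.ndarray
    n_transitions: int
    total_time: float
    bistable: bool

    @property
    def mean_transition_time(self) -> float:
        if self.n_transitions == 0:
            return math.inf
        return self.total_time / self.n_transitions


def detect_states(
    observable: np.ndarray,
    dt: float,
    seed: int = 0,
    debounce: float | None = None,
    tau: float = 0.01,
    n_iter: int = 100,
) -> StateStats:
    """Two-state Gaussian-HMM segmentation of a scalar observable.

    The observable is typically the cluster mean of x over one excitatory
    group, sampled at ``dt``.  The HMM is fit by EM (quantile-based
    initialization, fixed seed), decoded by Viterbi, and label runs
    shorter than ``debounce`` (default 5 tau) are merged into their
    predecessor to suppress spurious transitions.  A degenerate fit (one
    state practically empty, or indistinguishable means) is reported as
    monostable.
    """
    from hmmlearn.hmm import GaussianHMM

    y = np.asarray(observable, dtype=float).reshape(-1, 1)
    if len(y) < 10:
        raise ValueError("observable too short")
    model = GaussianHMM(n_components=2, covariance_type="diag",
                        random_state=seed, n_iter=n_iter,
                        init_params="stc", params="stmc")
    q1, q3 = np.quantile(y, [0.25, 0.75])
    model.means_init = np.array([[q1], [q3]])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(y)
        labels = model.predict(y)
    # state 1 = up (larger mean)
    order = np.argsort(model.means_.ravel())
    labels = (labels == order[1]).astype(int)

    if debounce is None:
        debounce = 5.0 * tau
    min_run = max(int(round(debounce / dt)), 1)
    labels = _debounce(labels, min_run)

    total_time = len(y) * dt
    occ_up = labels.mean()
    stats_ok = 0.005 < occ_up < 0.995
    m = np.array([y[labels == s].mean() if np.any(labels == s) else np.nan
                  for s in (0, 1)])
    s = np.array([y[labels == s].std() if np.any(labels == s) else np.nan
                  for s in (0, 1)])
    sep_ok = (np.isfinite(m).all()
              and abs(m[1] - m[0]) > 0.5 * (s[0] + s[1]))
    runs_up, runs_down = _run_durations(labels, dt)
    n_trans = int(np.count_nonzero(np.diff(labels)))
    return StateStats(labels=labels, means=m, stds=s,
                      durations_up=runs_up, durations_down=runs_down,
                      n_transitions=n_trans, total_time=total_time,
                      bistable=bool(stats_ok and sep_ok))


def _debounce(labels: np.ndarray, min_run: int) -> np.ndarray:
    out = labels.copy()
    i = 0
    n = len(out)
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        if j - i < min_run and i > 0:
            out[i:j] = out[i - 1]
        i = j
    return out


def _run_durations(labels: np.ndarray, dt: float):
    change = np.nonzero(np.diff(labels))[0]
    bounds = np.concatenate(([0], change + 1, [len(labels)]))
    runs = np.diff(bounds) * dt
    states = labels[bounds[:-1]]
    return runs[states == 1], runs[states == 0]


def cluster_observable(trace: StateTrace, members: np.ndarray) -> np.ndarray:
    """Cluster-mean observable x̄(t) over the given neuron indices."""
    return trace.x[members].mean(axis=0)


# ---------------------------------------------------------------------------
# Eyring-Kramers transition-time prediction
# ---------------------------------------------------------------------------

@dataclass
class KramersPrediction:
    """Escape-time estimate from an effective double-well potential."""

    time_up_to_down: float           # s
    time_down_to_up: float           # s
    barrier_position: float
    well_positions: tuple[float, float]
    barrier_height: tuple[float, float]  # from (down, up) well

    @property
    def time(self) -> float:
        """Mean transition time (average of the two directions)."""
        return 0.5 * (self.time_up_to_down + self.time_down_to_up)


def predict_transition_time(
    up_stats: tuple[float, float],
    down_stats: tuple[float, float],
    tau: float = 0.01,
    n_grid: int = 4001,
) -> KramersPrediction:
    """Eyring-Kramers transition time from up/down means and stds.

    An equal-weight two-Gaussian mixture p(x) built from the conditional
    moments defines the effective potential U(x) = -ln p(x) (unit
    effective temperature).  The escape time from each well is the
    standard overdamped double-well estimate

        T = 2 pi / sqrt(U''(well) |U''(barrier)|) * exp(U(barrier) - U(well)),

    scaled by the relaxation time ``tau`` as the attempt timescale.  The
    wells must be distinct enough for an interior barrier to exist
    (means separated by more than half the summed stds), else the
    prediction is undefined and a ValueError is raised.
    """
    m_u, s_u = up_stats
    m_d, s_d = down_stats
    if s_u <= 0 or s_d <= 0:
        raise ValueError("state stds must be positive")
    if abs(m_u - m_d) <= 0.5 * (s_u + s_d):
        raise ValueError("wells merged: no interior barrier, prediction undefined")
    lo = min(m_u, m_d) - 4.0 * max(s_u, s_d)
    hi = max(m_u, m_d) + 4.0 * max(s_u, s_d)
    x = np.linspace(lo, hi, n_grid)
    dx = x[1] - x[0]

    def gauss(m, s):
        return np.exp(-0.5 * ((x - m) / s) ** 2) / (s * math.sqrt(2 * math.pi))

    p = 0.5 * gauss(m_u, s_u) + 0.5 * gauss(m_d, s_d)
    U = -np.log(p)
    # wells: local minima nearest to the two state means
    i_u = int(np.argmin(np.abs(x - m_u)))
    i_d = int(np.argmin(np.abs(x - m_d)))
    i_u = _slide_to_min(U, i_u)
    i_d = _slide_to_min(U, i_d)
    a, b = sorted((i_u, i_d))
    if a == b:
        raise ValueError("wells merged: no interior barrier, prediction undefined")
    i_b = a + int(np.argmax(U[a : b + 1]))
    if i_b in (a, b):
        raise ValueError("no interior barrier between the wells")
    d2 = np.gradient(np.gradient(U, dx), dx)
    curv_b = abs(d2[i_b])
    times = {}
    for name, i_w in (("up", i_u), ("down", i_d)):
        curv_w = d2[i_w]
        if curv_w <= 0 or curv_b == 0:
            raise ValueError("degenerate curvature at well or barrier")
        dU = U[i_b] - U[i_w]
        times[name] = tau * 2.0 * math.pi / math.sqrt(curv_w * curv_b) * math.exp(dU)
    return KramersPrediction(
        time_up_to_down=times["up"], time_down_to_up=times["down"],
        barrier_position=float(x[i_b]),
        well_positions=(float(x[i_d]), float(x[i_u])),
        barrier_height=(float(U[i_b] - U[i_d]), float(U[i_b] - U[i_u])))


def _slide_to_min(U: np.ndarray, i: int) -> int:
    n = len(U)
    while 0 < i < n - 1:
        if U[i - 1] < U[i]:
            i -= 1
        elif U[i + 1] < U[i]:
            i += 1
        else:
            break
    return i
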