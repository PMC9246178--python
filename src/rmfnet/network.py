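"""Domain types and builders for linear-exponential-reset (LER) networks.

An LER neuron carries an internal variable ``x`` that integrates synaptic
impulses linearly, relaxes exponentially toward zero with time constant
``tau``, and resets to zero whenever the neuron itself spikes.  Spikes are
emitted by a point process with stochastic intensity

    lambda(t) = h * exp(a * x(t)),

where ``h`` is the spontaneous (base) rate and ``a`` the excitability.
A network is a directed weighted graph of such neurons: weight ``mu[i, j]``
is the jump delivered to ``x_i`` when neuron ``j`` spikes.  On top of the
explicit graph, every neuron may receive a dense background of weak
excitatory synapses, summarized by its mean background drive ``c_i``
(in Hz, the product of aggregate background rate and synaptic strength).

Internal units are seconds and Hz throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "NetworkSpec",
    "PoissonDrive",
    "make_bistable_network",
    "make_layered_network",
    "make_random_network",
]

#: default single-neuron parameters (base rate 1 Hz, excitability 0.1,
#: membrane-like relaxation time 10 ms)
DEFAULT_H = 1.0
DEFAULT_A = 0.1
DEFAULT_TAU = 0.01


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of one LER neuron.

    Attributes
    ----------
    h : float
        Spontaneous firing rate in Hz (> 0).
    a : float
        Excitability, dimensionless (> 0).
    tau : float
        Relaxation time of the internal variable in seconds
        (0 < tau < inf; finite relaxation guarantees ergodicity).
    """

    h: float = DEFAULT_H
    a: float = DEFAULT_A
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        for f in ("h", "a", "tau"):
            object.__setattr__(self, f, float(getattr(self, f)))
        if not (self.h > 0):
            raise ValueError(f"base rate h must be > 0, got {self.h}")
        if not (self.a > 0):
            raise ValueError(f"excitability a must be > 0, got {self.a}")
        if not (0 < self.tau < np.inf):
            raise ValueError(f"relaxation time tau must be finite and > 0, got {self.tau}")


@dataclass(frozen=True)
class PoissonDrive:
    """Aggregate Poissonian input to a single neuron.

    ``channels`` is a sequence of ``(rate, weight)`` pairs: independent
    Poisson streams of the given rate (Hz, >= 0) delivering jumps of the
    given (signed, dimensionless) weight to the internal variable.
    ``background`` is the mean drive c (Hz, >= 0) of a dense cloud of weak
    excitatory synapses, entering the exponential-moment drive function as
    an exact linear term ``c * u``.
    """

    channels: tuple[tuple[float, float], ...] = ()
    background: float = 0.0

    def __post_init__(self) -> None:
        chans = tuple((float(b), float(m)) for b, m in self.channels)
        object.__setattr__(self, "channels", chans)
        for b, m in chans:
            if b < 0:
                raise ValueError(f"channel rate must be >= 0, got {b}")
            if not np.isfinite(m):
                raise ValueError(f"channel weight must be finite, got {m}")
        if self.background < 0:
            raise ValueError(f"background drive must be >= 0, got {self.background}")

    @property
    def mean_drive(self) -> float:
        """Net first-order drive sum(rate * weight) + background, in Hz."""
        return sum(b * m for b, m in self.channels) + self.background


@dataclass
class NetworkSpec:
    """Full parametrization of a K-neuron LER network.

    Attributes
    ----------
    params : list[NeuronParams]
        Per-neuron parameters, length K.
    weights : ndarray, shape (K, K)
        Synaptic jumps; ``weights[i, j]`` is delivered to neuron i when
        neuron j spikes.  The diagonal is zero: self-influence is the
        reset, not a synapse.
    background : ndarray, shape (K,)
        Per-neuron mean background drive c_i in Hz (>= 0).
    """

    params: list[NeuronParams]
    weights: np.ndarray
    background: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        K = len(self.params)
        if self.weights.shape != (K, K):
            raise ValueError(f"weights must be ({K}, {K}), got {self.weights.shape}")
        if np.any(np.diag(self.weights) != 0.0):
            raise ValueError("weight matrix must have a zero diagonal (no autapses)")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.background is None:
            self.background = np.zeros(K)
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (K,):
            raise ValueError(f"background must have shape ({K},)")
        if np.any(self.background < 0):
            raise ValueError("background drive must be >= 0")

    @property
    def K(self) -> int:
        return len(self.params)

    def h(self) -> np.ndarray:
        return np.array([p.h for p in self.params])

    def a(self) -> np.ndarray:
        return np.array([p.a for p in self.params])

    def tau(self) -> np.ndarray:
        return np.array([p.tau for p in self.params])

    def drive_for(self, i: int, rates: np.ndarray) -> PoissonDrive:
        """Incoming Poisson drive of neuron ``i`` given presynaptic rates.

        Channels with identical weights are merged (superposition of
        independent Poisson streams).
        """
        merged: dict[float, float] = {}
        row = self.weights[i]
        for j in range(self.K):
            w = row[j]
            if j != i and w != 0.0:
                merged[w] = merged.get(w, 0.0) + float(rates[j])
        chans = tuple((b, w) for w, b in merged.items())
        return PoissonDrive(channels=chans, background=float(self.background[i]))


# ---------------------------------------------------------------------------
# network builders
# ---------------------------------------------------------------------------

#: parameters used for the bistable two-group circuit
BISTABLE_A = np.log(100.0) / 20.0  # ~0.2303


def make_bistable_network(
    cluster_size: int,
    mu_e: float,
    mu_i: float,
    tmf_drive: float,
    h: float = DEFAULT_H,
    a: float = BISTABLE_A,
    tau: float = DEFAULT_TAU,
) -> NetworkSpec:
    """Two-group cross-inhibition circuit prone to bistable switching.

    The network has 4 clusters of ``cluster_size`` neurons each, in order
    Exc1, Inh1, Exc2, Inh2.  Within-group wiring: each excitatory cluster
    is fully connected within itself (no autapse) and fully excites its
    own inhibitory cluster.  Across groups: each inhibitory cluster fully
    inhibits the *other* group's excitatory and inhibitory clusters.
    All excitatory weights are ``mu_e`` (>= 0), all inhibitory weights
    ``mu_i`` (<= 0).  Every neuron receives the same mean background drive
    ``tmf_drive`` (Hz).
    """
    if cluster_size < 1:
        raise ValueError("cluster_size must be >= 1")
    if mu_e < 0:
        raise ValueError(f"excitatory weight mu_e must be >= 0, got {mu_e}")
    if mu_i > 0:
        raise ValueError(f"inhibitory weight mu_i must be <= 0, got {mu_i}")
    n = cluster_size
    K = 4 * n
    W = np.zeros((K, K))
    sl = {name: slice(k * n, (k + 1) * n) for k, name in enumerate(["E1", "I1", "E2", "I2"])}

    def connect(dst, src, w):
        W[sl[dst], sl[src]] = w

    for g, other in (("1", "2"), ("2", "1")):
        connect("E" + g, "E" + g, mu_e)        # recurrent excitation within Exc_g
        connect("I" + g, "E" + g, mu_e)        # Exc_g -> Inh_g
        connect("E" + other, "I" + g, mu_i)    # Inh_g -> Exc_other
        connect("I" + other, "I" + g, mu_i)    # Inh_g -> Inh_other
    np.fill_diagonal(W, 0.0)
    params = [NeuronParams(h=h, a=a, tau=tau)] * K
    return NetworkSpec(params=params, weights=W, background=np.full(K, float(tmf_drive)))


def bistable_clusters(cluster_size: int) -> list[np.ndarray]:
    """Index arrays of the four clusters (Exc1, Inh1, Exc2, Inh2)."""
    n = cluster_size
    return [np.arange(k * n, (k + 1) * n) for k in range(4)]


def _inhomogeneous_params(K_exc: int, K_inh: int, h: float, a: float, tau: float):
    return [NeuronParams(h=h, a=a, tau=tau)] * (K_exc + K_inh)


def make_layered_network(
    seed: int,
    layer_size: int = 20,
    n_exc_layers: int = 4,
    p_connect: float = 0.75,
    w_range: tuple[float, float] = (3.0, 6.0),
    h: float = 5.0,
    a: float = DEFAULT_A,
    tau: float = DEFAULT_TAU,
) -> NetworkSpec:
    """Feedforward network: 4 excitatory layers plus one inhibitory layer.

    Consecutive layers are connected with probability ``p_connect``; the
    last (inhibitory) layer projects back onto the first layer.  Synaptic
    magnitudes are uniform on ``w_range`` and negated for inhibitory
    sources.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n_layers = n_exc_layers + 1
    K = layer_size * n_layers
    W = np.zeros((K, K))
    layers = [np.arange(k * layer_size, (k + 1) * layer_size) for k in range(n_layers)]
    pairs = [(layers[k + 1], layers[k], 1.0) for k in range(n_layers - 1)]
    pairs.append((layers[0], layers[-1], -1.0))  # inhibitory feedback to layer 1
    for dst, src, sign in pairs:
        mask = rng.random((layer_size, layer_size)) < p_connect
        mags = rng.uniform(*w_range, size=(layer_size, layer_size))
        W[np.ix_(dst, src)] = sign * mags * mask
    np.fill_diagonal(W, 0.0)
    params = _inhomogeneous_params(layer_size * n_exc_layers, layer_size, h, a, tau)
    return NetworkSpec(params=params, weights=W)


def make_random_network(
    seed: int,
    n_exc: int = 80,
    n_inh: int = 20,
    p_connect: float = 0.5,
    w_range: tuple[float, float] = (0.0, 4.0),
    h: float = 5.0,
    a: float = DEFAULT_A,
    tau: float = DEFAULT_TAU,
) -> NetworkSpec:
    """Unstructured network: every ordered pair connected with prob. 0.5.

    The first ``n_exc`` neurons are excitatory, the rest inhibitory;
    magnitudes are uniform on ``w_range``, negated for inhibitory sources.
    """
    rng = np.random.default_rng(seed)
    K = n_exc + n_inh
    mask = rng.random((K, K)) < p_connect
    mags = rng.uniform(*w_range, size=(K, K))
    sign = np.ones(K)
    sign[n_exc:] = -1.0
    W = mags * mask * sign[None, :]
    np.fill_diagonal(W, 0.0)
    params = _inhomogeneous_params(n_exc, n_inh, h, a, tau)
    return NetworkSpec(params=params, weights=W)
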