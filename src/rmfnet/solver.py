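"""Self-consistent stationary rates of recurrent LER networks in the RMF limit.

Each neuron's stationary rate must equal its rate-transfer function
evaluated at the rates of its presynaptic neurons:

    beta_i = F_i({beta_j}),

which is solved by the naive fixed-point iteration beta <- F(beta)
(optionally damped).  The rate-transfer functions are exponentially
supralinear at low rates and weakly sublinear at high rates, so multiple
stable fixed points can coexist; they are located by iterating from an
ensemble of randomized initial conditions and clustering the limits.

For networks with permutation symmetry (e.g. the two-group bistable
circuit) the solver can first reduce neurons to equivalence classes
("clusters") sharing parameters and aggregated inputs, evaluating F once
per class; channel multiplicities enter as rate multipliers of the
incoming Poisson streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import NetworkSpec, PoissonDrive
from .rmf import rate_transfer

__all__ = [
    "RateSolution",
    "solve_fixed_point",
    "find_solutions",
    "reduce_clusters",
    "ClusterReduction",
]


@dataclass
class RateSolution:
    """Converged (or best-effort) self-consistent rate vector."""

    beta: np.ndarray             # Hz, per neuron (or per cluster)
    residual: float              # max_i |beta_i - F_i(beta)| / beta_i
    converged: bool
    n_iter: int
    beta0: np.ndarray = None     # type: ignore[assignment]
    history: list = field(default_factory=list, repr=False)
    cluster_sizes: np.ndarray | None = None

    def expand(self, assignment: np.ndarray) -> np.ndarray:
        """Lift a cluster-level rate vector to per-neuron rates."""
        return self.beta[assignment]


class PadeFailure(RuntimeError):
    """Padé resummation failed to converge for a specific neuron."""

    def __init__(self, neuron: int, beta: np.ndarray):
        super().__init__(f"rate-transfer resummation failed for neuron {neuron}")
        self.neuron = neuron
        self.rates = beta


# ---------------------------------------------------------------------------
# cluster reduction
# ---------------------------------------------------------------------------

@dataclass
class ClusterReduction:
    """Grouping of identical neurons with identical aggregated connectivity.

    ``assignment[i]`` is the cluster id of neuron i; ``multiplicity[c, d]``
    counts presynaptic neurons of cluster d seen by a representative of
    cluster c, and ``weight[c, d]`` the (common) synaptic weight.
    """

    network: NetworkSpec
    assignment: np.ndarray
    sizes: np.ndarray
    multiplicity: np.ndarray
    weight: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def representative(self, c: int) -> int:
        return int(np.nonzero(self.assignment == c)[0][0])

    def drive_for(self, c: int, rates: np.ndarray) -> PoissonDrive:
        """Aggregate incoming drive of cluster c given cluster rates."""
        chans = []
        for d in range(self.n_clusters):
            m = self.multiplicity[c, d]
            if m > 0 and self.weight[c, d] != 0.0:
                chans.append((m * float(rates[d]), float(self.weight[c, d])))
        rep = self.representative(c)
        return PoissonDrive(channels=tuple(chans),
                            background=float(self.network.background[rep]))


def reduce_clusters(network: NetworkSpec,
                    assignment: np.ndarray | None = None) -> ClusterReduction:
    """Partition neurons into equivalence classes for cluster-level solving.

    Without an explicit assignment, the coarsest equitable partition is
    computed by refinement: start from groups of identical (params,
    background) and split until the aggregated weight profile toward every
    class is identical within each class.  An explicit assignment is
    validated and rejected if the declared clusters are not symmetric.
    """
    K = network.K
    W = network.weights
    def _group(keys):
        seen: dict = {}
        out = np.empty(len(keys), dtype=int)
        for i, k in enumerate(keys):
            out[i] = seen.setdefault(k, len(seen))
        return out

    def _exchangeable(i: int, j: int) -> bool:
        # neurons i, j interchangeable by the transposition (i j)
        ri, rj = W[i].copy(), W[j].copy()
        ri[[i, j]] = ri[[j, i]]
        if not np.array_equal(ri, rj):
            return False
        ci, cj = W[:, i].copy(), W[:, j].copy()
        ci[[i, j]] = ci[[j, i]]
        return np.array_equal(ci, cj)

    if assignment is None:
        base = _group([(p.h, p.a, p.tau, float(c))
                       for p, c in zip(network.params, network.background)])
        parent = np.arange(K)

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for g in range(base.max() + 1):
            members = np.nonzero(base == g)[0]
            for idx, i in enumerate(members):
                for j in members[idx + 1:]:
                    if find(i) != find(j) and _exchangeable(i, j):
                        parent[find(j)] = find(i)
        assign = _group([int(find(i)) for i in range(K)])
    else:
        assign = np.asarray(assignment, dtype=int)

    n_cl = assign.max() + 1
    sizes = np.bincount(assign, minlength=n_cl)
    mult = np.zeros((n_cl, n_cl), dtype=int)
    weight = np.zeros((n_cl, n_cl))
    for c in range(n_cl):
        members = np.nonzero(assign == c)[0]
        rep = members[0]
        for d in range(n_cl):
            src = np.nonzero(assign == d)[0]
            ref_count = np.count_nonzero(W[rep, src])
            all_vals: set = set()
            for i in members:
                ws = W[i, src]
                nz = ws[ws != 0.0]
                all_vals.update(np.round(nz, 12).tolist())
                if len(nz) != ref_count:
                    raise ValueError(
                        f"cluster {c} has inhomogeneous in-degree from cluster {d}: "
                        "declared clusters are not symmetric")
            if len(all_vals) > 1:
                raise ValueError(
                    f"cluster {c} receives mixed weights from cluster {d}: "
                    "declared clusters are not symmetric")
            if ref_count:
                mult[c, d] = ref_count
                weight[c, d] = next(iter(all_vals))
        # check identical neuron params within cluster
        p0 = network.params[rep]
        for i in members:
            if network.params[i] != p0 or network.background[i] != network.background[rep]:
                raise ValueError(f"cluster {c} mixes distinct neuron parameters")
    return ClusterReduction(network=network, assignment=assign, sizes=sizes,
                            multiplicity=mult, weight=weight)


# ---------------------------------------------------------------------------
# fixed-point iteration
# ---------------------------------------------------------------------------

def _evaluate_F(network: NetworkSpec, beta: np.ndarray,
                reduction: ClusterReduction | None,
                delta: float, M_cap: int, n_per_a: int) -> np.ndarray:
    out = np.empty_like(beta)
    if reduction is None:
        for i in range(network.K):
            drive = network.drive_for(i, beta)
            r = rate_transfer(drive, network.params[i], delta=delta,
                              M_cap=M_cap, n_per_a=n_per_a)
            if not r.converged:
                raise PadeFailure(i, beta)
            out[i] = r.beta
    else:
        for c in range(reduction.n_clusters):
            drive = reduction.drive_for(c, beta)
            rep = reduction.representative(c)
            r = rate_transfer(drive, network.params[rep], delta=delta,
                              M_cap=M_cap, n_per_a=n_per_a)
            if not r.converged:
                raise PadeFailure(c, beta)
            out[c] = r.beta
    return out


def solve_fixed_point(
    network: NetworkSpec,
    beta0: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 500,
    reduction: ClusterReduction | None = None,
    damping: float = 1.0,
    accelerate: bool = True,
    delta: float = 1e-6,
    M_cap: int = 40,
    n_per_a: int = 200,
) -> RateSolution:
    """Fixed-point iteration beta <- F(beta) for the RMF rate system.

    ``tol`` is a relative residual (max_i |beta_i - F_i| / beta_i).  With
    a ``reduction``, ``beta0`` and the solution are cluster-level vectors.
    If the residual oscillates, the damping factor is halved (down to 1/8)
    to stabilize iterations near a bifurcation.  With ``accelerate`` the
    naive map is wrapped in Anderson mixing with a short memory, which
    removes the slowly contracting modes near the pitchfork bifurcation
    (contraction ratio -> 1) at no extra F evaluations; the converged
    point always satisfies the residual bound by direct evaluation at the
    returned vector.
    """
    beta = np.array(beta0, dtype=float)
    if np.any(beta <= 0):
        raise ValueError("initial rates must be positive")
    gamma = damping
    hist = []
    n_bad = 0
    mem_x: list[np.ndarray] = []    # iterates
    mem_g: list[np.ndarray] = []    # residual vectors F(x) - x
    m_and = 3
    for it in range(1, max_iter + 1):
        F = _evaluate_F(network, beta, reduction, delta, M_cap, n_per_a)
        g = F - beta
        res = float(np.max(np.abs(g) / np.maximum(beta, 1e-12)))
        hist.append(res)
        if res < tol:
            return RateSolution(beta=beta, residual=res, converged=True,
                                n_iter=it, beta0=np.asarray(beta0, float),
                                history=hist,
                                cluster_sizes=None if reduction is None
                                else reduction.sizes)
        new = (1.0 - gamma) * beta + gamma * F
        # Engage Anderson mixing only once the naive residuals contract
        # cleanly and geometrically: before that the iterate may still be
        # escaping an unstable (saddle) fixed point along its unstable
        # manifold, and a Newton-like accelerator would converge onto the
        # saddle instead of a stable solution.
        committed = False
        if len(hist) >= 6:
            r = [hist[-j] / hist[-j - 1] for j in range(1, 6)]
            committed = (all(0.2 < x < 0.999 for x in r)
                         and max(r) - min(r) < 0.05)
        if accelerate and committed:
            mem_x.append(beta.copy())
            mem_g.append(g.copy())
            if len(mem_x) > m_and + 1:
                mem_x.pop(0)
                mem_g.pop(0)
            if len(mem_x) >= 2:
                dG = np.stack([mem_g[j + 1] - mem_g[j]
                               for j in range(len(mem_g) - 1)], axis=1)
                dX = np.stack([mem_x[j + 1] - mem_x[j]
                               for j in range(len(mem_x) - 1)], axis=1)
                theta, *_ = np.linalg.lstsq(dG, g, rcond=1e-10)
                cand = beta + g - (dX + dG) @ theta
                if np.all(np.isfinite(cand)) and np.all(cand > 0):
                    new = np.clip(cand, new / 8.0, new * 8.0)
        elif accelerate and not committed:
            mem_x.clear()
            mem_g.clear()
        beta = new
        if len(hist) >= 2 and res > hist[-2]:
            n_bad += 1
            if n_bad >= 3 and gamma > 0.125:
                gamma *= 0.5
                n_bad = 0
                mem_x.clear()
                mem_g.clear()
    return RateSolution(beta=beta, residual=hist[-1], converged=False,
                        n_iter=max_iter, beta0=np.asarray(beta0, float),
                        history=hist,
                        cluster_sizes=None if reduction is None else reduction.sizes)


def rate_jacobian(
    network: NetworkSpec,
    beta: np.ndarray,
    reduction: ClusterReduction | None = None,
    eps: float = 1e-3,
    delta: float = 1e-6,
    M_cap: int = 40,
    n_per_a: int = 200,
) -> np.ndarray:
    """Forward-difference Jacobian dF_i/dbeta_j of the rate-transfer map.

    The fixed-point iteration beta <- F(beta) is locally stable iff the
    spectral radius of this Jacobian is below 1.
    """
    beta = np.asarray(beta, dtype=float)
    F0 = _evaluate_F(network, beta, reduction, delta, M_cap, n_per_a)
    n = len(beta)
    J = np.empty((n, n))
    for j in range(n):
        pert = beta.copy()
        dbj = eps * max(beta[j], 1e-3)
        pert[j] += dbj
        Fj = _evaluate_F(network, pert, reduction, delta, M_cap, n_per_a)
        J[:, j] = (Fj - F0) / dbj
    return J


def find_solutions(
    network: NetworkSpec,
    n_starts: int = 8,
    eps_scale: float = 5.0,
    seed: int = 0,
    tol: float = 5e-6,
    reduction: ClusterReduction | None = None,
    cluster_tol: float = 1e-3,
    biased_starts: bool = True,
    classify: bool = True,
    **solve_kw,
) -> list[RateSolution]:
    """Locate distinct stable fixed points from randomized initial conditions.

    Starts are beta0 = h + eps with eps uniform on [0, eps_scale] per
    component; with ``biased_starts`` two deterministic starts biased
    toward each half of the network are prepended (useful to reach both
    branches of a mirror-symmetric bistable system).  Converged limits
    within relative distance ``cluster_tol`` are merged; representatives
    are returned sorted by descending first-component rate.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    if reduction is None:
        h = network.h()
    else:
        h = np.array([network.params[reduction.representative(c)].h
                      for c in range(reduction.n_clusters)])
    starts = []
    if biased_starts:
        n = len(h)
        b1 = h.copy() + 0.1 * eps_scale
        b1[: n // 2] += eps_scale
        b2 = h.copy() + 0.1 * eps_scale
        b2[n // 2 :] += eps_scale
        starts += [b1, b2]
    starts += [h + rng.uniform(0.0, eps_scale, size=len(h))
               for _ in range(n_starts)]
    sols: list[RateSolution] = []
    failures = 0

    def _try_add(b0) -> RateSolution | None:
        nonlocal failures
        try:
            sol = solve_fixed_point(network, b0, tol=tol, reduction=reduction,
                                    **solve_kw)
        except PadeFailure:
            failures += 1
            return None
        if not sol.converged:
            failures += 1
            return None
        for other in sols:
            dist = np.max(np.abs(sol.beta - other.beta)
                          / np.maximum(other.beta, 1e-12))
            if dist < cluster_tol:
                return None
        sols.append(sol)
        return sol

    for b0 in starts:
        _try_add(b0)

    # Anderson-assisted solves can land on unstable (saddle) fixed points;
    # classify via the Jacobian spectral radius and re-seed along the
    # unstable eigendirection to reach the flanking stable solutions.
    if classify and reduction is not None and reduction.n_clusters <= 16:
        kw = {k: solve_kw[k] for k in ("delta", "M_cap", "n_per_a")
              if k in solve_kw}
        round2: list[np.ndarray] = []
        keep = []
        for sol in sols:
            try:
                J = rate_jacobian(network, sol.beta, reduction, **kw)
            except PadeFailure:
                keep.append(sol)      # cannot classify; keep as-is
                continue
            eigval, eigvec = np.linalg.eig(J)
            k_max = int(np.argmax(np.abs(eigval)))
            rho = float(np.abs(eigval[k_max]))
            if rho < 1.0:
                keep.append(sol)
            else:
                v = np.real(eigvec[:, k_max])
                v = v / np.max(np.abs(v))
                for sgn in (+1.0, -1.0):
                    b0 = sol.beta * (1.0 + sgn * 0.2 * v)
                    round2.append(np.maximum(b0, 1e-3))
        if round2:
            sols = keep
            for b0 in round2:
                _try_add(b0)
        else:
            sols = keep
    if not sols:
        raise RuntimeError(
            f"no convergent start among {len(starts)} ({failures} failures)")
    sols.sort(key=lambda s: -s.beta[0])
    return sols
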