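"""Closed-form and heuristic reference models.

Three families of baselines complement the full RMF calculation:

* linear Hawkes networks (no reset, rate = intensity): stationary rates
  solve a linear system, and the RMF intensity variance follows from
  Campbell's formula;
* the no-reset first-order approximation of the LER rate-transfer
  function, beta = h exp(sum_j beta_j w_j + c tau a) with effective
  weights w_j = tau int_0^a (e^{mu_j v} - 1)/v dv;
* thermodynamic-mean-field (TMF) approximations, in which the stochastic
  input stream is replaced by its deterministic mean drive D = sum beta_j
  mu_j + c: between spikes x follows the deterministic flow, making the
  dynamics a renewal process whose survival function yields the rate and
  the state moments.  The TMF construction erases input variability,
  which is exactly what comparing it against the RMF moments quantifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .network import NeuronParams, PoissonDrive
from .rmf import aggregate_drive

__all__ = [
    "hawkes_rates",
    "hawkes_rmf_variance",
    "first_order_rate",
    "effective_weight",
    "tmf_rate_and_moments",
    "TMFResult",
]


# ---------------------------------------------------------------------------
# linear Hawkes baseline
# ---------------------------------------------------------------------------

def hawkes_rates(h: np.ndarray, tau: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Stationary rates of a linear (excitatory) Hawkes network.

    Solves beta = h + diag(tau) W beta.  All weights must be nonnegative
    (linear Hawkes intensities cannot absorb inhibition) and the system
    must be stable, i.e. admit a nonnegative solution.
    """
    h = np.atleast_1d(np.asarray(h, dtype=float))
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    if np.any(W < 0):
        raise ValueError("linear Hawkes model requires nonnegative weights")
    K = len(h)
    A = np.eye(K) - tau[:, None] * W
    try:
        beta = np.linalg.solve(A, h)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"unstable Hawkes system (singular balance): {e}") from e
    if np.any(beta <= 0) or not np.all(np.isfinite(beta)):
        raise ValueError(
            "unstable Hawkes system: the linear balance admits no "
            "nonnegative stationary rates (spectral condition violated)")
    return beta


def hawkes_rmf_variance(tau: np.ndarray, weights: np.ndarray,
                        rates: np.ndarray) -> np.ndarray:
    """RMF intensity variance of a Hawkes network via Campbell's formula.

    V[lambda_i] = (tau_i / 2) sum_j mu_ij^2 beta_j for Poissonian inputs.
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    return 0.5 * tau * (W ** 2) @ rates


# ---------------------------------------------------------------------------
# no-reset first order
# ---------------------------------------------------------------------------

def effective_weight(mu: float, neuron: NeuronParams, n: int = 2000) -> float:
    """Effective synaptic weight w = tau int_0^a (e^{mu v} - 1)/v dv.

    Reduces to tau mu a for weak synapses (|mu| << 1/a); the exponential
    enhancement of finite-size excitatory jumps is the leading finite-size
    effect of the RMF framework.
    """
    from scipy.integrate import simpson

    a = neuron.a
    v = np.linspace(0.0, a, n + 1)
    g = np.empty_like(v)
    g[1:] = np.expm1(mu * v[1:]) / v[1:]
    g[0] = mu
    return neuron.tau * float(simpson(g, dx=v[1] - v[0]))


def first_order_rate(drive: PoissonDrive, neuron: NeuronParams
                     ) -> tuple[float, list[float]]:
    """No-reset rate beta = h exp(sum_j beta_j w_j + c tau a) and the w_j."""
    ws = [effective_weight(mu, neuron) for _, mu in drive.channels]
    expo = sum(b * w for (b, _), w in zip(drive.channels, ws))
    expo += drive.background * neuron.tau * neuron.a
    return neuron.h * math.exp(expo), ws


# ---------------------------------------------------------------------------
# TMF renewal approximations
# ---------------------------------------------------------------------------

@dataclass
class TMFResult:
    """TMF rate and internal-variable moments."""

    beta: float                  # Hz
    mean_x: float
    std_x: float
    variant: str


def tmf_rate_and_moments(
    drive: PoissonDrive,
    neuron: NeuronParams,
    variant: str = "with_relaxation",
    dt_factor: float = 5e-3,
    t_deterministic: float = 25.0,
) -> TMFResult:
    """TMF approximation of the stationary rate and x-moments.

    ``with_relaxation``: after each reset x follows x' = -x/tau + D from
    0, the hazard is lambda(t) = h e^{a x(t)}, and rate/moments follow
    from the renewal survival function S(t) = exp(-int_0^t lambda):
    beta = 1 / int S, E[x^n] = beta int x(t)^n S(t) dt.
    ``without_relaxation``: same with x(t) = D t (divergent survival for
    D <= 0 is reported as an error).
    ``high_rate_closed_form``: beta = a D / ln(1 + a D / h), the
    large-drive asymptotic (requires D > 0).
    """
    h, a, tau = neuron.h, neuron.a, neuron.tau
    D = aggregate_drive(drive).slope0

    if variant == "high_rate_closed_form":
        if D <= 0:
            raise ValueError("high-rate closed form requires positive net drive")
        g = a * D / h
        beta = a * D / math.log1p(g)
        return TMFResult(beta=beta, mean_x=math.nan, std_x=math.nan,
                         variant=variant)

    if variant == "with_relaxation":
        x_of = lambda t: D * tau * (-np.expm1(-t / tau))
        x_inf = D * tau
    elif variant == "without_relaxation":
        if D <= 0:
            raise ValueError(
                "without relaxation and non-positive net drive the survival "
                "function is not integrable (neuron silenced): divergent")
        x_of = lambda t: D * t
        x_inf = None
    else:
        raise ValueError(f"unknown TMF variant: {variant}")

    # integrate the survival function on an adaptive grid; with relaxation
    # the hazard plateaus at lambda_inf after ~10 tau and the tail is
    # handled analytically
    dt = tau * dt_factor
    t_grid = np.arange(0.0, t_deterministic * tau + dt, dt)
    x_vals = x_of(t_grid)
    lam = h * np.exp(a * x_vals)
    Lam = cumulative_trapezoid(lam, dx=dt, initial=0.0)
    if variant == "without_relaxation":
        # extend until the survival integral converges
        while Lam[-1] < 40.0:
            t_extra = np.arange(t_grid[-1] + dt, 2 * t_grid[-1], dt)
            x_e = x_of(t_extra)
            lam_e = h * np.exp(a * x_e)
            Lam_e = Lam[-1] + cumulative_trapezoid(
                np.concatenate(([lam[-1]], lam_e)), dx=dt)
            t_grid = np.concatenate([t_grid, t_extra])
            x_vals = np.concatenate([x_vals, x_e])
            lam = np.concatenate([lam, lam_e])
            Lam = np.concatenate([Lam, Lam_e])
            if len(t_grid) > 5e7:
                raise RuntimeError("survival integral did not converge")
    S = np.exp(-Lam)
    int_S = np.trapezoid(S, dx=dt)
    int_xS = np.trapezoid(x_vals * S, dx=dt)
    int_x2S = np.trapezoid(x_vals ** 2 * S, dx=dt)
    if variant == "with_relaxation":
        # analytic tail: x ~ x_inf, constant hazard lambda_inf
        lam_inf = h * math.exp(a * x_inf)
        tail = S[-1] / lam_inf
        int_S += tail
        int_xS += x_inf * tail
        int_x2S += x_inf ** 2 * tail
    beta = 1.0 / int_S
    mean_x = beta * int_xS
    ex2 = beta * int_x2S
    var = max(ex2 - mean_x ** 2, 0.0)
    return TMFResult(beta=beta, mean_x=mean_x, std_x=math.sqrt(var),
                     variant=variant)
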