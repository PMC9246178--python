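"""Replica-mean-field rate and moment calculations for a single LER neuron.

Under the Poisson hypothesis a neuron driven by independent Poisson streams
admits a stationary moment-generating function L(u) = E[exp(u x)] that
satisfies a delay differential equation.  Solving it by a resolvent
(iterated-kernel) expansion expresses the stationary rate as

    h / beta = 1 - a * sum_m (-h tau)^m Q_m(-a),

where the kernels Q_m are built recursively from the homogeneous solution
q(u) = exp(tau * int_a^u V(v)/v dv) and the exponential-moment drive
V(u) = sum_j beta_j (exp(mu_j u) - 1) + c u.  The series is divergent for
excitation-dominated drives (the base rate h is a singular perturbation
parameter), so it is resummed by walking the zigzag diagonal chain of Padé
approximants.

Numerics: q and the kernels vary over thousands of orders of magnitude on
the nested mesh, so the entire kernel pipeline is carried in a signed-log
representation (sign and log-magnitude arrays); per-interval integrals use
exponential-fit quadrature, cumulative sums use ``np.logaddexp.accumulate``,
and the final Padé tables are solved in extended precision with mpmath.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import mpmath
import numpy as np
from scipy.integrate import cumulative_simpson

from .network import NeuronParams, PoissonDrive

__all__ = [
    "aggregate_drive",
    "compute_q",
    "iterate_kernels",
    "pade_eval",
    "rate_transfer",
    "mgf_profile",
    "moments",
    "KernelTable",
    "PadeSum",
    "RateResult",
    "MomentSet",
]

_NEG_INF = -np.inf


# ---------------------------------------------------------------------------
# drive function
# ---------------------------------------------------------------------------

def aggregate_drive(drive: PoissonDrive) -> Callable[[np.ndarray], np.ndarray]:
    """Exponential-moment drive V(u) = sum_j beta_j (e^{mu_j u} - 1) + c u.

    Returns a vectorized callable with attributes ``slope0`` (the removable
    limit of V(u)/u at u = 0, equal to sum_j beta_j mu_j + c) and ``drive``.
    """
    rates = np.array([b for b, _ in drive.channels])
    mus = np.array([m for _, m in drive.channels])
    c = drive.background

    def V(u):
        u = np.asarray(u, dtype=float)
        if rates.size:
            out = np.expm1(np.multiply.outer(u, mus)) @ rates
        else:
            out = np.zeros_like(u)
        return out + c * u

    V.slope0 = float(rates @ mus + c) if rates.size else float(c)
    V.drive = drive
    return V


# ---------------------------------------------------------------------------
# signed-log helpers
# ---------------------------------------------------------------------------

def _log_abs_expm1(x: np.ndarray) -> np.ndarray:
    """log|e^x - 1|, elementwise, overflow-safe."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    big = x >= 30.0
    out[big] = x[big]
    mid = ~big & (x != 0.0)
    with np.errstate(divide="ignore"):
        out[mid] = np.log(np.abs(np.expm1(x[mid])))
    out[x == 0.0] = _NEG_INF
    return out


def _log_em1_over_d(d: np.ndarray) -> np.ndarray:
    """log((e^d - 1)/d), elementwise; the function is positive for all d."""
    d = np.asarray(d, dtype=float)
    out = np.empty_like(d)
    small = np.abs(d) < 1e-6
    out[small] = d[small] / 2.0
    big = d >= 30.0
    out[big] = d[big] - np.log(d[big])
    rest = ~small & ~big
    out[rest] = np.log(np.expm1(d[rest]) / d[rest])
    return out


def _signed_log_add(s1, l1, s2, l2):
    """Sum of two signed-log numbers, vectorized -> (sign, log|.|).

    Invariant maintained throughout the module: sign == 0 iff log == -inf.
    """
    s1, l1, s2, l2 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (s1, l1, s2, l2))
    )
    same = s1 == s2
    with np.errstate(invalid="ignore", divide="ignore"):
        l_same = np.logaddexp(l1, l2)
        l_hi = np.maximum(l1, l2)
        l_lo = np.minimum(l1, l2)
        s_hi = np.where(l1 >= l2, s1, s2)
        ratio = np.exp(l_lo - l_hi)          # nan when both are -inf
        l_opp = l_hi + np.log1p(-ratio)      # -inf on exact cancellation
    l_out = np.where(same, l_same, l_opp)
    s_out = np.where(same, s1, s_hi)
    dead = np.isnan(l_out) | np.isneginf(l_out)
    s_out = np.where(dead, 0.0, s_out)
    l_out = np.where(np.isnan(l_out), _NEG_INF, l_out)
    return s_out, l_out


def _interval_integrals(s: np.ndarray, logf: np.ndarray, dx: float):
    """Signed-log integrals of f over each mesh interval.

    ``f = s * exp(logf)`` on a uniform mesh.  Within an interval where the
    sign is constant, f is interpolated exponentially (exact for locally
    exponential integrands, which is what the kernel recursion produces);
    across a sign change the trapezoid rule is used (the magnitude is small
    there for continuous f).
    """
    s0, s1 = s[:-1], s[1:]
    F0, F1 = logf[:-1], logf[1:]
    same = (s0 == s1) & (s0 != 0.0)
    with np.errstate(invalid="ignore"):
        d = np.where(same, np.subtract(F1, F0, where=same, out=np.zeros_like(F0)), 0.0)
    log_same = F0 + math.log(dx) + _log_em1_over_d(d)
    # trapezoid for mixed/zero-sign intervals: (f0 + f1) * dx / 2
    st, lt = _signed_log_add(s0, F0 + math.log(dx / 2.0), s1, F1 + math.log(dx / 2.0))
    sI = np.where(same, s0, st)
    lI = np.where(same, log_same, lt)
    zero = (s0 == 0.0) & (s1 == 0.0)
    sI = np.where(zero, 0.0, sI)
    lI = np.where(zero, _NEG_INF, lI)
    return sI, lI


def _signed_log_cumsum(sI: np.ndarray, lI: np.ndarray):
    """Cumulative signed-log sums with a leading zero term."""
    pos = np.where(sI > 0, lI, _NEG_INF)
    neg = np.where(sI < 0, lI, _NEG_INF)
    cum_pos = np.concatenate(([_NEG_INF], np.logaddexp.accumulate(pos)))
    cum_neg = np.concatenate(([_NEG_INF], np.logaddexp.accumulate(neg)))
    return _signed_log_add(np.ones_like(cum_pos), cum_pos, -np.ones_like(cum_neg), cum_neg)


# ---------------------------------------------------------------------------
# homogeneous solution and kernel table
# ---------------------------------------------------------------------------

def compute_q(
    drive: PoissonDrive,
    neuron: NeuronParams,
    u: np.ndarray,
) -> np.ndarray:
    """Homogeneous solution q(u) = exp(tau * int_a^u V(v)/v dv) on a uniform grid.

    The grid must be uniform and contain u = a.  The removable singularity
    of V(v)/v at v = 0 is replaced by its series limit.  q(a) = 1 exactly.
    """
    u = np.asarray(u, dtype=float)
    dx = u[1] - u[0]
    if not np.allclose(np.diff(u), dx):
        raise ValueError("mesh must be uniform")
    ia = int(np.argmin(np.abs(u - neuron.a)))
    if abs(u[ia] - neuron.a) > 1e-9 * max(neuron.a, 1.0):
        raise ValueError("mesh must contain u = a")
    return np.exp(_log_q(drive, neuron, u, ia))


def _log_q(drive: PoissonDrive, neuron: NeuronParams, v: np.ndarray, ia: int) -> np.ndarray:
    V = aggregate_drive(drive)
    g = np.empty_like(v)
    nz = v != 0.0
    g[nz] = neuron.tau * V(v[nz]) / v[nz]
    g[~nz] = neuron.tau * V.slope0
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("drive function overflowed on the kernel mesh")
    cum = cumulative_simpson(g, dx=v[1] - v[0], initial=0.0)
    return cum - cum[ia]


@dataclass
class KernelTable:
    """Iterated kernels Q_m of the resolvent expansion, in signed-log form.

    The u-mesh is uniform with spacing a/n_per_a, running from -3a/2 up to
    (M - m)a for kernel order m (nested domains).  ``coef_sign[m]`` and
    ``coef_log[m]`` hold Q_m(-a), the m-th series coefficient.
    """

    neuron: NeuronParams
    drive: PoissonDrive
    M: int
    n_per_a: int
    u: np.ndarray                    # full u-mesh, u[k] = -3a/2 + k * a/n
    log_q: np.ndarray                # log q(u + a) on the same index set
    kernel_sign: list = field(repr=False, default_factory=list)
    kernel_log: list = field(repr=False, default_factory=list)
    coef_sign: np.ndarray = None     # type: ignore[assignment]
    coef_log: np.ndarray = None      # type: ignore[assignment]

    @property
    def iu0(self) -> int:
        return 3 * self.n_per_a // 2

    def coeffs_float(self) -> np.ndarray:
        """Series coefficients c_m = Q_m(-a) as floats (inf on overflow)."""
        with np.errstate(over="ignore"):
            return self.coef_sign * np.exp(self.coef_log)

    def inv_radius(self) -> np.ndarray:
        """Divergence diagnostic 1/r_m = |c_m|^{1/m} for m >= 1 (inf on overflow)."""
        with np.errstate(over="ignore"):
            return np.exp(self.log_inv_radius())

    def log_inv_radius(self) -> np.ndarray:
        """log(1/r_m) = log|c_m| / m for m >= 1; overflow-safe form."""
        return self.coef_log[1:] / np.arange(1, self.M + 1)

    def log_q0(self) -> float:
        """log q(0) (q-grid value at v = 0)."""
        return float(self.log_q[self.n_per_a // 2])

    def kernel_values_at(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(sign, log) of Q_m at mesh index k, for all orders m with k in domain."""
        s, l = [], []
        for m in range(self.M + 1):
            if k < len(self.kernel_sign[m]):
                s.append(self.kernel_sign[m][k])
                l.append(self.kernel_log[m][k])
        return np.array(s), np.array(l)


def iterate_kernels(
    drive: PoissonDrive,
    neuron: NeuronParams,
    M: int = 40,
    n_per_a: int = 200,
) -> KernelTable:
    """Build the iterated-kernel table Q_0 .. Q_M for one neuron's drive.

    Q_0(u) = (q(u+a) - 1)/u and
    Q_m(u) = q(u+a) * (1/u) * int_a^{u+a} Q_{m-1}(v)/q(v) dv,
    with removable limits at u = 0 (Q_0 -> tau V(a)/a, Q_m -> Q_{m-1}(a)).
    The mesh spans u in [-3a/2, (M-m)a] per order (the extra margin below
    -a supports moment extraction from the MGF profile around zero).
    """
    if M < 0:
        raise ValueError("M must be >= 0")
    a, tau = neuron.a, neuron.tau
    n = int(n_per_a)
    if n % 2:
        n += 1
    dx = a / n
    n_tot = (M + 1) * n + (3 * n) // 2          # last index of the full mesh
    k = np.arange(n_tot + 1)
    u = -1.5 * a + k * dx                        # u-mesh; v-mesh is u + a
    v = u + a                                    # q is tabulated at v = u + a
    ia_v = 3 * n // 2                            # v = a
    log_q = _log_q(drive, neuron, v, ia_v)

    iu0 = 3 * n // 2                             # u = 0
    iua = 5 * n // 2                             # u = a
    ium = n // 2                                 # u = -a

    # Q_0 = (q(u+a) - 1)/u
    with np.errstate(divide="ignore", invalid="ignore"):
        l0 = _log_abs_expm1(log_q) - np.log(np.abs(u))
    s0 = np.sign(log_q) * np.sign(u)
    s0[log_q == 0.0] = 0.0
    l0[log_q == 0.0] = _NEG_INF
    lim0 = tau * aggregate_drive(drive)(np.array([a]))[0] / a   # q'(a)
    s0[iu0] = np.sign(lim0)
    l0[iu0] = np.log(abs(lim0)) if lim0 != 0.0 else _NEG_INF

    table = KernelTable(neuron=neuron, drive=drive, M=M, n_per_a=n, u=u, log_q=log_q)
    table.kernel_sign.append(s0)
    table.kernel_log.append(l0)

    for m in range(1, M + 1):
        dom = (M - m) * n + 3 * n // 2           # last u-index of Q_m
        kf = dom                                  # f is needed on v-indices 0..dom
        sp = table.kernel_sign[m - 1]
        lp = table.kernel_log[m - 1]
        # f(v) = Q_{m-1}(v)/q(v); Q_{m-1} at u = v lives at index k + n
        sf = sp[n : kf + n + 1]
        lf = lp[n : kf + n + 1] - log_q[: kf + 1]
        sI, lI = _interval_integrals(sf, lf, dx)
        sS, lS = _signed_log_cumsum(sI, lI)
        # G(v) = int_a^v f = S(v) - S(a)
        sG, lG = _signed_log_add(sS, lS, -sS[ia_v], np.full_like(lS, lS[ia_v]))
        with np.errstate(divide="ignore", invalid="ignore"):
            lQ = log_q[: kf + 1] + lG - np.log(np.abs(u[: kf + 1]))
        sQ = sG * np.sign(u[: kf + 1])
        sQ[iu0] = sp[iua]
        lQ[iu0] = lp[iua]
        table.kernel_sign.append(sQ)
        table.kernel_log.append(lQ)

    table.coef_sign = np.array([table.kernel_sign[m][ium] for m in range(M + 1)])
    table.coef_log = np.array([table.kernel_log[m][ium] for m in range(M + 1)])
    bad = ~np.isfinite(table.coef_log) & (table.coef_sign != 0.0)
    if np.any(bad):
        raise FloatingPointError("non-finite kernel coefficients")
    return table


# ---------------------------------------------------------------------------
# Padé resummation
# ---------------------------------------------------------------------------

@dataclass
class PadeSum:
    """Result of resumming a (possibly divergent) series at one point."""

    value: float
    converged: bool
    M_used: int
    chain: list[float] = field(default_factory=list)
    method: str = "pade"


def _terms_to_mpf(sign: np.ndarray, logabs: np.ndarray, y: float) -> list:
    """Terms d_m = c_m y^m as mpf, from signed-log coefficients."""
    out = []
    ly = mpmath.log(abs(y)) if y != 0 else mpmath.mpf("-inf")
    sy = 1.0 if y >= 0 else -1.0
    for m, (s, l) in enumerate(zip(sign, logabs)):
        if s == 0.0 or l == _NEG_INF or (y == 0 and m > 0):
            out.append(mpmath.mpf(0))
        else:
            out.append(mpmath.sign(s) * (sy ** m) * mpmath.exp(mpmath.mpf(l) + m * ly))
    return out


def pade_eval(
    coeffs,
    y: float,
    delta: float = 1e-6,
    M_cap: int = 40,
    coeff_logs: np.ndarray | None = None,
    dps: int = 40,
) -> PadeSum:
    """Resum sum_m c_m y^m by the zigzag diagonal Padé chain.

    ``coeffs`` is either a float array c_m, or (with ``coeff_logs``) the
    sign array of a signed-log representation.  The rescaled series
    d_m = c_m y^m is evaluated at 1, walking
    [m,m] -> [m,m+1] -> [m+1,m+1] -> ... until two successive chain values
    differ by less than ``delta`` (relative), the coefficients are
    exhausted, or ``M_cap`` orders are consumed.  Singular Padé systems are
    skipped.  Nonconvergence is flagged, never raised.
    """
    if coeff_logs is None:
        c = np.asarray(coeffs, dtype=float)
        sign = np.sign(c)
        with np.errstate(divide="ignore"):
            logs = np.log(np.abs(c))
    else:
        sign = np.asarray(coeffs, dtype=float)
        logs = np.asarray(coeff_logs, dtype=float)
    n_coef = min(len(sign), M_cap + 1)
    if n_coef < 2:
        raise ValueError("need at least 2 series coefficients")
    if np.all(sign[:n_coef] == 0.0):
        return PadeSum(value=0.0, converged=True, M_used=0, chain=[0.0])
    with mpmath.workdps(dps):
        d = _terms_to_mpf(sign[:n_coef], logs[:n_coef], y)
        chain: list[float] = []
        prev = None
        best = float(d[0])
        orders = []
        mm = 0
        while True:  # zigzag: [0,0], [0,1], [1,1], [1,2], [2,2], ...
            orders.append((mm, mm))
            orders.append((mm, mm + 1))
            mm += 1
            if 2 * mm >= n_coef:
                break
        converged = False
        used = 0
        for (L, Mo) in orders:
            if L + Mo + 1 > n_coef:
                break
            try:
                if L == 0 and Mo == 0:
                    val = d[0]
                else:
                    p, q = mpmath.pade(d[: L + Mo + 1], L, Mo)
                    den = mpmath.fsum(q)
                    if den == 0:
                        continue
                    val = mpmath.fsum(p) / den
            except (ZeroDivisionError, ValueError):
                continue
            fval = float(val)
            if not math.isfinite(fval):
                continue
            chain.append(fval)
            used = L + Mo
            best = fval
            if prev is not None and abs(fval - prev) <= delta * max(1.0, abs(fval)):
                converged = True
                break
            # two-cycle at the coefficient-noise level: both interleaved
            # subsequences ([m,m] and [m,m+1]) stabilized
            if (len(chain) >= 4
                    and abs(fval - chain[-3]) <= delta * max(1.0, abs(fval))
                    and abs(chain[-2] - chain[-4]) <= delta * max(1.0, abs(chain[-2]))):
                best = 0.5 * (fval + chain[-2])
                converged = True
                break
            prev = fval
    return PadeSum(value=best, converged=converged, M_used=used, chain=chain, method="pade")


def taylor_eval(coeffs, y: float, delta: float = 1e-6, M_cap: int = 40,
                coeff_logs: np.ndarray | None = None) -> PadeSum:
    """Direct partial sums of sum_m c_m y^m with the same stopping rule."""
    if coeff_logs is None:
        c = np.asarray(coeffs, dtype=float)
        sign = np.sign(c)
        with np.errstate(divide="ignore"):
            logs = np.log(np.abs(c))
    else:
        sign, logs = np.asarray(coeffs, float), np.asarray(coeff_logs, float)
    n_coef = min(len(sign), M_cap + 1)
    with mpmath.workdps(30):
        d = _terms_to_mpf(sign[:n_coef], logs[:n_coef], y)
        chain, prev = [], None
        total = mpmath.mpf(0)
        converged, used = False, 0
        for m, t in enumerate(d):
            total += t
            fval = float(total)
            chain.append(fval)
            used = m
            if not math.isfinite(fval):
                break
            if prev is not None and abs(fval - prev) <= delta * max(1.0, abs(fval)):
                converged = True
                break
            prev = fval
    return PadeSum(value=chain[-1], converged=converged, M_used=used, chain=chain,
                   method="taylor")


# ---------------------------------------------------------------------------
# rate-transfer function and moments
# ---------------------------------------------------------------------------

@dataclass
class RateResult:
    """Stationary rate of one neuron under Poissonian drive."""

    beta: float                  # Hz
    converged: bool
    method: str
    M_used: int
    series_value: float          # resummed S = sum c_m y^m
    table: KernelTable | None = None


Method = Literal["pade", "taylor", "first_order"]


def first_order_log_q0(drive: PoissonDrive, neuron: NeuronParams, n_per_a: int = 400) -> float:
    """log q(0) via direct quadrature (no kernel table needed)."""
    a = neuron.a
    n = n_per_a + (n_per_a % 2)
    v = np.linspace(0.0, a, n + 1)
    V = aggregate_drive(drive)
    g = np.empty_like(v)
    g[1:] = neuron.tau * V(v[1:]) / v[1:]
    g[0] = neuron.tau * V.slope0
    from scipy.integrate import simpson

    return -float(simpson(g, dx=v[1] - v[0]))


def rate_transfer(
    drive: PoissonDrive,
    neuron: NeuronParams,
    method: Method = "pade",
    delta: float = 1e-6,
    M_cap: int = 40,
    n_per_a: int = 200,
    table: KernelTable | None = None,
) -> RateResult:
    """Stationary RMF output rate beta of a neuron under Poissonian drive.

    beta = h / (1 - a S) with S the resummed series sum_m Q_m(-a)(-h tau)^m.
    ``method='first_order'`` returns the no-reset approximation h/q(0)
    (exact first-order term of the expansion).  A table built for the same
    drive may be passed to amortize the kernel computation (e.g. when
    varying h, on which the kernels do not depend).
    """
    h, a, tau = neuron.h, neuron.a, neuron.tau
    if method == "first_order":
        lq0 = first_order_log_q0(drive, neuron)
        return RateResult(beta=h * math.exp(-lq0), converged=True,
                          method=method, M_used=0, series_value=0.0)
    y = -h * tau
    ev = pade_eval if method == "pade" else taylor_eval
    if table is not None:
        ps = ev(table.coef_sign, y, delta=delta, M_cap=M_cap, coeff_logs=table.coef_log)
    else:
        # the chain usually converges well below M_cap orders: ladder the
        # (M-quadratic-cost) kernel table up only on nonconvergence
        ladder = sorted({min(12, M_cap), min(24, M_cap), M_cap})
        for M_try in ladder:
            table = iterate_kernels(drive, neuron, M=M_try, n_per_a=n_per_a)
            ps = ev(table.coef_sign, y, delta=delta, M_cap=M_try,
                    coeff_logs=table.coef_log)
            if ps.converged:
                break
    S = ps.value
    denom = 1.0 - a * S
    ok = ps.converged and denom > 0.0 and math.isfinite(denom)
    beta = h / denom if denom > 0 and math.isfinite(denom) else math.inf
    return RateResult(beta=beta, converged=ok, method=method,
                      M_used=ps.M_used, series_value=S, table=table)


def mgf_profile(
    drive: PoissonDrive,
    neuron: NeuronParams,
    beta: float,
    u_targets: Sequence[float],
    table: KernelTable | None = None,
    delta: float = 1e-6,
    M_cap: int = 40,
    n_per_a: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """MGF values L(u) = beta/h + (u - a) H(u - a) at requested points.

    H(w) = (beta/h) sum_m (-h tau)^m Q_m(w) is resummed per point by the
    Padé chain; each target u is snapped to the kernel mesh.  Returns
    (L values, per-point convergence flags).  L(0) = 1 and L(a) = beta/h
    hold by construction of beta.
    """
    h, a, tau = neuron.h, neuron.a, neuron.tau
    if table is None:
        table = iterate_kernels(drive, neuron, M=M_cap, n_per_a=n_per_a)
    y = -h * tau
    dx = a / table.n_per_a
    out = np.empty(len(u_targets))
    oks = np.empty(len(u_targets), dtype=bool)
    for idx, ut in enumerate(u_targets):
        w = ut - a
        k = int(round((w + 1.5 * a) / dx))
        if k < 0 or k > len(table.u) - 1:
            raise ValueError(f"target u={ut} outside kernel mesh")
        w_grid = table.u[k]
        s, l = table.kernel_values_at(k)
        if len(s) < 2:
            raise ValueError(f"too few kernel orders at u={ut}; increase M")
        ps = pade_eval(s, y, delta=delta, M_cap=M_cap, coeff_logs=l)
        H = (beta / h) * ps.value
        out[idx] = beta / h + w_grid * H
        oks[idx] = ps.converged
    return out, oks


@dataclass
class MomentSet:
    """Stationary moments of the internal variable x and the intensity lambda."""

    beta: float                       # Hz
    x_moments: np.ndarray             # M_n(x), n = 0..n_max
    lambda_moments: dict              # order -> M_n(lambda) in Hz^n
    converged: bool
    method: str = "pade"

    @property
    def mean_x(self) -> float:
        return float(self.x_moments[1])

    @property
    def std_x(self) -> float:
        var = self.x_moments[2] - self.x_moments[1] ** 2
        return math.sqrt(max(var, 0.0))

    def std_lambda(self) -> float:
        m1 = self.lambda_moments[1]
        m2 = self.lambda_moments[2]
        return math.sqrt(max(m2 - m1 * m1, 0.0))


def moments(
    drive: PoissonDrive,
    neuron: NeuronParams,
    n_max: int = 4,
    lambda_orders: Sequence[int] = (1, 2),
    lambda_cutoff: int | None = None,
    delta: float = 1e-6,
    M_cap: int = 40,
    n_per_a: int = 200,
    rate: RateResult | None = None,
) -> MomentSet:
    """Moments of x and lambda from the resummed MGF.

    M_n(x) is the n-th derivative of L at 0, extracted by a least-squares
    polynomial fit of degree n_max + 4 to L on the window [-a/2, a/2].
    M_n(lambda) = h^n E[e^{n a x}] = h^n L(n a); by default this is
    evaluated directly from the resummed profile (the fully summed form of
    the series h^n sum_k (a n)^k / k! M_k(x)); passing ``lambda_cutoff``
    instead truncates that series using the fitted x-moments (diagnostic
    use; the fitted moments degrade beyond small k).
    """
    h, a = neuron.h, neuron.a
    if rate is None:
        rate = rate_transfer(drive, neuron, delta=delta, M_cap=M_cap, n_per_a=n_per_a)
    table = rate.table
    beta = rate.beta
    # fit window [-a/2, a/2], ~33 mesh-aligned points
    n = table.n_per_a
    step = max(n // 32, 1)
    ks = np.arange(0, n + 1, step)
    u_win = -a / 2 + ks * (a / n)
    L_vals, ok = mgf_profile(drive, neuron, beta, u_win, table=table,
                             delta=delta, M_cap=M_cap)
    deg = n_max + 4
    t = u_win / (a / 2.0)
    if np.all(L_vals > 0):
        # fit the cumulant generating function ln L: far closer to a low
        # degree polynomial than L itself when the mean drift is large,
        # which keeps the extracted low-order derivatives accurate
        coefs = np.polynomial.polynomial.polyfit(t, np.log(L_vals), deg)
        kappa = np.array([math.factorial(k) * coefs[k] * (2.0 / a) ** k
                          for k in range(n_max + 1)])
        xm = np.empty(n_max + 1)
        xm[0] = 1.0
        for n in range(1, n_max + 1):
            xm[n] = sum(math.comb(n - 1, k) * kappa[k + 1] * xm[n - 1 - k]
                        for k in range(n))
    else:
        coefs = np.polynomial.polynomial.polyfit(t, L_vals, deg)
        xm = np.array([math.factorial(k) * coefs[k] * (2.0 / a) ** k
                       for k in range(n_max + 1)])
        xm[0] = 1.0
    lam: dict[int, float] = {}
    for nn in lambda_orders:
        if lambda_cutoff is not None:
            kk = np.arange(0, min(lambda_cutoff, n_max) + 1)
            terms = (a * nn) ** kk / np.array([math.factorial(int(k)) for k in kk]) * xm[kk]
            lam[nn] = h ** nn * float(terms.sum())
        elif nn == 0:
            lam[nn] = 1.0
        elif nn == 1:
            lam[nn] = beta
        else:
            Lval, oknn = mgf_profile(drive, neuron, beta, [nn * a], table=table,
                                     delta=delta, M_cap=M_cap)
            ok = np.append(ok, oknn)
            lam[nn] = h ** nn * float(Lval[0])
    return MomentSet(beta=beta, x_moments=xm, lambda_moments=lam,
                     converged=bool(rate.converged and np.all(ok)))
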