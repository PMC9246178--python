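"""RMF engine: drive function, homogeneous solution, iterated kernels,
Padé resummation, rate-transfer function and moments.

Frozen expected values were computed with an independent mpmath
arbitrary-precision quadrature oracle (direct evaluation of the defining
integrals, no shared code with the mesh pipeline).
"""

import math

import numpy as np
import pytest

from rmfnet.network import NeuronParams, PoissonDrive
from rmfnet.rmf import (
    aggregate_drive,
    compute_q,
    iterate_kernels,
    mgf_profile,
    moments,
    pade_eval,
    rate_transfer,
    taylor_eval,
)

EMPTY = PoissonDrive()


class TestAggregateDrive:
    def test_empty_drive_is_identically_zero(self):
        V = aggregate_drive(EMPTY)
        assert np.all(V(np.linspace(-1, 1, 7)) == 0.0)
        assert V.slope0 == 0.0

    def test_single_channel_value(self):
        # 500*(e^0.3 - 1); mpmath oracle
        V = aggregate_drive(PoissonDrive(channels=((500.0, 3.0),)))
        assert V(np.array([0.1]))[0] == pytest.approx(174.92940378800155, rel=1e-12)

    def test_vanishes_at_zero_with_correct_slope(self):
        d = PoissonDrive(channels=((200.0, 2.0), (100.0, -1.0)), background=50.0)
        V = aggregate_drive(d)
        assert V(np.array([0.0]))[0] == 0.0
        assert V.slope0 == pytest.approx(200 * 2 - 100 + 50)
        u = 1e-8
        assert V(np.array([u]))[0] / u == pytest.approx(V.slope0, rel=1e-6)


class TestHomogeneousSolution:
    def test_no_inputs_gives_unity(self, neuron):
        u = np.linspace(-0.1, 0.4, 501)
        assert np.allclose(compute_q(EMPTY, neuron, u), 1.0)

    def test_normalized_at_a_for_any_drive(self, neuron, exc_drive):
        u = np.linspace(-0.1, 0.4, 501)
        q = compute_q(exc_drive, neuron, u)
        ia = np.argmin(np.abs(u - neuron.a))
        assert q[ia] == pytest.approx(1.0, abs=1e-12)
        assert np.all(q > 0)

    def test_q_at_zero_matches_quadrature_oracle(self, neuron, exc_drive):
        # q(0) = exp(-tau*beta_e*int_0^a (e^v-1)/v dv); mpmath oracle
        u = np.linspace(-0.1, 0.4, 2001)
        q = compute_q(exc_drive, neuron, u)
        i0 = np.argmin(np.abs(u))
        assert q[i0] == pytest.approx(0.35859339342199533, rel=1e-6)


class TestIteratedKernels:
    def test_no_inputs_all_coefficients_vanish(self, neuron):
        t = iterate_kernels(EMPTY, neuron, M=8)
        assert np.all(t.coef_sign == 0.0)

    def test_Q0_removable_limit_at_zero(self, neuron):
        # Q_0(0) = tau*V(a)/a by l'Hopital
        d = PoissonDrive(channels=((500.0, 3.0),))
        t = iterate_kernels(d, neuron, M=2)
        V_a = 500.0 * math.expm1(3.0 * neuron.a)
        got = t.kernel_sign[0][t.iu0] * math.exp(t.kernel_log[0][t.iu0])
        assert got == pytest.approx(neuron.tau * V_a / neuron.a, rel=1e-12)

    def test_low_order_coefficients_match_mpmath_oracle(self, neuron):
        d = PoissonDrive(channels=((500.0, 3.0),))
        t = iterate_kernels(d, neuron, M=2)
        c = t.coeffs_float()
        assert c[0] == pytest.approx(8.021889507810773, rel=1e-8)
        assert c[1] == pytest.approx(13.867401403628613, rel=1e-5)

    def test_divergence_diagnostics_reproduce_input_type_pattern(self, neuron):
        """Strong excitation: 1/r_m grows without bound; inhibition: plateau."""
        exc = iterate_kernels(PoissonDrive(channels=((500.0, 3.0),)), neuron, M=40)
        lr_exc = exc.log_inv_radius()
        # superexponential growth: increasing beyond small m, unbounded
        assert np.all(np.diff(lr_exc[3:]) > 0)
        assert lr_exc[-1] > lr_exc[9] + math.log(100.0)
        inh = iterate_kernels(PoissonDrive(channels=((500.0, -3.0),)), neuron, M=40)
        lr_inh = inh.log_inv_radius()
        # bounded: the tail varies slowly and stays finite
        assert np.all(np.isfinite(lr_inh))
        assert abs(lr_inh[-1] - lr_inh[-10]) < 0.2


class TestPade:
    def test_geometric_series(self):
        ps = pade_eval([1.0] * 10, 0.5)
        assert ps.converged
        assert ps.value == pytest.approx(2.0, rel=1e-12)

    def test_euler_series_resummation(self):
        # sum (-1)^m m! y^m at y=0.1 -> int_0^inf e^-t/(1+0.1t) dt (mpmath)
        coeffs = [(-1) ** m * math.factorial(m) for m in range(25)]
        ps = pade_eval(coeffs, 0.1, delta=1e-8)
        assert ps.converged
        assert ps.value == pytest.approx(0.91563333939788081, rel=1e-6)

    def test_taylor_eval_gives_partial_sums(self):
        coeffs = [1.0, 2.0, 3.0, 4.0]
        ps = taylor_eval(coeffs, 0.5, delta=0.0)
        partials = np.cumsum([c * 0.5 ** m for m, c in enumerate(coeffs)])
        assert np.allclose(ps.chain, partials)

    def test_all_zero_series(self):
        ps = pade_eval([0.0, 0.0, 0.0], -0.5)
        assert ps.converged and ps.value == 0.0

    def test_requires_two_coefficients(self):
        with pytest.raises(ValueError):
            pade_eval([1.0], 0.5)


class TestRateTransfer:
    def test_no_inputs_beta_equals_h_all_methods(self, neuron):
        for method in ("pade", "taylor", "first_order"):
            r = rate_transfer(EMPTY, neuron, method=method)
            assert r.beta == pytest.approx(neuron.h, rel=1e-9), method

    def test_zeroth_truncation_is_first_order_formula(self, neuron, exc_drive):
        """Truncating the series at M=0 reproduces h/q(0) algebraically."""
        r0 = rate_transfer(exc_drive, neuron, method="taylor", M_cap=0)
        rf = rate_transfer(exc_drive, neuron, method="first_order")
        assert r0.beta == pytest.approx(rf.beta, rel=1e-5)

    def test_taylor_and_pade_agree_when_series_converges(self, neuron):
        # inhibition-dominated drive: finite radius, direct summation works
        d = PoissonDrive(channels=((500.0, -3.0),))
        rp = rate_transfer(d, neuron, method="pade")
        rt = rate_transfer(d, neuron, method="taylor")
        assert rp.converged and rt.converged
        assert rp.beta == pytest.approx(rt.beta, rel=1e-5)

    def test_monotone_in_excitatory_and_inhibitory_rates(self, neuron):
        betas_e = [rate_transfer(PoissonDrive(channels=((b, 1.0),)), neuron).beta
                   for b in (0.0, 500.0, 1000.0, 2000.0)]
        assert np.all(np.diff(betas_e) > 0)
        betas_i = [rate_transfer(PoissonDrive(channels=((b, -1.0),)), neuron).beta
                   for b in (0.0, 500.0, 1000.0, 2000.0)]
        assert np.all(np.diff(betas_i) < 0)

    def test_spontaneous_spiking_dominates_at_large_h(self, exc_drive):
        """beta/h -> 1 as h grows: resets erase input integration."""
        ratios = []
        for h in (1.0, 10.0, 100.0):
            n = NeuronParams(h=h, a=0.1, tau=0.01)
            r = rate_transfer(exc_drive, n)
            assert r.converged
            ratios.append(r.beta / h)
        assert ratios[0] > ratios[1] > ratios[2] > 1.0
        assert ratios[2] < 1.5


class TestMGFAndMoments:
    def test_profile_normalization(self, neuron, exc_drive):
        r = rate_transfer(exc_drive, neuron)
        L, ok = mgf_profile(exc_drive, neuron, r.beta, [0.0, neuron.a],
                            table=r.table)
        assert ok.all()
        assert L[0] == pytest.approx(1.0, abs=1e-6)
        assert L[1] == pytest.approx(r.beta / neuron.h, rel=1e-6)

    def test_no_inputs_degenerate_distribution(self, neuron):
        ms = moments(EMPTY, neuron, n_max=3, lambda_orders=(1, 2))
        assert ms.x_moments[0] == 1.0
        assert np.allclose(ms.x_moments[1:], 0.0, atol=1e-9)
        assert ms.lambda_moments[1] == pytest.approx(neuron.h, rel=1e-9)
        assert ms.lambda_moments[2] == pytest.approx(neuron.h ** 2, rel=1e-6)

    def test_second_moment_dominates_squared_mean(self, neuron, exc_drive):
        ms = moments(exc_drive, neuron, n_max=2)
        assert ms.converged
        assert ms.x_moments[2] >= ms.x_moments[1] ** 2

    def test_mean_x_approaches_linear_drive_prediction(self, neuron):
        # weak drive: E[x] ~ tau * beta_e * mu_e (relaxation/input balance)
        d = PoissonDrive(channels=((200.0, 0.1),))
        ms = moments(d, neuron, n_max=2)
        assert ms.mean_x == pytest.approx(0.01 * 200 * 0.1, rel=0.05)
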