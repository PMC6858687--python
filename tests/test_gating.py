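"""Gating core: rate constants, persistent-current transform, three-state
drug-binding subsystem and its exact propagation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import null_space

from navsim import (
    ChannelState,
    DrugModel,
    GatingParams,
    HSubsystemState,
    NO_DRUG,
    h_inf_prime,
    h_subsystem_matrix,
    persistent_transform,
    propagate,
    sodium_current,
    standard_h_rates,
    steady_state,
)
from navsim import gating


class TestStandardRates:
    def test_midpoint_rates_are_half_tau(self, wt_params):
        V = wt_params.h_inf_Vhalf_mV
        alpha, beta = standard_h_rates(V, wt_params)
        tau = float(gating.tau_h(V, wt_params))
        assert alpha == pytest.approx(0.5 / tau)
        assert beta == pytest.approx(0.5 / tau)

    def test_hyperpolarized_limit_beta_vanishes(self, wt_params):
        alpha, beta = standard_h_rates(-150.0, wt_params)
        assert beta == pytest.approx(0.0, abs=1e-5)
        assert alpha > 0

    def test_rate_ratio_reproduces_boltzmann(self, wt_params):
        # independent evaluation of the Boltzmann steady state at -90 mV
        expected = 1.0 / (1.0 + np.exp((-90.0 - wt_params.h_inf_Vhalf_mV) / wt_params.h_inf_k_mV))
        alpha, beta = standard_h_rates(-90.0, wt_params)
        assert alpha / (alpha + beta) == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_voltage_rejected(self, wt_params):
        with pytest.raises(ValueError, match="finite"):
            standard_h_rates(np.nan, wt_params)


class TestPersistentTransform:
    def test_worked_example(self):
        alpha_p, beta_p = persistent_transform(0.5, 4.0, 0.05)
        assert alpha_p == pytest.approx(0.7)
        assert beta_p == pytest.approx(3.8)

    def test_identity_and_degenerate_cases(self):
        assert persistent_transform(0.5, 4.0, 0.0) == (0.5, 4.0)
        alpha_p, beta_p = persistent_transform(0.5, 4.0, 1.0)
        assert beta_p == 0.0
        assert alpha_p == pytest.approx(4.5)

    @settings(deadline=None, derandomize=True)
    @given(
        alpha=st.floats(0, 100),
        beta=st.floats(0, 100),
        P=st.floats(0, 1),
    )
    def test_rate_sum_preserved_exactly(self, alpha, beta, P):
        """The transform must not change the apparent fast time constant."""
        alpha_p, beta_p = persistent_transform(alpha, beta, P)
        assert float(alpha_p + beta_p) == pytest.approx(alpha + beta, rel=1e-15, abs=1e-12)

    def test_out_of_range_P_rejected(self):
        with pytest.raises(ValueError):
            persistent_transform(0.5, 4.0, 1.5)


class TestHInfPrime:
    @pytest.mark.parametrize(
        "h, P, expected",
        [(0.0, 0.05, 0.05), (1.0, 0.3, 1.0), (0.5, 0.05, 0.525)],
    )
    def test_values(self, h, P, expected):
        assert h_inf_prime(h, P) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(
        h1=st.floats(0, 1), h2=st.floats(0, 1),
        P1=st.floats(0, 1), P2=st.floats(0, 1),
    )
    def test_bounds_and_monotonicity(self, h1, h2, P1, P2):
        v = h_inf_prime(h1, P1)
        assert P1 - 1e-12 <= v <= 1 + 1e-12
        if h2 >= h1:
            assert h_inf_prime(h2, P1) >= v - 1e-12
        if P2 >= P1:
            assert h_inf_prime(h1, P2) >= v - 1e-12

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            h_inf_prime(1.2, 0.0)


class TestSubsystemMatrix:
    def test_columns_sum_to_zero(self, wt_params, gs967):
        for V in (-120.0, -90.0, -40.0, 0.0, 40.0):
            Q = h_subsystem_matrix(V, wt_params, gs967)
            np.testing.assert_allclose(Q.sum(axis=0), 0.0, atol=1e-15)

    def test_no_direct_available_to_bound_edge(self, wt_params, gs967):
        Q = h_subsystem_matrix(0.0, wt_params, gs967)
        assert Q[2, 0] == 0.0 and Q[0, 2] == 0.0

    def test_zero_drug_block_reduces_to_two_states(self, wt_params):
        Q = h_subsystem_matrix(-60.0, wt_params, NO_DRUG)
        assert Q[2, 1] == 0.0  # no binding flux into the bound state
        state = propagate(steady_state(-90.0, wt_params), -60.0, 50.0, wt_params, NO_DRUG)
        assert state.h_sub.pIGS == 0.0

    def test_bound_fraction_matches_binding_equilibrium(self, mutant_params, gs967):
        """At a strongly depolarized potential the available state empties
        (up to the persistent floor) and the I/I_drug pool partitions by
        the binding equilibrium λ[GS]/(λ[GS]+μ).  The null space of the
        generator is computed by an independent linear solve."""
        # impose alpha'=0 by zeroing the persistent floor contribution
        params = mutant_params.replace(P_persist=0.0)
        Q = h_subsystem_matrix(60.0, params, gs967)
        Q[0, 1] = 0.0  # alpha' -> 0: no recovery path
        Q[1, 1] = -(Q[2, 1])  # rebalance column sum without recovery
        ns = null_space(Q)
        p = ns[:, 0] / ns[:, 0].sum()
        kon, koff = gs967.kon_per_ms, gs967.koff_per_ms
        assert p[2] / (p[1] + p[2]) == pytest.approx(kon / (kon + koff), rel=1e-9)


class TestPropagate:
    def test_long_step_reaches_modified_steady_state(self, mutant_params):
        state = steady_state(-120.0, mutant_params)
        out = propagate(state, -30.0, 5000.0, mutant_params, NO_DRUG)
        hi = float(gating.h_inf(-30.0, mutant_params))
        expected = h_inf_prime(hi, mutant_params.P_persist)
        assert out.h_sub.pA == pytest.approx(expected, abs=1e-9)

    def test_semigroup_property(self, wt_params, gs967):
        state = steady_state(-90.0, wt_params, gs967)
        one = propagate(state, -20.0, 7.0, wt_params, gs967)
        two = propagate(
            propagate(state, -20.0, 3.0, wt_params, gs967), -20.0, 4.0, wt_params, gs967
        )
        np.testing.assert_allclose(
            one.h_sub.as_vector(), two.h_sub.as_vector(), atol=1e-10
        )
        assert one.m == pytest.approx(two.m, abs=1e-12)
        assert one.s == pytest.approx(two.s, abs=1e-12)

    def test_drug_free_reduction_to_two_state_analytic(self, mutant_params):
        """With no drug the three-state propagation must equal the
        closed-form h(t) = h'inf + (h0 - h'inf) exp(-(a'+b')t)."""
        state = steady_state(-90.0, mutant_params)
        h0 = state.h_sub.pA
        for V in (-70.0, -40.0, 0.0):
            alpha_p, beta_p = gating.effective_h_rates(V, mutant_params)
            hp = h_inf_prime(float(gating.h_inf(V, mutant_params)), mutant_params.P_persist)
            for dt in (0.1, 1.0, 10.0):
                out = propagate(state, V, dt, mutant_params, NO_DRUG)
                analytic = hp + (h0 - hp) * np.exp(-(float(alpha_p) + float(beta_p)) * dt)
                assert out.h_sub.pA == pytest.approx(analytic, abs=1e-10)

    def test_probability_conservation_along_protocol(self, mutant_params, gs967):
        state = steady_state(-90.0, mutant_params, gs967)
        for V, dt in [(0.0, 70.0), (-90.0, 3.0), (0.0, 20.0), (-120.0, 500.0)]:
            state = propagate(state, V, dt, mutant_params, gs967)
            vec = state.h_sub.as_vector()
            assert np.all(vec >= 0) and np.all(vec <= 1)
            assert vec.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_brute_force_ode_integration(self, wt_params):
        """Eigen-propagation vs a fixed-step 4th-order Runge-Kutta oracle
        on 100 random (V, P_persist, [GS967]) conditions."""
        rng = np.random.default_rng(42)
        n = 100
        Vs = rng.uniform(-120, 60, n)
        Ps = rng.uniform(0, 0.1, n)
        concs = rng.uniform(0, 10, n)
        worst = 0.0
        for V, P, conc in zip(Vs, Ps, concs):
            params = wt_params.replace(P_persist=float(P))
            drug = DrugModel(concentration_uM=float(conc))
            state = steady_state(-90.0, params)
            out = propagate(state, float(V), 1.0, params, drug)
            # brute-force RK4, dt = 1e-4 ms
            Q = h_subsystem_matrix(float(V), params, drug)
            p = state.h_sub.as_vector()
            dt = 1e-4
            for _ in range(10_000):
                k1 = Q @ p
                k2 = Q @ (p + 0.5 * dt * k1)
                k3 = Q @ (p + 0.5 * dt * k2)
                k4 = Q @ (p + dt * k3)
                p = p + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            worst = max(worst, float(np.max(np.abs(out.h_sub.as_vector() - p))))
        assert worst < 1e-8

    def test_depolarized_steady_state_is_persistent_fraction(self, wt_params):
        for P in (0.01, 0.05):
            params = wt_params.replace(P_persist=P)
            ss = steady_state(60.0, params)
            assert ss.h_sub.pA == pytest.approx(P, abs=1e-6)

    def test_rejects_nonpositive_dt(self, wt_params):
        with pytest.raises(ValueError):
            propagate(steady_state(-90, wt_params), -90.0, 0.0, wt_params)


class TestSodiumCurrent:
    def test_reversal_and_closed_gates(self, wt_params):
        open_state = ChannelState(m=1.0, s=1.0, h_sub=HSubsystemState(1.0, 0.0, 0.0))
        assert sodium_current(wt_params.E_Na_mV, open_state, wt_params) == 0.0
        shut = ChannelState(m=0.0, s=1.0, h_sub=HSubsystemState(1.0, 0.0, 0.0))
        assert sodium_current(-10.0, shut, wt_params) == 0.0

    def test_product_form_arithmetic(self):
        params = GatingParams(G_Na_nS=10.0)
        state = ChannelState(m=1.0, s=1.0, h_sub=HSubsystemState(1.0, 0.0, 0.0))
        assert sodium_current(-10.0, state, params) == pytest.approx(-600.0)
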