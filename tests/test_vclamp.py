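"""Voltage-clamp engine: protocol simulation and derived summary curves."""

import numpy as np
import pandas as pd
import pytest

from navsim import GatingParams, DrugModel, NO_DRUG, Trace
from navsim import gating, vclamp
from navsim.fitting import fit_boltzmann, fit_recovery
from navsim.vclamp import (
    Epoch,
    SweepSpec,
    VoltageProtocol,
    default_iv_protocol,
    iv_summary,
    recovery_protocol,
    run_protocol,
    ssi_protocol,
)


class TestRunProtocol:
    def test_empty_protocol_rejected(self, wt_params):
        proto = VoltageProtocol(name="x", epochs=())
        with pytest.raises(ValueError, match="at least one epoch"):
            run_protocol(proto, wt_params)

    def test_holding_only_trace_is_flat(self, wt_params):
        proto = VoltageProtocol(name="hold", epochs=(Epoch(50.0, -90.0),), holding_mV=-90.0)
        (tr,) = run_protocol(proto, wt_params)
        assert np.ptp(tr.y) < 1e-6 * max(1.0, np.max(np.abs(tr.y)))

    def test_iv_family_inactivates_completely_without_persistence(self, wt_params):
        traces = run_protocol(default_iv_protocol(step_mV=[-10.0, 0.0]), wt_params)
        table = iv_summary(traces)
        # transient inward peak, end-pulse decayed to ~0
        assert (table["peak_pA"] < -100).all()
        assert (table["end_pulse_pA"].abs() < 0.02 * table["peak_pA"].abs()).all()

    def test_persistent_plateau_matches_closed_form(self, mutant_params):
        """End-pulse current of the P=5% channel at 0 mV agrees with the
        direct steady-state evaluation G(V-E)·m_inf³·h'_inf·s(t)."""
        traces = run_protocol(default_iv_protocol(step_mV=[0.0]), mutant_params)
        end = iv_summary(traces)["end_pulse_pA"].iloc[0]
        p = mutant_params
        mi = float(gating.m_inf(0.0, p))
        hp = float(gating.h_inf_prime(float(gating.h_inf(0.0, p)), p.P_persist))
        # s at the end of the 70 ms step, starting from holding steady state
        s0 = float(gating.s_inf(-90.0, p))
        si = float(gating.s_inf(0.0, p))
        ts = float(gating.tau_s(0.0, p))
        s_end = si + (s0 - si) * np.exp(-69.0 / ts)  # final-2-ms window midpoint
        expected = p.G_Na_nS * (0.0 - p.E_Na_mV) * mi**3 * hp * s_end
        assert end == pytest.approx(expected, rel=0.02)

    def test_end_over_peak_ratio_for_persistent_mutant(self, mutant_params):
        traces = run_protocol(default_iv_protocol(step_mV=[0.0]), mutant_params)
        row = iv_summary(traces).iloc[0]
        ratio = row["end_pulse_pA"] / row["peak_pA"]
        assert 0.04 <= ratio <= 0.08

    def test_deterministic_traces(self, wt_params, gs967):
        proto = default_iv_protocol(step_mV=[-20.0, 0.0])
        a = run_protocol(proto, wt_params, gs967)
        b = run_protocol(proto, wt_params, gs967)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.y, tb.y) and np.array_equal(ta.t, tb.t)

    def test_sampling_rate_invariance_of_summaries(self, mutant_params):
        coarse = iv_summary(
            run_protocol(default_iv_protocol(step_mV=[0.0], sample_interval_ms=0.02), mutant_params)
        )
        fine = iv_summary(
            run_protocol(default_iv_protocol(step_mV=[0.0], sample_interval_ms=0.01), mutant_params)
        )
        for col in ("peak_pA", "end_pulse_pA"):
            assert fine[col].iloc[0] == pytest.approx(coarse[col].iloc[0], rel=1e-3)


class TestIVSummary:
    def test_flat_zero_trace(self):
        t = np.arange(0, 80.0, 0.02)
        tr = Trace(t, np.zeros_like(t), {"step_start_ms": 5.0, "step_end_ms": 75.0, "step_mV": 0.0})
        row = iv_summary([tr]).iloc[0]
        assert row["peak_pA"] == 0.0 and row["end_pulse_pA"] == 0.0

    def test_recovers_inserted_extremum(self):
        t = np.arange(0, 80.0, 0.02)
        y = np.zeros_like(t)
        y[np.argmin(np.abs(t - 10.0))] = -1234.0
        tr = Trace(t, y, {"step_start_ms": 5.0, "step_end_ms": 75.0, "step_mV": -20.0})
        assert iv_summary([tr])["peak_pA"].iloc[0] == -1234.0

    def test_step_shorter_than_window_rejected(self):
        t = np.arange(0, 5.0, 0.02)
        tr = Trace(t, np.zeros_like(t), {"step_start_ms": 1.0, "step_end_ms": 2.0, "step_mV": 0.0})
        with pytest.raises(ValueError, match="shorter"):
            iv_summary([tr])


class TestRecoveryProtocol:
    def test_short_interval_matches_end_of_conditioning_ratio(self, wt_params):
        rec = recovery_protocol(wt_params, intervals_ms=[0.05, 1.0])
        # with essentially no recovery time the test pulse sees the
        # conditioning-end availability (≈ 0 for a fully inactivating channel)
        assert rec["fraction"].iloc[0] < 0.1

    def test_drug_free_tau_matches_analytic_rate(self, wt_params):
        """Single-exponential recovery at -90 mV must report 1/(α'+β').

        A short conditioning pulse avoids engaging the slow gate and
        intervals below 2 ms are excluded because the activation gate has
        not yet fully deactivated there.
        """
        alpha, beta = gating.effective_h_rates(-90.0, wt_params)
        tau_true = 1.0 / float(alpha + beta)
        rec = recovery_protocol(
            wt_params, conditioning_ms=5.0, intervals_ms=np.geomspace(2.0, 12.0, 25)
        )
        fit = fit_recovery(rec["interval_ms"], rec["fraction"], n_components=1)
        assert fit.taus_ms[0] == pytest.approx(tau_true, rel=0.01)

    def test_drug_introduces_dominant_slow_component(self, wt_params, gs967):
        rec = recovery_protocol(wt_params, gs967)
        fit = fit_recovery(rec["interval_ms"], rec["fraction"], n_components=2)
        assert fit.taus_ms[-1] >= 400.0
        assert fit.amplitude_fractions[-1] > 0.5

    def test_unsorted_intervals_rejected(self, wt_params):
        with pytest.raises(ValueError):
            recovery_protocol(wt_params, intervals_ms=[5.0, 1.0])


class TestSSIProtocol:
    def test_full_availability_at_hyperpolarized_prepulse(self, wt_params):
        ssi = ssi_protocol(wt_params, prepulse_mV=[-120.0, -60.0, -40.0], prepulse_ms=100.0)
        assert ssi["norm_peak"].iloc[0] == pytest.approx(1.0, abs=0.02)
        assert (np.diff(ssi["norm_peak"]) <= 1e-9).all()

    def test_fitted_midpoint_recovers_input_parameter(self, wt_params):
        ssi = ssi_protocol(wt_params, prepulse_ms=100.0)
        fit = fit_boltzmann(ssi["prepulse_mV"], ssi["norm_peak"])
        assert fit.Vhalf_mV == pytest.approx(wt_params.h_inf_Vhalf_mV, abs=0.5)

    def test_persistent_floor_instead_of_zero(self, mutant_params):
        """With P=5% the availability curve floors near the persistent
        fraction (scaled by slow-gate availability) instead of zero.

        Oracle: dense closed-form evaluation of the test-pulse current
        from the gate relaxation formulas, independent of the engine."""
        ssi = ssi_protocol(mutant_params, prepulse_ms=100.0)
        floor = ssi["norm_peak"].iloc[-1]
        assert floor > 0.03  # far from zero

        p = mutant_params

        def closed_form_peak(pA0: float, s0: float) -> float:
            t = np.arange(0.1, 20.0, 0.002)
            mi = float(gating.m_inf(0.0, p))
            tm = float(gating.tau_m(0.0, p))
            m = mi * (1.0 - np.exp(-t / tm))
            hp = float(gating.h_inf_prime(float(gating.h_inf(0.0, p)), p.P_persist))
            th = 1.0 / float(sum(gating.effective_h_rates(0.0, p)))
            h = hp + (pA0 - hp) * np.exp(-t / th)
            si = float(gating.s_inf(0.0, p))
            ts = float(gating.tau_s(0.0, p))
            s = si + (s0 - si) * np.exp(-t / ts)
            return float(np.max(m**3 * h * s))

        def prepulse_state(Vpre: float) -> tuple[float, float]:
            hp = float(gating.h_inf_prime(float(gating.h_inf(Vpre, p)), p.P_persist))
            h0 = float(gating.h_inf_prime(float(gating.h_inf(-90.0, p)), p.P_persist))
            th = 1.0 / float(sum(gating.effective_h_rates(Vpre, p)))
            pA0 = hp + (h0 - hp) * np.exp(-100.0 / th)
            si = float(gating.s_inf(Vpre, p))
            ts = float(gating.tau_s(Vpre, p))
            s0 = si + (float(gating.s_inf(-90.0, p)) - si) * np.exp(-100.0 / ts)
            return pA0, s0

        expected_floor = closed_form_peak(*prepulse_state(-10.0)) / closed_form_peak(
            *prepulse_state(-120.0)
        )
        assert floor == pytest.approx(expected_floor, rel=0.05)

    def test_empty_family_rejected(self, wt_params):
        with pytest.raises(ValueError):
            ssi_protocol(wt_params, prepulse_mV=[])


class TestSlowInactivationOnset:
    def test_availability_declines_with_conditioning_duration(self, wt_params):
        onset = vclamp.slow_inactivation_onset(
            wt_params, durations_ms=[10.0, 100.0, 1000.0, 5000.0]
        )
        assert (np.diff(onset["fraction"]) < 0).all()
        # long conditioning drives availability toward the depolarized
        # slow-gate steady state (near zero)
        assert onset["fraction"].iloc[-1] < 0.2


class TestDrugBlockPattern:
    def test_late_block_exceeds_peak_block_for_persistent_mutants(self, gs967):
        """For every persistent-current mutant the end-pulse current is
        suppressed more strongly than the peak (late-current selectivity)."""
        for P in (0.01, 0.03, 0.05):
            params = GatingParams(P_persist=P)
            proto = default_iv_protocol(step_mV=[0.0])
            before = iv_summary(run_protocol(proto, params, NO_DRUG)).iloc[0]
            after = iv_summary(run_protocol(proto, params, gs967)).iloc[0]
            peak_ratio = after["peak_pA"] / before["peak_pA"]
            end_ratio = after["end_pulse_pA"] / before["end_pulse_pA"]
            assert end_ratio < peak_ratio

    def test_small_drug_effect_on_non_persistent_end_pulse(self, wt_params, gs967):
        """Late current of the fully inactivating channel is already ~0;
        the drug's late-current effect is correspondingly negligible
        relative to the peak current scale."""
        proto = default_iv_protocol(step_mV=[0.0])
        before = iv_summary(run_protocol(proto, wt_params, NO_DRUG)).iloc[0]
        after = iv_summary(run_protocol(proto, wt_params, gs967)).iloc[0]
        change = abs(after["end_pulse_pA"] - before["end_pulse_pA"])
        assert change < 0.05 * abs(before["peak_pA"])
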