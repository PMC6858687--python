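"""Voltage-clamp protocol engine.

Voltages are piecewise constant, so every epoch is propagated
analytically: first-order relaxation for the m and s gates and the
eigen-solution of the three-state fast-inactivation subsystem, evaluated
at the requested sample times.  Derived summaries (IV table, steady-state
inactivation, recovery from inactivation, slow-inactivation onset) are
computed from the simulated traces or directly from the analytic
per-epoch solutions.

Conventions: holding potential −90 mV; peak = signed extremum after a
0.1 ms blanking window at the step onset; end-pulse = mean of the final
2 ms of the step.  The drug is equilibrated at holding (60 s) before
every protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import gating
from .params import NO_DRUG, DrugModel, GatingParams
from .trace import Trace

PEAK_BLANK_MS = 0.1
END_PULSE_WINDOW_MS = 2.0
EQUILIBRATION_MS = 60_000.0


@dataclass(frozen=True)
class Epoch:
    duration_ms: float
    voltage_mV: float

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("epoch duration must be > 0")


@dataclass(frozen=True)
class SweepSpec:
    """One epoch whose voltage or duration is swept across a family."""

    epoch_index: int
    values: tuple[float, ...]
    dimension: str = "voltage"  # "voltage" or "duration"

    def __post_init__(self) -> None:
        if self.dimension not in ("voltage", "duration"):
            raise ValueError("sweep dimension must be 'voltage' or 'duration'")
        if len(self.values) == 0:
            raise ValueError("sweep must list at least one value")


@dataclass(frozen=True)
class VoltageProtocol:
    name: str
    epochs: tuple[Epoch, ...]
    sweep: SweepSpec | None = None
    holding_mV: float = -90.0
    sample_interval_ms: float = 0.02

    def __post_init__(self) -> None:
        if self.sample_interval_ms <= 0:
            raise ValueError("sample_interval_ms must be > 0")
        if self.sweep is not None and not (0 <= self.sweep.epoch_index < len(self.epochs)):
            raise ValueError("sweep epoch index out of range")

    def realize(self, value: float | None = None) -> tuple[Epoch, ...]:
        """Concrete epoch list for one sweep value."""
        if self.sweep is None or value is None:
            return self.epochs
        ep = list(self.epochs)
        old = ep[self.sweep.epoch_index]
        if self.sweep.dimension == "voltage":
            ep[self.sweep.epoch_index] = Epoch(old.duration_ms, value)
        else:
            ep[self.sweep.epoch_index] = Epoch(value, old.voltage_mV)
        return tuple(ep)


class _EpochSolution:
    """Closed-form gating solution within one constant-voltage epoch."""

    def __init__(self, state: gating.ChannelState, V: float, params: GatingParams, drug: DrugModel):
        self.V = float(V)
        self.params = params
        self.m0, self.s0 = state.m, state.s
        self.mi = float(gating.m_inf(V, params))
        self.si = float(gating.s_inf(V, params))
        self.tm = float(gating.tau_m(V, params))
        self.ts = float(gating.tau_s(V, params))
        Q = gating.h_subsystem_matrix(V, params, drug)
        w, P = np.linalg.eig(Q)
        self.w = w
        self.P = P
        self.c = np.linalg.solve(P, state.h_sub.as_vector())

    def gates_at(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = np.asarray(t, dtype=float)
        m = self.mi + (self.m0 - self.mi) * np.exp(-t / self.tm)
        s = self.si + (self.s0 - self.si) * np.exp(-t / self.ts)
        # pA(t) = sum_j P[0,j] c_j exp(w_j t)
        pA = np.real((self.P[0] * self.c) @ np.exp(np.outer(self.w, t)))
        return m, s, pA

    def current_at(self, t: np.ndarray) -> np.ndarray:
        m, s, pA = self.gates_at(t)
        p = self.params
        return p.G_Na_nS * (self.V - p.E_Na_mV) * m**3 * pA * s

    def state_at(self, t: float) -> gating.ChannelState:
        m = self.mi + (self.m0 - self.mi) * np.exp(-t / self.tm)
        s = self.si + (self.s0 - self.si) * np.exp(-t / self.ts)
        pvec = np.real(self.P @ (self.c * np.exp(self.w * t)))
        pvec = np.clip(pvec, 0.0, 1.0)
        return gating.ChannelState(
            m=float(np.clip(m, 0.0, 1.0)),
            s=float(np.clip(s, 0.0, 1.0)),
            h_sub=gating.HSubsystemState.from_vector(pvec),
        )


def equilibrated_state(
    params: GatingParams, drug: DrugModel, holding_mV: float, duration_ms: float = EQUILIBRATION_MS
) -> gating.ChannelState:
    """Drug-free steady state at holding, then ``duration_ms`` of drug exposure."""
    state = gating.steady_state(holding_mV, params, NO_DRUG)
    if drug.concentration_uM > 0:
        state = gating.propagate(state, holding_mV, duration_ms, params, drug)
    return state


def run_protocol(
    protocol: VoltageProtocol,
    params: GatingParams,
    drug: DrugModel = NO_DRUG,
    model_id: str = "model",
) -> list[Trace]:
    """Simulate a protocol; one current trace per sweep value."""
    if len(protocol.epochs) == 0:
        raise ValueError("protocol must contain at least one epoch")
    state0 = equilibrated_state(params, drug, protocol.holding_mV)
    sweep_values: Sequence[float | None]
    sweep_values = protocol.sweep.values if protocol.sweep is not None else [None]

    traces = []
    for value in sweep_values:
        epochs = protocol.realize(value)
        durations = np.array([e.duration_ms for e in epochs])
        starts = np.concatenate([[0.0], np.cumsum(durations)])
        total = starts[-1]
        dt = protocol.sample_interval_ms
        t_all = np.arange(0.0, total + dt / 2, dt)
        t_all = t_all[t_all <= total + 1e-12]
        y_all = np.empty_like(t_all)

        state = state0
        for i, ep in enumerate(epochs):
            sol = _EpochSolution(state, ep.voltage_mV, params, drug)
            lo, hi = starts[i], starts[i + 1]
            last = i == len(epochs) - 1
            mask = (t_all >= lo - 1e-12) & ((t_all < hi - 1e-12) | (last & (t_all <= hi + 1e-12)))
            y_all[mask] = sol.current_at(t_all[mask] - lo)
            state = sol.state_at(ep.duration_ms)

        meta = {
            "protocol": protocol.name,
            "units": "pA",
            "sample_interval_ms": dt,
            "holding_mV": protocol.holding_mV,
            "model_id": model_id,
            "epoch_starts_ms": list(np.round(starts[:-1], 9)),
            "epoch_voltages_mV": [e.voltage_mV for e in epochs],
        }
        if protocol.sweep is not None:
            i_sw = protocol.sweep.epoch_index
            meta["sweep_value"] = value
            meta["sweep_dimension"] = protocol.sweep.dimension
            meta["step_start_ms"] = float(starts[i_sw])
            meta["step_end_ms"] = float(starts[i_sw + 1])
            meta["step_mV"] = epochs[i_sw].voltage_mV
        traces.append(Trace(t_all, y_all, meta))
    return traces


# ---------------------------------------------------------------------------
# Trace measurements
# ---------------------------------------------------------------------------


def measure_peak(trace: Trace, start_ms: float, end_ms: float, blank_ms: float = PEAK_BLANK_MS) -> float:
    """Signed extremum within a window, blanking the first ``blank_ms``.

    The right edge is open so a sample falling exactly on the next epoch
    boundary (already at the post-step voltage) is excluded.
    """
    sub = trace.slice(start_ms + blank_ms, end_ms, right_open=True)
    if len(sub.y) == 0:
        raise ValueError("empty measurement window")
    return float(sub.y[np.argmax(np.abs(sub.y))])


def measure_end_pulse(trace: Trace, end_ms: float, window_ms: float = END_PULSE_WINDOW_MS) -> float:
    """Mean of the final ``window_ms`` before ``end_ms`` (right-open)."""
    sub = trace.slice(end_ms - window_ms, end_ms, right_open=True)
    if len(sub.y) == 0:
        raise ValueError("empty end-pulse window")
    return float(np.mean(sub.y))


def iv_summary(traces: Sequence[Trace]) -> pd.DataFrame:
    """Per-sweep peak and end-pulse current of an IV step family."""
    rows = []
    for tr in traces:
        if "step_start_ms" not in tr.meta:
            raise ValueError("trace lacks step-window metadata; not from a swept protocol")
        lo, hi = tr.meta["step_start_ms"], tr.meta["step_end_ms"]
        if hi - lo < END_PULSE_WINDOW_MS:
            raise ValueError("step shorter than the end-pulse averaging window")
        rows.append(
            {
                "step_mV": tr.meta["step_mV"],
                "peak_pA": measure_peak(tr, lo, hi),
                "end_pulse_pA": measure_end_pulse(tr, hi),
            }
        )
    return pd.DataFrame(rows).sort_values("step_mV", ignore_index=True)


# ---------------------------------------------------------------------------
# Built-in protocol families
# ---------------------------------------------------------------------------


def default_iv_protocol(
    step_mV: Sequence[float] | None = None,
    step_ms: float = 70.0,
    holding_mV: float = -90.0,
    sample_interval_ms: float = 0.02,
) -> VoltageProtocol:
    """IV family: 5 ms at holding, test step, 10 ms tail at holding."""
    if step_mV is None:
        step_mV = np.arange(-80.0, 40.0 + 1e-9, 5.0)
    epochs = (
        Epoch(5.0, holding_mV),
        Epoch(step_ms, 0.0),
        Epoch(10.0, holding_mV),
    )
    return VoltageProtocol(
        name="iv",
        epochs=epochs,
        sweep=SweepSpec(1, tuple(float(v) for v in step_mV)),
        holding_mV=holding_mV,
        sample_interval_ms=sample_interval_ms,
    )


def default_recovery_intervals(n: int = 31) -> np.ndarray:
    """Log-spaced recovery intervals 0.5 ms – 3 s."""
    return np.geomspace(0.5, 3000.0, n)


def _pulse_peak(
    state: gating.ChannelState,
    V: float,
    duration_ms: float,
    params: GatingParams,
    drug: DrugModel,
    dt: float = 0.01,
) -> tuple[float, gating.ChannelState]:
    sol = _EpochSolution(state, V, params, drug)
    t = np.arange(0.0, duration_ms + dt / 2, dt)
    y = sol.current_at(t)
    blank = t >= PEAK_BLANK_MS
    peak = float(y[blank][np.argmax(np.abs(y[blank]))])
    return peak, sol.state_at(duration_ms)


def recovery_protocol(
    params: GatingParams,
    drug: DrugModel = NO_DRUG,
    conditioning_ms: float = 70.0,
    conditioning_mV: float = 0.0,
    recovery_mV: float = -90.0,
    intervals_ms: Sequence[float] | None = None,
    test_mV: float = 0.0,
    test_ms: float = 20.0,
    holding_mV: float = -90.0,
) -> pd.DataFrame:
    """Two-pulse recovery-from-inactivation curve.

    Fractional recovery = test-pulse peak / conditioning-pulse peak for
    each recovery interval at ``recovery_mV``.
    """
    if intervals_ms is None:
        intervals_ms = default_recovery_intervals()
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    if np.any(intervals_ms <= 0):
        raise ValueError("recovery intervals must be positive")
    if np.any(np.diff(intervals_ms) < 0):
        raise ValueError("recovery intervals must be sorted ascending")

    state0 = equilibrated_state(params, drug, holding_mV)
    cond_peak, cond_end = _pulse_peak(state0, conditioning_mV, conditioning_ms, params, drug)
    if abs(cond_peak) < 1e-12:
        raise ValueError("conditioning-pulse peak is zero; cannot normalize recovery")

    rows = []
    for interval in intervals_ms:
        state = gating.propagate(cond_end, recovery_mV, float(interval), params, drug)
        test_peak, _ = _pulse_peak(state, test_mV, test_ms, params, drug)
        rows.append({"interval_ms": float(interval), "fraction": test_peak / cond_peak})
    return pd.DataFrame(rows)


def ssi_protocol(
    params: GatingParams,
    drug: DrugModel = NO_DRUG,
    prepulse_mV: Sequence[float] | None = None,
    prepulse_ms: float = 500.0,
    test_mV: float = 0.0,
    test_ms: float = 20.0,
    holding_mV: float = -90.0,
) -> pd.DataFrame:
    """Steady-state inactivation (availability) curve, normalized to the
    largest test-pulse peak across the prepulse family."""
    if prepulse_mV is None:
        prepulse_mV = np.arange(-120.0, -10.0 + 1e-9, 5.0)
    prepulse_mV = np.asarray(prepulse_mV, dtype=float)
    if len(prepulse_mV) == 0:
        raise ValueError("prepulse family must not be empty")
    if np.any(np.diff(prepulse_mV) < 0):
        raise ValueError("prepulse family must be sorted ascending")

    state0 = equilibrated_state(params, drug, holding_mV)
    peaks = []
    for vp in prepulse_mV:
        state = gating.propagate(state0, float(vp), prepulse_ms, params, drug)
        peak, _ = _pulse_peak(state, test_mV, test_ms, params, drug)
        peaks.append(peak)
    peaks = np.array(peaks)
    norm = peaks[np.argmax(np.abs(peaks))]
    return pd.DataFrame({"prepulse_mV": prepulse_mV, "norm_peak": peaks / norm})


def slow_inactivation_onset(
    params: GatingParams,
    drug: DrugModel = NO_DRUG,
    conditioning_mV: float = 0.0,
    durations_ms: Sequence[float] | None = None,
    gap_ms: float = 20.0,
    gap_mV: float = -90.0,
    test_mV: float = 0.0,
    test_ms: float = 20.0,
    holding_mV: float = -90.0,
) -> pd.DataFrame:
    """Onset of slow inactivation: conditioning of swept duration, a brief
    hyperpolarized gap to let fast inactivation recover, then a test pulse."""
    if durations_ms is None:
        durations_ms = np.geomspace(10.0, 10_000.0, 16)
    state0 = equilibrated_state(params, drug, holding_mV)
    ref_state = gating.propagate(state0, gap_mV, gap_ms, params, drug)
    ref_peak, _ = _pulse_peak(ref_state, test_mV, test_ms, params, drug)
    rows = []
    for dur in np.asarray(durations_ms, dtype=float):
        state = gating.propagate(state0, conditioning_mV, float(dur), params, drug)
        state = gating.propagate(state, gap_mV, gap_ms, params, drug)
        peak, _ = _pulse_peak(state, test_mV, test_ms, params, drug)
        rows.append({"duration_ms": float(dur), "fraction": peak / ref_peak})
    return pd.DataFrame(rows)
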