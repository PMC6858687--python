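"""Na⁺ channel gating core.

The sodium current follows the product form

    I_Na = G_Na · (V − E_Na) · m³ · h · s

with Hodgkin-Huxley activation (m) and slow inactivation (s) gates and an
extended three-state fast-inactivation subsystem

    A  ⇌(β′_h / α′_h)  I  ⇌(λ[drug] / μ)  I_drug

in which the blocker binds exclusively to the fast-inactivated state I.
``h`` in the product form is the occupancy of the available state A.

A mutation-imposed persistent-current fraction ``P_persist`` is encoded by
transforming the two-state rate constants:

    β′_h = (1 − P_persist)·β_h
    α′_h = α_h + P_persist·β_h

which leaves α+β (and hence the fast-inactivation time constant)
unchanged while raising the depolarized steady state of A from ≈0 to
exactly ``P_persist``.

Time propagation at constant voltage is exact: first-order relaxation for
m and s, and the matrix exponential of the 3×3 subsystem generator —
computed by eigen-decomposition, with a scaling-and-squaring fallback for
numerically degenerate spectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm as _expm

from .params import NO_DRUG, DrugModel, GatingParams

logger = logging.getLogger(__name__)

__all__ = [
    "HSubsystemState",
    "ChannelState",
    "boltzmann",
    "m_inf",
    "tau_m",
    "h_inf",
    "tau_h",
    "s_inf",
    "tau_s",
    "standard_h_rates",
    "persistent_transform",
    "h_inf_prime",
    "effective_h_rates",
    "h_subsystem_matrix",
    "h_subsystem_steady_state",
    "steady_state",
    "propagate",
    "sodium_current",
]


def boltzmann(V, Vhalf, k):
    """Two-state Boltzmann steady state 1/(1+exp((V−V½)/k))."""
    return 1.0 / (1.0 + np.exp((np.asarray(V, dtype=float) - Vhalf) / k))


def m_inf(V, p: GatingParams):
    return boltzmann(V, p.m_inf_Vhalf_mV, p.m_inf_k_mV)


def tau_m(V, p: GatingParams):
    V = np.asarray(V, dtype=float)
    return p.tau_m_min_ms + p.tau_m_amp_ms / (
        1.0 + np.exp((V - p.tau_m_Vmid_mV) / p.tau_m_k_mV)
    )


def h_inf(V, p: GatingParams):
    return boltzmann(V, p.h_inf_Vhalf_mV, p.h_inf_k_mV)


def tau_h(V, p: GatingParams):
    """Bell-shaped fast-inactivation time constant (ms)."""
    x = (np.asarray(V, dtype=float) - p.tau_h_Vmid_mV) / p.tau_h_k_mV
    return p.tau_h_min_ms + p.tau_h_amp_ms / (np.exp(x) + np.exp(-x))


def s_inf(V, p: GatingParams):
    return boltzmann(V, p.s_inf_Vhalf_mV, p.s_inf_k_mV)


def tau_s(V, p: GatingParams):
    x = (np.asarray(V, dtype=float) - p.tau_s_Vmid_mV) / p.tau_s_k_mV
    return p.tau_s_min_ms + p.tau_s_amp_ms / (np.exp(x) + np.exp(-x))


def _check_voltage(V) -> None:
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite (got non-finite V)")


def standard_h_rates(V, params: GatingParams):
    """Two-state fast-inactivation rate constants (α_h, β_h) in ms⁻¹.

    α_h = h∞/τ_h (recovery), β_h = (1−h∞)/τ_h (inactivation); α_h is
    additionally multiplied by ``alpha_h_scale`` to model
    recovery-accelerating mutations.
    """
    _check_voltage(V)
    hi = h_inf(V, params)
    th = tau_h(V, params)
    alpha = params.alpha_h_scale * hi / th
    beta = (1.0 - hi) / th
    return alpha, beta


def persistent_transform(alpha_h, beta_h, P_persist):
    """Impose a persistent fraction on two-state inactivation rates.

    Returns (α′_h, β′_h) = (α + P·β, (1−P)·β).  The sum α+β is preserved
    exactly, so the apparent fast-inactivation time constant is untouched.
    """
    alpha_h = np.asarray(alpha_h, dtype=float)
    beta_h = np.asarray(beta_h, dtype=float)
    if np.any(alpha_h < 0) or np.any(beta_h < 0):
        raise ValueError("rate constants must be >= 0")
    P = float(P_persist)
    if not 0.0 <= P <= 1.0:
        raise ValueError("P_persist must lie in [0, 1]")
    return alpha_h + P * beta_h, (1.0 - P) * beta_h


def h_inf_prime(h_inf_value, P_persist):
    """Modified steady-state availability h′∞ = P + (1−P)·h∞."""
    h = np.asarray(h_inf_value, dtype=float)
    P = float(P_persist)
    if np.any(h < 0) or np.any(h > 1):
        raise ValueError("h_inf must lie in [0, 1]")
    if not 0.0 <= P <= 1.0:
        raise ValueError("P_persist must lie in [0, 1]")
    return P + (1.0 - P) * h


def effective_h_rates(V, params: GatingParams):
    """Persistent-transformed rates (α′_h, β′_h) at voltage V."""
    alpha, beta = standard_h_rates(V, params)
    return persistent_transform(alpha, beta, params.P_persist)


@dataclass
class HSubsystemState:
    """Occupancies of the fast-inactivation subsystem (A, I, I_drug)."""

    pA: float
    pI: float
    pIGS: float

    def __post_init__(self) -> None:
        vec = self.as_vector()
        if np.any(vec < -1e-12) or np.any(vec > 1.0 + 1e-12):
            raise ValueError("occupancies must lie in [0, 1]")
        if abs(vec.sum() - 1.0) > 1e-10:
            raise ValueError("occupancies must sum to 1 within 1e-10")

    def as_vector(self) -> np.ndarray:
        return np.array([self.pA, self.pI, self.pIGS], dtype=float)

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "HSubsystemState":
        return cls(float(vec[0]), float(vec[1]), float(vec[2]))


@dataclass
class ChannelState:
    """Full gating state: m, s gates plus the fast-inactivation subsystem."""

    m: float
    s: float
    h_sub: HSubsystemState

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0 or not 0.0 <= self.s <= 1.0:
            raise ValueError("gate variables must lie in [0, 1]")

    @property
    def h(self) -> float:
        """Available fraction of the fast-inactivation subsystem."""
        return self.h_sub.pA


def h_subsystem_matrix(V, params: GatingParams, drug: DrugModel = NO_DRUG) -> np.ndarray:
    """Generator matrix Q (ms⁻¹) of the A ⇌ I ⇌ I_drug chain.

    Column convention: dp/dt = Q·p for p = (pA, pI, pIGS); columns sum to
    zero (probability conservation).  There is no direct A ↔ I_drug edge.
    """
    alpha, beta = effective_h_rates(V, params)
    alpha = float(alpha)
    beta = float(beta)
    kon = drug.kon_per_ms
    koff = drug.koff_per_ms
    return np.array(
        [
            [-beta, alpha, 0.0],
            [beta, -(alpha + kon), koff],
            [0.0, kon, -koff],
        ]
    )


def h_subsystem_steady_state(V, params: GatingParams, drug: DrugModel = NO_DRUG) -> HSubsystemState:
    """Equilibrium occupancies of the chain (detailed balance of a linear chain)."""
    alpha, beta = effective_h_rates(V, params)
    alpha = float(alpha)
    beta = float(beta)
    kon = drug.kon_per_ms
    koff = drug.koff_per_ms
    # Unnormalized equilibrium weights along the chain A — I — I_drug.
    wA = alpha * koff
    wI = beta * koff
    wIGS = beta * kon
    total = wA + wI + wIGS
    if total == 0.0:
        # alpha = beta = 0 cannot happen for positive tau_h; defensive only.
        return HSubsystemState(1.0, 0.0, 0.0)
    return HSubsystemState(wA / total, wI / total, wIGS / total)


def steady_state(V, params: GatingParams, drug: DrugModel = NO_DRUG) -> ChannelState:
    """Full channel steady state at a holding potential."""
    return ChannelState(
        m=float(m_inf(V, params)),
        s=float(s_inf(V, params)),
        h_sub=h_subsystem_steady_state(V, params, drug),
    )


def _propagator(Q: np.ndarray, dt: float) -> np.ndarray:
    """exp(Q·dt) by eigen-decomposition; scaling-and-squaring fallback."""
    try:
        w, P = np.linalg.eig(Q)
        cond = np.linalg.cond(P)
        if not np.isfinite(cond) or cond > 1e10:
            raise np.linalg.LinAlgError(f"ill-conditioned eigenbasis (cond={cond:.2e})")
        T = (P * np.exp(w * dt)) @ np.linalg.inv(P)
        logger.debug("h-subsystem propagator via eigen-decomposition")
        return np.real(T)
    except np.linalg.LinAlgError as exc:
        logger.info("eigen-decomposition degenerate (%s); using scaling-and-squaring", exc)
        return _expm(Q * dt)


def propagate(
    state: ChannelState,
    V: float,
    dt: float,
    params: GatingParams,
    drug: DrugModel = NO_DRUG,
) -> ChannelState:
    """Advance the gating state by ``dt`` ms at constant voltage ``V``.

    m and s relax exponentially toward their steady states; the
    fast-inactivation subsystem advances by the exact matrix exponential
    of its generator.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    _check_voltage(V)
    em = np.exp(-dt / float(tau_m(V, params)))
    es = np.exp(-dt / float(tau_s(V, params)))
    mi = float(m_inf(V, params))
    si = float(s_inf(V, params))
    m_new = mi + (state.m - mi) * em
    s_new = si + (state.s - si) * es

    Q = h_subsystem_matrix(V, params, drug)
    p_new = _propagator(Q, dt) @ state.h_sub.as_vector()
    p_new = np.clip(p_new, 0.0, 1.0)
    return ChannelState(m=m_new, s=s_new, h_sub=HSubsystemState.from_vector(p_new))


def sodium_current(V, state: ChannelState, params: GatingParams):
    """I_Na = G_Na·(V − E_Na)·m³·h·s in pA (inward negative for V < E_Na)."""
    return (
        params.G_Na_nS
        * (np.asarray(V, dtype=float) - params.E_Na_mV)
        * state.m**3
        * state.h
        * state.s
    )
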