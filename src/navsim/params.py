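"""Parameter containers and config (de)serialisation.

All quantities live in a single internal unit system: time in ms, voltage
in mV, current in pA, conductance in nS (voltage-clamp mode) or mS/cm²
(neuron mode), concentration in μM, capacitance in pF.  Field names carry
unit suffixes so that serialized configs are self-describing.  Drug rate
constants are conventionally quoted per second and per μM·s in the
literature; they are converted to per-ms at the module boundary (see
:class:`DrugModel`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import yaml

#: Schema identifiers written into every serialized config.
GATING_SCHEMA = "navsim/gating-params/v1"
DRUG_SCHEMA = "navsim/drug-model/v1"
NEURON_SCHEMA = "navsim/neuron-params/v1"

_VALIDATION_GRID_MV = np.linspace(-120.0, 60.0, 181)


@dataclass
class GatingParams:
    """Voltage-dependent gating parameterization of the Na⁺ conductance.

    Steady states are Boltzmann functions 1/(1+exp((V−V½)/k)); activation
    uses a negative slope factor (m rises with depolarization), the two
    inactivation gates positive slope factors.  Time constants are a
    sigmoid for activation and bell-shaped (1/cosh-like) curves for fast
    and slow inactivation.

    ``P_persist`` is the imposed persistent-current fraction: the modified
    inactivation scheme guarantees a non-inactivating occupancy of exactly
    ``P_persist`` at strongly depolarized voltages.  ``alpha_h_scale``
    multiplies the recovery rate constant α_h and models mutations that
    accelerate recovery from fast inactivation.
    """

    G_Na_nS: float = 50.0
    E_Na_mV: float = 50.0

    m_inf_Vhalf_mV: float = -35.0
    m_inf_k_mV: float = -7.0
    tau_m_min_ms: float = 0.03
    tau_m_amp_ms: float = 0.1
    tau_m_Vmid_mV: float = -30.0
    tau_m_k_mV: float = 10.0

    h_inf_Vhalf_mV: float = -62.0
    h_inf_k_mV: float = 6.0
    tau_h_min_ms: float = 0.35
    tau_h_amp_ms: float = 16.0
    tau_h_Vmid_mV: float = -60.0
    tau_h_k_mV: float = 10.0

    s_inf_Vhalf_mV: float = -55.0
    s_inf_k_mV: float = 8.0
    tau_s_min_ms: float = 500.0
    tau_s_amp_ms: float = 4000.0
    tau_s_Vmid_mV: float = -50.0
    tau_s_k_mV: float = 15.0

    P_persist: float = 0.0
    alpha_h_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("m_inf_k_mV", "h_inf_k_mV", "s_inf_k_mV"):
            if getattr(self, name) == 0:
                raise ValueError(f"{name} must be nonzero")
        if not 0.0 <= self.P_persist <= 1.0:
            raise ValueError("P_persist must lie in [0, 1]")
        if self.G_Na_nS < 0:
            raise ValueError("G_Na_nS must be >= 0")
        if self.alpha_h_scale < 0:
            raise ValueError("alpha_h_scale must be >= 0")
        from . import gating  # deferred: gating imports this module

        for tau in (gating.tau_m, gating.tau_h, gating.tau_s):
            vals = tau(_VALIDATION_GRID_MV, self)
            if not np.all(vals > 0):
                raise ValueError(
                    f"time-constant function {tau.__name__} must be strictly "
                    "positive on [-120, +60] mV"
                )

    def replace(self, **changes: Any) -> "GatingParams":
        return dataclasses.replace(self, **changes)


@dataclass
class DrugModel:
    """Inactivated-state blocker kinetics (GS967-like).

    ``lam_per_uM_s`` and ``mu_per_s`` are the association and dissociation
    rate constants in the units they are quoted in (μM⁻¹ s⁻¹ and s⁻¹);
    the per-ms values used internally are exposed as properties.  Binding
    is voltage independent and strictly inactivated-state selective.
    """

    lam_per_uM_s: float = 10.0
    mu_per_s: float = 1.0
    concentration_uM: float = 0.0

    def __post_init__(self) -> None:
        if self.lam_per_uM_s < 0:
            raise ValueError("association rate must be >= 0")
        if self.mu_per_s <= 0:
            raise ValueError("dissociation rate must be > 0")
        if self.concentration_uM < 0:
            raise ValueError("concentration must be >= 0")

    @property
    def kon_per_ms(self) -> float:
        """Pseudo-first-order binding rate λ·[drug], per ms."""
        return self.lam_per_uM_s * self.concentration_uM * 1e-3

    @property
    def koff_per_ms(self) -> float:
        """Unbinding rate μ, per ms."""
        return self.mu_per_s * 1e-3

    def replace(self, **changes: Any) -> "DrugModel":
        return dataclasses.replace(self, **changes)


#: Drug-free placeholder used as a default throughout.
NO_DRUG = DrugModel(concentration_uM=0.0)


@dataclass
class NeuronParams:
    """Single-compartment cylinder with delayed-rectifier K⁺ and leak.

    Membrane area is the lateral (side-wall) surface π·L·d only, the
    common compartmental-simulator convention.  K⁺ gating is a classic
    n⁴ delayed rectifier with α_n = a·(V−V_a)/(1−exp(−(V−V_a)/k_a)) and
    β_n = b·exp(−(V−V_b)/k_b), all rates in ms⁻¹.
    """

    length_um: float = 25.0
    diameter_um: float = 25.0
    Cm_uF_per_cm2: float = 1.0
    gNa_mS_per_cm2: float = 150.0
    gK_mS_per_cm2: float = 30.0
    gLeak_mS_per_cm2: float = 0.4
    E_Na_mV: float = 50.0
    E_K_mV: float = -85.0
    E_leak_mV: float = -70.0
    V_init_mV: float = -70.0

    n_alpha_rate: float = 0.02
    n_alpha_Vhalf_mV: float = -30.0
    n_alpha_k_mV: float = 10.0
    n_beta_rate: float = 0.25
    n_beta_Vhalf_mV: float = -40.0
    n_beta_k_mV: float = 80.0

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.diameter_um <= 0:
            raise ValueError("geometry must be positive")
        for name in ("gNa_mS_per_cm2", "gK_mS_per_cm2", "gLeak_mS_per_cm2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def area_cm2(self) -> float:
        """Side-wall area π·L·d in cm² (1 μm² = 1e-8 cm²)."""
        return np.pi * self.length_um * self.diameter_um * 1e-8

    @property
    def capacitance_pF(self) -> float:
        return self.Cm_uF_per_cm2 * self.area_cm2 * 1e6

    def replace(self, **changes: Any) -> "NeuronParams":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# Config (de)serialisation: flat documents with a schema tag; unknown fields
# are rejected so silent typos cannot change a simulation.
# ---------------------------------------------------------------------------

_SCHEMAS = {
    GATING_SCHEMA: GatingParams,
    DRUG_SCHEMA: DrugModel,
    NEURON_SCHEMA: NeuronParams,
}
_CLASS_SCHEMAS = {v: k for k, v in _SCHEMAS.items()}


def to_config_dict(params: Any) -> dict[str, Any]:
    """Serialize a parameter dataclass to a flat dict with a schema tag."""
    cls = type(params)
    if cls not in _CLASS_SCHEMAS:
        raise TypeError(f"unknown parameter class {cls.__name__}")
    out: dict[str, Any] = {"schema": _CLASS_SCHEMAS[cls]}
    out.update(dataclasses.asdict(params))
    return out


def from_config_dict(doc: dict[str, Any]) -> Any:
    """Reconstruct a parameter object, rejecting unknown fields."""
    doc = dict(doc)
    schema = doc.pop("schema", None)
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown or missing schema identifier: {schema!r}")
    cls = _SCHEMAS[schema]
    known = {f.name for f in fields(cls)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown fields for {cls.__name__}: {sorted(unknown)}")
    return cls(**doc)


def save_config(params: Any, path: str | Path) -> None:
    path = Path(path)
    doc = to_config_dict(params)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=True))


def load_config(path: str | Path) -> Any:
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return from_config_dict(doc)
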