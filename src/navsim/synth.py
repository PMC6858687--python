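"""Surrogate patch-clamp datasets for exercising the analysis pipeline.

Generates whole-cell-like (HEK) or low-driving-force two-electrode
voltage-clamp-like (oocyte) cohorts: per-cell parameter variability
(lognormal draws for positive scale factors, normal draws for voltage
shifts), additive white Gaussian recording noise, and mutant effects
expressed along the axes the biology exhibits — a rightward shift of the
fast-inactivation midpoint, accelerated recovery from inactivation, an
increased persistent-current fraction, and reduced functional
expression.  Every generated cell carries its ground-truth parameters so
that fits can be scored against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import gating, vclamp
from .params import NO_DRUG, DrugModel, GatingParams
from .trace import Trace, write_trace

#: SSI prepulse used in the synthetic battery: long enough for the fast
#: gate to equilibrate (≳20 τ_h everywhere) but short enough to leave the
#: slow gate nearly untouched, so fitted midpoints report the fast gate.
SSI_PREPULSE_MS = 100.0

#: Recovery intervals for the synthetic battery: a log grid from 0.2 ms
#: (resolving sub-millisecond recovery of strongly accelerated mutants)
#: to 3 s (covering the slow drug-bound component).
RECOVERY_INTERVALS_MS = np.geomspace(0.2, 3000.0, 36)


@dataclass(frozen=True)
class MutantSpec:
    """Effect axes of an inactivation-impaired (or low-expression) variant."""

    label: str
    dVhalf_inact_mV: float = 0.0
    recovery_speed_factor: float = 1.0
    P_persist: float = 0.0
    expression_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.recovery_speed_factor < 0 or self.expression_factor < 0:
            raise ValueError("scale factors must be >= 0")
        if not 0.0 <= self.P_persist <= 1.0:
            raise ValueError("P_persist must lie in [0, 1]")


WT_SPEC = MutantSpec("WT")

#: Presets spanning the qualitative mutant classes: three increasingly
#: severe inactivation-impaired variants, one pure persistent-current
#: variant and one low-expression variant.
PRESETS: dict[str, MutantSpec] = {
    "wt": WT_SPEC,
    "inact-mild": MutantSpec("inact-mild", 3.0, 1.5, 0.01),
    "inact-moderate": MutantSpec("inact-moderate", 5.0, 2.0, 0.03),
    "inact-severe": MutantSpec("inact-severe", 8.0, 3.0, 0.05),
    "persistent-only": MutantSpec("persistent-only", 0.0, 1.0, 0.05),
    "low-expression": MutantSpec("low-expression", expression_factor=0.05),
}


def apply_mutant(base: GatingParams, spec: MutantSpec) -> GatingParams:
    """Perturb a channel parameterization along the mutant axes."""
    return base.replace(
        h_inf_Vhalf_mV=base.h_inf_Vhalf_mV + spec.dVhalf_inact_mV,
        alpha_h_scale=base.alpha_h_scale * spec.recovery_speed_factor,
        P_persist=spec.P_persist,
        G_Na_nS=base.G_Na_nS * spec.expression_factor,
    )


def effective_inactivation_vhalf(params: GatingParams) -> float:
    """Midpoint of the steady-state availability curve.

    Scaling α_h by f shifts the apparent midpoint to V½ + k·ln f (the
    voltage where the scaled h∞ crosses 1/2); the persistent floor does
    not move the midpoint because h′∞ is affine in h∞.
    """
    return params.h_inf_Vhalf_mV + params.h_inf_k_mV * np.log(params.alpha_h_scale)


def recovery_tau_ms(params: GatingParams, V_mV: float = -90.0) -> float:
    """Drug-free recovery time constant 1/(α′+β′) at the recovery voltage."""
    alpha, beta = gating.effective_h_rates(V_mV, params)
    return float(1.0 / (alpha + beta))


@dataclass
class CohortConfig:
    """Cohort-level generation settings.

    ``mode`` tags the emulated recording configuration: ``whole-cell``
    (physiological Na⁺ gradient) or ``tevc`` (low-Na⁺ bath; the reversal
    potential drops to +10 mV, shrinking the driving force as in oocyte
    recordings).  All coefficients of variation apply per cell.
    """

    n_cells: int = 10
    capacitance_mean_pF: float = 15.0
    capacitance_sd_pF: float = 4.0
    cv_gna: float = 0.3
    cv_recovery: float = 0.10
    cv_persist: float = 0.10
    sd_dvhalf_mV: float = 1.0
    noise_sd_pA: float = 5.0
    seed: int = 0
    mode: str = "whole-cell"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("capacitance_sd_pF", "cv_gna", "cv_recovery", "cv_persist",
                     "sd_dvhalf_mV", "noise_sd_pA"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mode not in ("whole-cell", "tevc"):
            raise ValueError("mode must be 'whole-cell' or 'tevc'")


TEVC_E_NA_MV = 10.0


@dataclass
class CellData:
    """All simulated recordings of one synthetic cell plus ground truth."""

    cell_id: str
    params: GatingParams
    capacitance_pF: float
    iv_traces: list[Trace] = field(default_factory=list)
    ssi: pd.DataFrame | None = None
    recovery: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)


def _add_noise(trace: Trace, sd: float, rng: np.random.Generator) -> Trace:
    if sd == 0:
        return trace
    return Trace(trace.t, trace.y + rng.normal(0.0, sd, size=trace.y.shape), dict(trace.meta))


def generate_cell(
    base: GatingParams,
    mutant: MutantSpec = WT_SPEC,
    drug: DrugModel = NO_DRUG,
    protocols: Sequence[str] = ("iv", "ssi", "recovery"),
    noise_sd_pA: float = 5.0,
    seed: int = 0,
    cell_id: str = "cell",
    capacitance_pF: float = 15.0,
) -> CellData:
    """Simulate one cell's protocol battery with additive Gaussian noise.

    The returned truth dict records every effective parameter needed to
    score fits against the generator.
    """
    rng = np.random.default_rng(seed)
    params = apply_mutant(base, mutant)
    cell = CellData(
        cell_id=cell_id,
        params=params,
        capacitance_pF=capacitance_pF,
        truth={
            "cell_id": cell_id,
            "label": mutant.label,
            "G_Na_nS": params.G_Na_nS,
            "capacitance_pF": capacitance_pF,
            "P_persist": params.P_persist,
            "Vhalf_inact_mV": effective_inactivation_vhalf(params),
            "recovery_tau_ms": recovery_tau_ms(params),
            "concentration_uM": drug.concentration_uM,
            "seed": seed,
        },
    )
    if "iv" in protocols:
        traces = vclamp.run_protocol(vclamp.default_iv_protocol(), params, drug, model_id=cell_id)
        cell.iv_traces = [_add_noise(tr, noise_sd_pA, rng) for tr in traces]
    if "ssi" in protocols:
        ssi = vclamp.ssi_protocol(params, drug, prepulse_ms=SSI_PREPULSE_MS)
        # peak-measurement noise scales as noise/|reference peak|
        ref = abs(_reference_peak(params, drug))
        noisy = ssi["norm_peak"] + rng.normal(0.0, noise_sd_pA / max(ref, 1e-9), len(ssi))
        cell.ssi = pd.DataFrame({"prepulse_mV": ssi["prepulse_mV"], "norm_peak": noisy})
    if "recovery" in protocols:
        rec = vclamp.recovery_protocol(params, drug, intervals_ms=RECOVERY_INTERVALS_MS)
        ref = abs(_reference_peak(params, drug))
        noisy = rec["fraction"] + rng.normal(0.0, noise_sd_pA / max(ref, 1e-9), len(rec))
        cell.recovery = pd.DataFrame({"interval_ms": rec["interval_ms"], "fraction": noisy})
    return cell


def _reference_peak(params: GatingParams, drug: DrugModel) -> float:
    """Peak test-pulse current from holding; used to scale normalized noise."""
    state = vclamp.equilibrated_state(params, drug, -90.0)
    peak, _ = vclamp._pulse_peak(state, 0.0, 20.0, params, drug)
    return peak


def generate_cohort(
    config: CohortConfig,
    wt: GatingParams | None = None,
    mutants: Sequence[MutantSpec] = (WT_SPEC,),
    drug: DrugModel = NO_DRUG,
    protocols: Sequence[str] = ("iv", "ssi", "recovery"),
) -> tuple[list[CellData], pd.DataFrame]:
    """Generate ``config.n_cells`` cells per mutant group.

    Per-cell draws: G_Na and the recovery-speed and persistent-current
    factors lognormal with the configured CVs; the inactivation-midpoint
    jitter normal; capacitance normal (clipped positive).  Returns the
    cells and a tidy truth table (one row per cell).
    """
    if wt is None:
        wt = GatingParams()
    if config.mode == "tevc":
        wt = wt.replace(E_Na_mV=TEVC_E_NA_MV)
    rng = np.random.default_rng(config.seed)

    def lognormal_factor(cv: float) -> float:
        if cv == 0:
            return 1.0
        sigma = np.sqrt(np.log(1.0 + cv**2))
        return float(rng.lognormal(-0.5 * sigma**2, sigma))  # mean 1

    cells: list[CellData] = []
    rows = []
    for spec in mutants:
        for i in range(config.n_cells):
            cell_id = f"{spec.label}-{i:03d}"
            jittered = MutantSpec(
                label=spec.label,
                dVhalf_inact_mV=spec.dVhalf_inact_mV
                + (rng.normal(0.0, config.sd_dvhalf_mV) if config.sd_dvhalf_mV else 0.0),
                recovery_speed_factor=spec.recovery_speed_factor
                * lognormal_factor(config.cv_recovery),
                P_persist=min(spec.P_persist * lognormal_factor(config.cv_persist), 1.0),
                expression_factor=spec.expression_factor * lognormal_factor(config.cv_gna),
            )
            cap = max(
                float(rng.normal(config.capacitance_mean_pF, config.capacitance_sd_pF)), 1.0
            )
            cell_seed = int(rng.integers(0, 2**31 - 1))
            cell = generate_cell(
                wt,
                jittered,
                drug,
                protocols=protocols,
                noise_sd_pA=config.noise_sd_pA,
                seed=cell_seed,
                cell_id=cell_id,
                capacitance_pF=cap,
            )
            cells.append(cell)
            rows.append(cell.truth)
    return cells, pd.DataFrame(rows)


def write_cohort(cells: list[CellData], truth: pd.DataFrame, out_dir: str | Path) -> None:
    """Lay a cohort out on disk: one directory per cell with trace CSVs,
    SSI/recovery curve CSVs, and a top-level truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth.to_csv(out_dir / "truth.csv", index=False)
    for cell in cells:
        cdir = out_dir / cell.cell_id
        cdir.mkdir(exist_ok=True)
        for k, tr in enumerate(cell.iv_traces):
            write_trace(tr, cdir / f"iv_{k:02d}.csv")
        if cell.ssi is not None:
            cell.ssi.to_csv(cdir / "ssi.csv", index=False)
        if cell.recovery is not None:
            cell.recovery.to_csv(cdir / "recovery.csv", index=False)
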