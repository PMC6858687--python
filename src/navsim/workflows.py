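"""End-to-end condition-grid workflows with run manifests.

Two canned studies mirror the modelling questions the package exists
for: a voltage-clamp grid and a firing grid, each over the four
conditions {persistent fraction 0, 5%} × {blocker 0, 5 μM}.  Every run
writes a ``manifest.json`` recording the config hash, package version,
seeds, timestamps, unit conversions and every output file, so a run can
be reproduced bit-identically from its config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__, fitting, neuron, vclamp
from .params import DrugModel, GatingParams, NeuronParams

REQUIRED_UNITS = {
    "time": "ms",
    "voltage": "mV",
    "current": "pA",
    "concentration": "uM",
}

#: Conversions applied at the config boundary (drug rates are quoted in
#: per-second units in the literature and used per-ms internally).
UNIT_CONVERSIONS = [
    "lambda: uM^-1 s^-1 -> uM^-1 ms^-1 (x 1e-3)",
    "mu: s^-1 -> ms^-1 (x 1e-3)",
]


def default_grid_config() -> dict[str, Any]:
    return {
        "units": dict(REQUIRED_UNITS),
        "p_persist": [0.0, 0.05],
        "gs967_uM": [0.0, 5.0],
        "lambda_per_uM_s": 10.0,
        "mu_per_s": 1.0,
        "holding_mV": -90.0,
        "iv_step_mV": list(np.arange(-80.0, 40.0 + 1e-9, 5.0)),
        "amplitudes_pA": list(np.arange(10.0, 350.0 + 1e-9, 10.0)),
        "duration_ms": 400.0,
    }


def _validate_units(config: dict[str, Any]) -> None:
    units = config.get("units")
    if not isinstance(units, dict):
        raise ValueError("config must contain a 'units' block")
    missing = set(REQUIRED_UNITS) - set(units)
    if missing:
        raise ValueError(f"units block missing entries: {sorted(missing)}")
    wrong = {k: units[k] for k in REQUIRED_UNITS if units[k] != REQUIRED_UNITS[k]}
    if wrong:
        raise ValueError(f"unsupported units (internal system is {REQUIRED_UNITS}): {wrong}")


def config_hash(config: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seeds: list[int]
    created_utc: str
    outputs: list[str] = field(default_factory=list)
    unit_conversions: list[str] = field(default_factory=lambda: list(UNIT_CONVERSIONS))

    def write(self, out_dir: Path) -> Path:
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path


def _conditions(config: dict[str, Any]) -> list[dict[str, float]]:
    return [
        {"p_persist": float(p), "gs967_uM": float(c)}
        for p in config["p_persist"]
        for c in config["gs967_uM"]
    ]


def _condition_name(cond: dict[str, float]) -> str:
    return f"p{cond['p_persist']:g}_gs{cond['gs967_uM']:g}"


def run_vclamp_grid(
    config: dict[str, Any],
    out_dir: str | Path,
    write_traces: bool = False,
) -> RunManifest:
    """IV and recovery outputs for every condition, plus a combined summary.

    Per condition: ``iv_summary.csv`` (step, peak, end-pulse),
    ``recovery.csv`` (interval, fraction) and its exponential fit; the
    combined ``summary.csv`` adds the end-pulse/peak drug-effect view.
    """
    _validate_units(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config_hash(config),
        package_version=__version__,
        seeds=[],
        created_utc=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    )
    base = GatingParams()
    summary_rows = []
    for cond in _conditions(config):
        name = _condition_name(cond)
        cdir = out_dir / name
        cdir.mkdir(exist_ok=True)
        params = base.replace(P_persist=cond["p_persist"])
        drug = DrugModel(
            lam_per_uM_s=config["lambda_per_uM_s"],
            mu_per_s=config["mu_per_s"],
            concentration_uM=cond["gs967_uM"],
        )
        protocol = vclamp.default_iv_protocol(step_mV=config["iv_step_mV"])
        traces = vclamp.run_protocol(protocol, params, drug, model_id=name)
        iv = vclamp.iv_summary(traces)
        iv.to_csv(cdir / "iv_summary.csv", index=False)
        manifest.outputs.append(str(cdir / "iv_summary.csv"))
        if write_traces:
            from .trace import write_trace

            for k, tr in enumerate(traces):
                write_trace(tr, cdir / f"iv_{k:02d}.csv")
                manifest.outputs.append(str(cdir / f"iv_{k:02d}.csv"))

        rec = vclamp.recovery_protocol(params, drug)
        rec.to_csv(cdir / "recovery.csv", index=False)
        manifest.outputs.append(str(cdir / "recovery.csv"))
        fit = fitting.fit_recovery(rec["interval_ms"], rec["fraction"])

        at0 = iv.loc[(iv["step_mV"] - 0.0).abs().idxmin()]
        summary_rows.append(
            {
                "condition": name,
                "p_persist": cond["p_persist"],
                "gs967_uM": cond["gs967_uM"],
                "peak_at_0mV_pA": at0["peak_pA"],
                "end_pulse_at_0mV_pA": at0["end_pulse_pA"],
                "recovery_components": fit.n_components,
                "recovery_tau_fast_ms": fit.taus_ms[0],
                "recovery_tau_slow_ms": fit.taus_ms[-1],
                "recovery_slow_fraction": fit.amplitude_fractions[-1],
            }
        )
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out_dir / "summary.csv", index=False, float_format="%.10g")
    manifest.outputs.append(str(out_dir / "summary.csv"))
    manifest.write(out_dir)
    return manifest


def run_firing_grid(
    config: dict[str, Any],
    out_dir: str | Path,
) -> RunManifest:
    """Rheobase, sustained-firing threshold and the integrated-K⁺-charge
    curve for every condition; one table row per injection amplitude."""
    _validate_units(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config_hash(config),
        package_version=__version__,
        seeds=[],
        created_utc=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    )
    base = GatingParams()
    cell = NeuronParams()
    schedule = neuron.InjectionSchedule(
        amplitudes_pA=np.asarray(config["amplitudes_pA"], dtype=float),
        duration_ms=float(config["duration_ms"]),
    )
    threshold_rows = []
    tables = []
    for cond in _conditions(config):
        name = _condition_name(cond)
        params = base.replace(P_persist=cond["p_persist"])
        drug = DrugModel(
            lam_per_uM_s=config["lambda_per_uM_s"],
            mu_per_s=config["mu_per_s"],
            concentration_uM=cond["gs967_uM"],
        )
        scan = neuron.rheobase_scan(cell, params, drug, schedule)
        table = scan["table"].copy()
        table.insert(0, "condition", name)
        tables.append(table)
        threshold_rows.append(
            {
                "condition": name,
                "p_persist": cond["p_persist"],
                "gs967_uM": cond["gs967_uM"],
                "rheobase_pA": scan["rheobase_pA"]
                if scan["rheobase_pA"] is not None
                else "not reached",
                "sustained_threshold_pA": scan["sustained_threshold_pA"]
                if scan["sustained_threshold_pA"] is not None
                else "not reached",
            }
        )
    qk = pd.concat(tables, ignore_index=True)
    qk.to_csv(out_dir / "qk_table.csv", index=False, float_format="%.10g")
    pd.DataFrame(threshold_rows).to_csv(out_dir / "thresholds.csv", index=False)
    manifest.outputs.extend([str(out_dir / "qk_table.csv"), str(out_dir / "thresholds.csv")])
    manifest.write(out_dir)
    return manifest
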