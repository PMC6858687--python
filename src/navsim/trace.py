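"""Uniformly sampled time-series container and its on-disk format.

Traces are written as two-column CSV (``time_ms,value``) preceded by
``#``-prefixed comment lines carrying the metadata, together with a JSON
sidecar holding the same metadata for machine consumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

_UNIFORMITY_TOL_MS = 1e-9


@dataclass
class Trace:
    """A uniformly sampled signal (current in pA or voltage in mV)."""

    t: np.ndarray
    y: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("t must be strictly increasing")
            if np.ptp(dt) > _UNIFORMITY_TOL_MS:
                raise ValueError("t must be uniformly sampled within 1e-9 ms")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) >= 2 else float("nan")

    def slice(self, t0: float, t1: float, right_open: bool = False) -> "Trace":
        """Sub-trace with t0 <= t <= t1 (or t < t1 when ``right_open``)."""
        if right_open:
            mask = (self.t >= t0 - 1e-12) & (self.t < t1 - 1e-12)
        else:
            mask = (self.t >= t0 - 1e-12) & (self.t <= t1 + 1e-12)
        return Trace(self.t[mask], self.y[mask], dict(self.meta))


def write_trace(trace: Trace, csv_path: str | Path) -> Path:
    """Write a trace as commented CSV plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    lines = [f"# {k}: {json.dumps(v)}" for k, v in sorted(trace.meta.items())]
    lines.append("time_ms,value")
    lines.extend(f"{t:.9g},{y:.9g}" for t, y in zip(trace.t, trace.y))
    csv_path.write_text("\n".join(lines) + "\n")
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps(trace.meta, indent=2, sort_keys=True, default=str))
    return sidecar


def read_trace(csv_path: str | Path) -> Trace:
    csv_path = Path(csv_path)
    meta: dict[str, Any] = {}
    sidecar = csv_path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    ts: list[float] = []
    ys: list[float] = []
    for line in csv_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("time_ms"):
            if line.startswith("#") and ":" in line and not sidecar.exists():
                key, _, raw = line[1:].partition(":")
                try:
                    meta[key.strip()] = json.loads(raw.strip())
                except json.JSONDecodeError:
                    meta[key.strip()] = raw.strip()
            continue
        a, _, b = line.partition(",")
        ts.append(float(a))
        ys.append(float(b))
    return Trace(np.array(ts), np.array(ys), meta)
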