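"""Delimited-text I/O for traces, burst tables and titrations.

All tabular files are plain CSV with ``#`` header comments carrying units
and provenance (seed, package version); stopped-flow traces get a YAML
sidecar with their generation/acquisition metadata.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding import TitrationSeries
from .kinetics import KineticTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_titration",
    "read_titration",
]


def write_trace(trace: KineticTrace, path: str | Path) -> None:
    """Write a trace as two-column text plus a ``<path>.meta.yaml`` sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# time_s,signal\n")
        np.savetxt(fh, np.column_stack([trace.time, trace.signal]),
                   delimiter=",", fmt="%.9g")
    meta = {"ntr_conc_M": None if np.isnan(trace.ntr_conc) else float(trace.ntr_conc),
            "kind": trace.kind, **{k: _plain(v) for k, v in trace.meta.items()}}
    path.with_suffix(path.suffix + ".meta.yaml").write_text(yaml.safe_dump(meta))


def _plain(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def read_trace(path: str | Path) -> KineticTrace:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", comments="#")
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    meta = yaml.safe_load(sidecar.read_text()) if sidecar.exists() else {}
    conc = meta.pop("ntr_conc_M", None) if meta else None
    kind = meta.pop("kind", "association") if meta else "association"
    return KineticTrace(time=data[:, 0], signal=data[:, 1],
                        ntr_conc=float("nan") if conc is None else conc,
                        kind=kind, meta=meta or {})


def write_titration(series: TitrationSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# conc_M: molar; fraction_bound: dimensionless; n: bursts\n")
        series.to_dataframe().to_csv(fh, index=False)


def read_titration(path: str | Path) -> TitrationSeries:
    return TitrationSeries.from_csv(path)
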