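"""File formats for traces and subvolume series.

Traces are CSV with header columns ``time_s, dopl_nm`` plus an optional
JSON sidecar (``<stem>.meta.json``) carrying the sampling rate, stimulus
onsets and free-form metadata; without a sidecar the rate is inferred
from the time grid.  Subvolume series are long-format CSV with one row
per (timepoint, A-scan).  Round trips are lossless at double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import ORGTrace
from .phase import ConeSubvolumeSeries

__all__ = [
    "read_trace",
    "write_trace",
    "read_subvolume_series",
    "write_subvolume_series",
    "sidecar_path",
]

_TRACE_COLUMNS = ("time_s", "dopl_nm")
_SUBVOL_COLUMNS = (
    "timepoint", "a_scan", "isos_re", "isos_im", "cost_re", "cost_im"
)


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".meta.json")


def write_trace(trace: ORGTrace, path: str | Path) -> None:
    """Write a trace as CSV plus a JSON sidecar with fs/onsets/meta."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.t, "dopl_nm": trace.dopl})
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "fs_hz": trace.fs,
        "stimulus_onsets_s": list(trace.stimulus_onsets),
        "meta": _jsonable(trace.meta),
    }
    sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_trace(path: str | Path) -> ORGTrace:
    """Read a trace CSV (and its sidecar, if present).

    Raises on a missing column or a non-uniform time grid, naming the
    offending column/index.  NaN samples are preserved and flagged in
    ``meta['nan_samples']``.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} is missing column(s) {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    dopl = df["dopl_nm"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"trace file {path} has fewer than 2 samples")
    if not np.all(np.isfinite(t)):
        raise ValueError(f"trace file {path} has non-finite times")
    sc = sidecar_path(path)
    if sc.exists():
        info = json.loads(sc.read_text())
        fs = float(info["fs_hz"])
        onsets = tuple(info.get("stimulus_onsets_s", ()))
        meta = dict(info.get("meta", {}))
    else:
        fs = 1.0 / float(np.median(np.diff(t)))
        onsets = ()
        meta = {}
    dt = np.diff(t)
    bad = np.flatnonzero(np.abs(dt - 1.0 / fs) > 1e-9)
    if bad.size:
        raise ValueError(
            f"trace file {path}: time grid not uniform at index {bad[0] + 1}"
        )
    nan_idx = np.flatnonzero(~np.isfinite(dopl))
    if nan_idx.size:
        meta = {**meta, "nan_samples": nan_idx.tolist()}
    return ORGTrace(t=t, dopl=dopl, fs=fs, stimulus_onsets=onsets, meta=meta)


def write_subvolume_series(series: ConeSubvolumeSeries, path: str | Path) -> None:
    """Write a complex subvolume series as long-format CSV plus sidecar."""
    path = Path(path)
    n_t, n_a = series.isos.shape
    tp, a = np.meshgrid(np.arange(n_t), np.arange(n_a), indexing="ij")
    df = pd.DataFrame({
        "timepoint": tp.ravel(),
        "a_scan": a.ravel(),
        "isos_re": series.isos.real.ravel(),
        "isos_im": series.isos.imag.ravel(),
        "cost_re": series.cost.real.ravel(),
        "cost_im": series.cost.imag.ravel(),
    })
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "fs_hz": series.fs,
        "wavelength_nm": series.wavelength_nm,
        "stimulus_onsets_s": list(series.stimulus_onsets),
        "meta": _jsonable(series.meta),
    }
    sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_subvolume_series(path: str | Path) -> ConeSubvolumeSeries:
    """Read a long-format subvolume CSV written by write_subvolume_series."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _SUBVOL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subvolume file {path} is missing column(s) {missing}")
    n_t = int(df["timepoint"].max()) + 1
    n_a = int(df["a_scan"].max()) + 1
    if len(df) != n_t * n_a:
        raise ValueError(f"subvolume file {path} is not a complete grid")
    df = df.sort_values(["timepoint", "a_scan"])
    isos = (df["isos_re"].to_numpy() + 1j * df["isos_im"].to_numpy()).reshape(n_t, n_a)
    cost = (df["cost_re"].to_numpy() + 1j * df["cost_im"].to_numpy()).reshape(n_t, n_a)
    sc = sidecar_path(path)
    if not sc.exists():
        raise ValueError(f"subvolume file {path} requires sidecar {sc} (fs unknown)")
    info = json.loads(sc.read_text())
    return ConeSubvolumeSeries(
        isos=isos,
        cost=cost,
        fs=float(info["fs_hz"]),
        wavelength_nm=float(info.get("wavelength_nm", 850.0)),
        stimulus_onsets=tuple(info.get("stimulus_onsets_s", ())),
        meta=dict(info.get("meta", {})),
    )


def _jsonable(obj):
    """Best-effort conversion of metadata to JSON-serializable types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
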