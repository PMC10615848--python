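"""Reading and writing traces, rasters, event tables and configurations.

Delimited text is the interchange default (two-column time/value for
traces, CSV for event tables, edge lists for connectivity); HDF5 (h5py)
holds full simulation results, with rasters stored as ragged spike-time
arrays.
"""

from __future__ import annotations

from dataclasses import asdict, is_dataclass
from pathlib import Path

import h5py
import numpy as np
import yaml

from .ephys import Trace
from .observables import SpikeRaster

__all__ = [
    "write_trace_text",
    "read_trace_text",
    "write_trace_h5",
    "read_trace_h5",
    "write_raster_h5",
    "read_raster_h5",
    "write_result_h5",
    "config_to_dict",
    "save_config",
    "load_config",
]


def write_trace_text(path, trace: Trace, header: bool = True) -> None:
    """Two-column delimited text: time_s <TAB> value."""
    data = np.column_stack([trace.time(), trace.samples])
    hdr = f"time_s\t{trace.units or 'value'}" if header else ""
    np.savetxt(path, data, delimiter="\t", header=hdr, comments="")


def read_trace_text(path, units: str = "") -> Trace:
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    t, x = data[:, 0], data[:, 1]
    rate = 1.0 / np.median(np.diff(t))
    return Trace(x, rate=float(rate), units=units, t0=float(t[0]))


def write_trace_h5(path, trace: Trace, name: str = "trace") -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("samples", data=trace.samples)
        g.attrs["rate"] = trace.rate
        g.attrs["units"] = trace.units
        g.attrs["t0"] = trace.t0


def read_trace_h5(path, name: str = "trace") -> Trace:
    with h5py.File(path, "r") as f:
        g = f[name]
        return Trace(
            g["samples"][...],
            rate=float(g.attrs["rate"]),
            units=str(g.attrs["units"]),
            t0=float(g.attrs["t0"]),
        )


def write_raster_h5(path, raster: SpikeRaster, name: str = "raster") -> None:
    """Raster as ragged spike-time arrays (variable-length float64)."""
    vlen = h5py.vlen_dtype(np.float64)
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        ds = g.create_dataset("spike_times", (raster.n_cells,), dtype=vlen)
        for i, s in enumerate(raster.spike_times):
            ds[i] = s
        g.attrs["duration"] = raster.duration
        if raster.cell_labels is not None:
            g.create_dataset("is_interneuron", data=raster.cell_labels.astype(np.uint8))


def read_raster_h5(path, name: str = "raster") -> SpikeRaster:
    with h5py.File(path, "r") as f:
        g = f[name]
        trains = [np.asarray(s, dtype=float) for s in g["spike_times"][...]]
        labels = (
            g["is_interneuron"][...].astype(bool) if "is_interneuron" in g else None
        )
        return SpikeRaster(trains, float(g.attrs["duration"]), labels)


def write_result_h5(path, result) -> None:
    """Persist a SimulationResult: raster, tonic trace, f_m, optional LFP."""
    write_raster_h5(path, result.raster)
    with h5py.File(path, "a") as f:
        for name in ("t_ms", "g_tonic", "gaba_e", "f_m"):
            if name in f:
                del f[name]
            f.create_dataset(name, data=getattr(result, name))
        if result.lfp is not None:
            if "lfp" in f:
                del f["lfp"]
            f.create_dataset("lfp", data=result.lfp)
        f.attrs["seed"] = result.seed
        f.attrs["config_yaml"] = yaml.safe_dump(config_to_dict(result.config))


def config_to_dict(config) -> dict:
    """Recursively convert a (nested) dataclass configuration to plain types."""

    def convert(obj):
        if is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return convert(config)


def save_config(path, config) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path) -> dict:
    """Load a YAML configuration into a plain nested dict."""
    return yaml.safe_load(Path(path).read_text())
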