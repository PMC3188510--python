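"""Readers/writers for simulation artifacts.

HDF5 is the canonical container for simulation results and signal series
(ragged spike data as parallel arrays, traces as datasets, provenance as
attributes); CSV is available for flat exports (spike rasters, scalar
series); JSON for reports and manifests.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .config import spec_from_dict, spec_to_dict
from .inputs import Stimulus
from .series import SignalSeries
from .simulate import SimulationResult

__all__ = [
    "write_result", "read_result",
    "write_series", "read_series",
    "write_connectivity", "read_connectivity",
    "raster_to_csv", "raster_from_csv",
    "write_json",
]

_SCHEMA = 1


class IOError_(RuntimeError):
    pass


def write_result(result: SimulationResult, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = _SCHEMA
        f.attrs["kind"] = "SimulationResult"
        for a in ("dt", "duration_ms", "warmup_ms", "seed", "spec_hash",
                  "wiring_hash", "gamma"):
            f.attrs[a] = getattr(result, a)
        f.attrs["stimulus"] = json.dumps({
            "contrast": result.stimulus.contrast,
            "orientation": result.stimulus.orientation,
            "flashed": result.stimulus.flashed,
            "on_ms": result.stimulus.on_ms, "off_ms": result.stimulus.off_ms})
        if result.spec is not None:
            f.attrs["spec_yaml"] = yaml.safe_dump(spec_to_dict(result.spec))
        g = f.create_group("spikes")
        g.create_dataset("ids", data=result.spike_ids)
        g.create_dataset("times", data=result.spike_times)
        g = f.create_group("layout")
        g.create_dataset("angles", data=result.angles)
        g.attrs["offsets"] = json.dumps({f"{l}:{k}": int(v)
                                         for (l, k), v in result.offsets.items()})
        g.attrs["sizes"] = json.dumps({f"{l}:{k}": int(v)
                                       for (l, k), v in result.sizes.items()})
        g = f.create_group("traces")
        for name, series in result.traces.items():
            d = g.create_dataset(name, data=series.samples)
            d.attrs["fs_hz"] = series.fs_hz
            d.attrs["units"] = series.units
            d.attrs["meta"] = json.dumps(series.meta, default=str)
        f.attrs["chi"] = json.dumps(result.chi)
        f.attrs["chi_components"] = json.dumps(result.chi_components)
        if result.input_share is not None:
            g = f.create_group("input_share")
            for k, v in result.input_share.items():
                g.create_dataset(k, data=v)
        if result.mean_exc_conductance is not None:
            f.create_dataset("mean_exc_conductance",
                             data=result.mean_exc_conductance)


def read_result(path: str | Path) -> SimulationResult:
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("kind") != "SimulationResult":
                raise IOError_(f"{path}: not a SimulationResult file")
            if int(f.attrs.get("schema", -1)) != _SCHEMA:
                raise IOError_(
                    f"{path}: schema version {f.attrs.get('schema')} unsupported "
                    f"(expected {_SCHEMA})")
            offsets = {tuple(k.split(":")): v for k, v in
                       json.loads(f["layout"].attrs["offsets"]).items()}
            sizes = {tuple(k.split(":")): v for k, v in
                     json.loads(f["layout"].attrs["sizes"]).items()}
            traces = {}
            for name, d in f["traces"].items():
                traces[name] = SignalSeries(d[()], float(d.attrs["fs_hz"]),
                                            str(d.attrs["units"]),
                                            json.loads(d.attrs["meta"]))
            stim = Stimulus(**json.loads(f.attrs["stimulus"]))
            spec = None
            if "spec_yaml" in f.attrs:
                spec = spec_from_dict(yaml.safe_load(f.attrs["spec_yaml"]))
            share = None
            if "input_share" in f:
                share = {k: v[()] for k, v in f["input_share"].items()}
            mec = (f["mean_exc_conductance"][()]
                   if "mean_exc_conductance" in f else None)
            return SimulationResult(
                spike_ids=f["spikes/ids"][()], spike_times=f["spikes/times"][()],
                traces=traces, chi=json.loads(f.attrs["chi"]),
                chi_components=json.loads(f.attrs["chi_components"]),
                input_share=share, mean_exc_conductance=mec,
                angles=f["layout/angles"][()], offsets=offsets, sizes=sizes,
                dt=float(f.attrs["dt"]), duration_ms=float(f.attrs["duration_ms"]),
                warmup_ms=float(f.attrs["warmup_ms"]), seed=int(f.attrs["seed"]),
                spec_hash=str(f.attrs["spec_hash"]),
                wiring_hash=str(f.attrs["wiring_hash"]),
                gamma=float(f.attrs["gamma"]), stimulus=stim, spec=spec)
    except OSError as exc:
        raise IOError_(f"{path}: corrupt or unreadable HDF5 file ({exc})") from None


def write_connectivity(matrix, path: str | Path) -> None:
    """Store a wiring realization: per-pathway adjacency as CSR integer
    arrays with parallel conductance/latency attributes."""
    from .connectivity import ConnectivityMatrix  # noqa: F401 (type doc)
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = _SCHEMA
        f.attrs["kind"] = "ConnectivityMatrix"
        f.attrs["n_total"] = matrix.n_total
        f.attrs["gamma"] = matrix.gamma
        f.attrs["gamma_scope"] = matrix.gamma_scope
        f.attrs["offsets"] = json.dumps({f"{l}:{k}": int(v)
                                         for (l, k), v in matrix.offsets.items()})
        f.attrs["sizes"] = json.dumps({f"{l}:{k}": int(v)
                                       for (l, k), v in matrix.sizes.items()})
        f.create_dataset("angles", data=matrix.angles)
        for w in matrix.wirings:
            g = f.create_group(f"pathways/{w.pathway.name}")
            g.create_dataset("indptr", data=w.indptr)
            g.create_dataset("targets", data=w.targets)
            g.attrs["latency"] = w.latency
            g.attrs["conductances"] = json.dumps(w.conductances)
            g.attrs["base_conductances"] = json.dumps(w.base_conductances)
            g.attrs["pathway"] = json.dumps({
                "source_layer": w.pathway.source_layer,
                "source_kind": w.pathway.source_kind,
                "target_layer": w.pathway.target_layer,
                "target_kind": w.pathway.target_kind,
                "p0": w.pathway.p0, "p1": w.pathway.p1,
                "latency": w.pathway.latency,
                "interlayer": w.pathway.interlayer})


def read_connectivity(path: str | Path):
    from .config import PathwaySpec
    from .connectivity import ConnectivityMatrix, PathwayWiring
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("kind") != "ConnectivityMatrix":
                raise IOError_(f"{path}: not a ConnectivityMatrix file")
            offsets = {tuple(k.split(":")): v for k, v in
                       json.loads(f.attrs["offsets"]).items()}
            sizes = {tuple(k.split(":")): v for k, v in
                     json.loads(f.attrs["sizes"]).items()}
            wirings = []
            for name, g in f["pathways"].items():
                pw = PathwaySpec(**json.loads(g.attrs["pathway"]))
                wirings.append(PathwayWiring(
                    pathway=pw, indptr=g["indptr"][()], targets=g["targets"][()],
                    latency=float(g.attrs["latency"]),
                    base_conductances=json.loads(g.attrs["base_conductances"]),
                    conductances=json.loads(g.attrs["conductances"])))
            return ConnectivityMatrix(
                n_total=int(f.attrs["n_total"]), offsets=offsets, sizes=sizes,
                angles=f["angles"][()], wirings=wirings,
                gamma=float(f.attrs["gamma"]),
                gamma_scope=str(f.attrs["gamma_scope"]))
    except OSError as exc:
        raise IOError_(f"{path}: corrupt or unreadable HDF5 file ({exc})") from None


def write_series(series: SignalSeries, path: str | Path, name: str = "series") -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = _SCHEMA
        f.attrs["kind"] = "SignalSeries"
        d = f.create_dataset(name, data=series.samples)
        d.attrs["fs_hz"] = series.fs_hz
        d.attrs["units"] = series.units
        d.attrs["meta"] = json.dumps(series.meta, default=str)


def read_series(path: str | Path, name: str = "series") -> SignalSeries:
    try:
        with h5py.File(path, "r") as f:
            d = f[name]
            return SignalSeries(d[()], float(d.attrs["fs_hz"]),
                                str(d.attrs["units"]), json.loads(d.attrs["meta"]))
    except OSError as exc:
        raise IOError_(f"{path}: corrupt or unreadable HDF5 file ({exc})") from None


def raster_to_csv(result: SimulationResult, path: str | Path) -> None:
    """Two-column CSV export of the spike raster (neuron_id, time_ms)."""
    arr = np.column_stack([result.spike_ids.astype(float), result.spike_times])
    np.savetxt(path, arr, fmt=("%d", "%.3f"), delimiter=",",
               header="neuron_id,time_ms", comments="")


def raster_from_csv(path: str | Path):
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    return data[:, 0].astype(np.int64), data[:, 1]


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=1, default=default))
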