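"""File I/O: spike rasters (HDF5/CSV), topologies, events and metrics.

Conventions: times in ms, voltages in mV, conductances in pS; 0-based
neuron IDs with excitatory IDs first.  The edge-list CSV uses seconds for
tau_rec/tau_facil (matching common usage for these slow constants) and ms
for tau_I; everything in HDF5 is stored in the package's native units.
"""
from __future__ import annotations

from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .dynamics import SimulationResult, StimulationProtocol
from .events import NetworkSpikeEvent
from .topology import NetworkTopology


class FileFormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


# --------------------------------------------------------------------------
# spike rasters
# --------------------------------------------------------------------------

def write_raster_h5(result: SimulationResult, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("spikes")
        g.create_dataset("neuron_id", data=result.spike_neuron)
        g.create_dataset("time_ms", data=result.spike_time)
        g.create_dataset("forced", data=result.spike_forced.astype(np.uint8))
        meta = f.create_group("meta")
        meta.attrs.update({
            "n_exc": result.n_exc, "n_inh": result.n_inh,
            "dt_ms": result.dt, "duration_ms": result.duration,
            "warmup_ms": result.warmup, "version": _pkg_version,
            "seed": -1 if result.seed is None else int(result.seed),
        })
        f.create_dataset("silenced", data=np.asarray(result.silenced, np.int64))
        tr = f.create_group("traces")
        for name, arr, times in (
                ("vstar", result.vstar, result.vstar_times),
                ("v", result.v, result.v_times),
                ("g_exc", result.g_exc, result.g_times),
                ("g_inh", result.g_inh, result.g_times),
                ("resources", result.resources, result.resource_times)):
            if arr is not None:
                d = tr.create_group(name)
                d.create_dataset("values", data=arr)
                d.create_dataset("times_ms", data=times)
        if result.protocol is not None:
            pr = f.create_group("protocol")
            sites = result.protocol.sites
            pr.create_dataset("site_ids", data=np.concatenate(sites)
                              if sites else np.empty(0, np.int64))
            pr.create_dataset("site_sizes",
                              data=np.array([len(s) for s in sites], np.int64))
            pr.create_dataset("event_times_ms", data=result.protocol.event_times)
            pr.create_dataset("event_sites", data=result.protocol.event_sites)


def read_raster_h5(path) -> SimulationResult:
    with h5py.File(path, "r") as f:
        try:
            meta = dict(f["meta"].attrs)
            spikes = f["spikes"]
            kwargs = dict(
                n_exc=int(meta["n_exc"]), n_inh=int(meta["n_inh"]),
                dt=float(meta["dt_ms"]), duration=float(meta["duration_ms"]),
                warmup=float(meta["warmup_ms"]),
                spike_neuron=spikes["neuron_id"][:].astype(np.int32),
                spike_time=spikes["time_ms"][:],
                spike_forced=spikes["forced"][:].astype(bool),
                silenced=f["silenced"][:] if "silenced" in f else np.empty(0, np.int64),
                seed=int(meta.get("seed", -1)),
            )
        except KeyError as exc:
            raise FileFormatError(
                f"{path}: missing dataset/attribute {exc} "
                "(not a pioneernet raster file?)") from exc
        tr = f.get("traces", {})
        def get(name):
            if name in tr:
                return tr[name]["values"][:], tr[name]["times_ms"][:]
            return None, None
        kwargs["vstar"], kwargs["vstar_times"] = get("vstar")
        kwargs["v"], kwargs["v_times"] = get("v")
        kwargs["g_exc"], g_times = get("g_exc")
        kwargs["g_inh"], _ = get("g_inh")
        kwargs["g_times"] = g_times
        kwargs["resources"], kwargs["resource_times"] = get("resources")
        if "protocol" in f:
            pr = f["protocol"]
            sizes = pr["site_sizes"][:]
            ids = pr["site_ids"][:]
            sites, pos = [], 0
            for s in sizes:
                sites.append(ids[pos:pos + s])
                pos += s
            kwargs["protocol"] = StimulationProtocol(
                sites, pr["event_times_ms"][:], pr["event_sites"][:])
        return SimulationResult(**kwargs)


def write_spikes_csv(result: SimulationResult, path) -> None:
    pd.DataFrame({
        "neuron_id": result.spike_neuron,
        "time_ms": np.round(result.spike_time, 1),
        "forced": result.spike_forced.astype(int),
    }).to_csv(path, index=False)


def read_spikes_csv(path, n_exc: int, n_inh: int, dt: float,
                    duration: float, warmup: float = 0.0) -> SimulationResult:
    """Ingest a generic spike raster CSV (columns neuron_id, time_ms and
    optionally forced) for use with the analysis modules."""
    df = pd.read_csv(path)
    for col in ("neuron_id", "time_ms"):
        if col not in df.columns:
            raise FileFormatError(f"{path}: missing required column {col!r}")
    forced = df["forced"].astype(bool).to_numpy() if "forced" in df.columns \
        else np.zeros(len(df), dtype=bool)
    order = np.argsort(df["time_ms"].to_numpy(), kind="stable")
    return SimulationResult(
        n_exc=n_exc, n_inh=n_inh, dt=dt, duration=duration, warmup=warmup,
        spike_neuron=df["neuron_id"].to_numpy(np.int32)[order],
        spike_time=df["time_ms"].to_numpy(float)[order],
        spike_forced=forced[order])


# --------------------------------------------------------------------------
# events
# --------------------------------------------------------------------------

EVENT_COLUMNS = ["t_peak_ms", "A_max_Hz", "t_onset_ms", "t_offset_ms",
                 "label", "site"]


def write_events_csv(events: Sequence[NetworkSpikeEvent], path) -> None:
    pd.DataFrame([{
        "t_peak_ms": ev.t_peak, "A_max_Hz": ev.a_max,
        "t_onset_ms": ev.t_onset, "t_offset_ms": ev.t_offset,
        "label": ev.label, "site": ev.site,
    } for ev in events], columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events_csv(path) -> list:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing event columns {missing}")
    return [NetworkSpikeEvent(
        t_peak=float(r.t_peak_ms), a_max=float(r.A_max_Hz),
        t_onset=float(r.t_onset_ms), t_offset=float(r.t_offset_ms),
        label=str(r.label), site=int(r.site)) for r in df.itertuples()]


# --------------------------------------------------------------------------
# metrics table
# --------------------------------------------------------------------------

def write_metrics_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_metrics_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "neuron_id" not in df.columns:
        raise FileFormatError(f"{path}: not a metrics table (no neuron_id)")
    return df


# --------------------------------------------------------------------------
# topology
# --------------------------------------------------------------------------

def write_topology_h5(topo: NetworkTopology, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs.update({"n_exc": topo.n_exc, "n_inh": topo.n_inh,
                        "kind": topo.kind, "version": _pkg_version})
        f.create_dataset("pre", data=topo.pre)
        f.create_dataset("post", data=topo.post)
        for name in ("weight", "U", "tau_rec", "tau_facil"):
            arr = getattr(topo, name)
            if arr is not None:
                f.create_dataset(name, data=arr)


def read_topology_h5(path) -> NetworkTopology:
    with h5py.File(path, "r") as f:
        try:
            kwargs = dict(
                n_exc=int(f.attrs["n_exc"]), n_inh=int(f.attrs["n_inh"]),
                pre=f["pre"][:], post=f["post"][:],
                kind=str(f.attrs.get("kind", "custom")))
        except KeyError as exc:
            raise FileFormatError(
                f"{path}: missing dataset/attribute {exc}") from exc
        for name in ("weight", "U", "tau_rec", "tau_facil"):
            if name in f:
                kwargs[name] = f[name][:]
        return NetworkTopology(**kwargs)


def write_edges_csv(topo: NetworkTopology, path) -> None:
    pd.DataFrame({
        "pre_id": topo.pre, "post_id": topo.post,
        "weight_pS": topo.weight, "U": topo.U,
        "tau_rec_s": topo.tau_rec / 1000.0,
        "tau_facil_s": topo.tau_facil / 1000.0,
        "tau_I_ms": topo.tau_I,
    }).to_csv(path, index=False)


def read_edges_csv(path, n_exc: int, n_inh: int) -> NetworkTopology:
    df = pd.read_csv(path)
    required = ["pre_id", "post_id", "weight_pS", "U", "tau_rec_s", "tau_facil_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing edge columns {missing}")
    return NetworkTopology(
        n_exc=n_exc, n_inh=n_inh,
        pre=df["pre_id"].to_numpy(np.int32),
        post=df["post_id"].to_numpy(np.int32),
        weight=df["weight_pS"].to_numpy(float),
        U=df["U"].to_numpy(float),
        tau_rec=df["tau_rec_s"].to_numpy(float) * 1000.0,
        tau_facil=df["tau_facil_s"].to_numpy(float) * 1000.0)
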