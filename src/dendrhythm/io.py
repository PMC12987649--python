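"""Plain-text and HDF5 I/O for trains, rate traces, synapse tables, events
and recorded traces."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import RateTrace, SpikeTrain
from .events import EventSeries
from .synapses import SynapseSpec

__all__ = [
    "write_spike_trains", "read_spike_trains",
    "write_spike_trains_h5", "read_spike_trains_h5",
    "write_rate_trace", "read_rate_trace",
    "write_synapse_table", "read_synapse_table",
    "write_events", "read_events", "write_traces_h5", "read_traces_h5",
]


def write_spike_trains(path, trains: dict[int, SpikeTrain]) -> None:
    """Two-column delimited text: node_id <TAB> time_ms, one row per spike."""
    with open(path, "w") as fh:
        fh.write("node_id\ttime_ms\n")
        for nid in sorted(trains):
            for t in trains[nid].times:
                fh.write(f"{nid}\t{t:.6f}\n")


def read_spike_trains(path) -> dict[int, SpikeTrain]:
    tab = pd.read_csv(path, sep="\t")
    out = {}
    for nid, grp in tab.groupby("node_id"):
        out[int(nid)] = SpikeTrain(int(nid),
                                   np.sort(grp["time_ms"].to_numpy()))
    return out


def write_spike_trains_h5(path, trains: dict[int, SpikeTrain],
                          group: str = "spike_trains") -> None:
    import h5py
    with h5py.File(path, "a") as fh:
        g = fh.require_group(group)
        for nid, tr in trains.items():
            name = f"node_{nid:06d}"
            if name in g:
                del g[name]
            g.create_dataset(name, data=tr.times)


def read_spike_trains_h5(path, group: str = "spike_trains") -> dict:
    import h5py
    out = {}
    with h5py.File(path, "r") as fh:
        for name, ds in fh[group].items():
            nid = int(name.split("_")[1])
            out[nid] = SpikeTrain(nid, ds[...])
    return out


def write_rate_trace(path, trace: RateTrace) -> None:
    """Single-column text with a one-line header carrying t0 and dt (ms)."""
    with open(path, "w") as fh:
        fh.write(f"# t0={trace.t0} dt={trace.dt}\n")
        for v in trace.values:
            fh.write(f"{v:.9g}\n")


def read_rate_trace(path) -> RateTrace:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        values = np.loadtxt(fh)
    return RateTrace(float(meta["t0"]), float(meta["dt"]), values)


def write_synapse_table(path, specs: list[SynapseSpec]) -> None:
    from .synapses import synapse_table
    synapse_table(specs).to_csv(path, sep="\t", index=False)


def read_synapse_table(path) -> list[SynapseSpec]:
    tab = pd.read_csv(path, sep="\t")
    return [SynapseSpec(
        int(r["synapse_id"]), int(r["compartment_id"]), float(r["pos"]),
        str(r["class"]), str(r["zone"]), str(r["subtree"]),
        int(r["node_id"]), float(r["p_release"]), str(r["stp"]),
        g_ampa=float(r["g_ampa_uS"]), g_nmda=float(r["g_nmda_uS"]),
        g_gaba=float(r["g_gaba_uS"]))
        for r in tab.to_dict("records")]


def write_events(path, events: list[EventSeries]) -> None:
    """Delimited text: compartment_id, kind, onset_ms, offset_ms (NaN for
    point events)."""
    with open(path, "w") as fh:
        fh.write("compartment_id\tkind\tonset_ms\toffset_ms\n")
        for ev in events:
            offs = ev.offsets if ev.offsets is not None \
                else [np.nan] * ev.n
            for on, off in zip(ev.onsets, offs):
                fh.write(f"{ev.comp}\t{ev.kind}\t{on:.4f}\t{off:.4f}\n")


def read_events(path) -> list[EventSeries]:
    tab = pd.read_csv(path, sep="\t")
    out = []
    for (comp, kind), grp in tab.groupby(["compartment_id", "kind"]):
        onsets = grp["onset_ms"].to_numpy()
        offsets = grp["offset_ms"].to_numpy()
        has_off = not np.all(np.isnan(offsets))
        order = np.argsort(onsets)
        out.append(EventSeries(int(comp), str(kind), onsets[order],
                               offsets[order] if has_off else None))
    return out


def write_traces_h5(path, traces) -> None:
    """TraceSet to HDF5: one dataset per recorded quantity, dt/units attrs."""
    import h5py
    with h5py.File(path, "w") as fh:
        fh.attrs["dt_ms"] = traces.dt
        fh.attrs["dt_rec_ms"] = traces.dt_rec
        fh.attrs["duration_ms"] = traces.duration
        fh.create_dataset("comp_ids", data=traces.comp_ids)
        fh.create_dataset("region", data=np.array(
            [str(r) for r in traces.region], dtype="S16"))
        fh.create_dataset("subtree", data=np.array(
            [str(r) for r in traces.subtree], dtype="S16"))
        fh.create_dataset("path_dist_um", data=traces.path_dist)
        for name, units in [("v", "mV"), ("gna", "mS/cm2"),
                            ("i_nmda", "nA"), ("i_ca", "nA"),
                            ("v_soma", "mV")]:
            ds = fh.create_dataset(name, data=getattr(traces, name))
            ds.attrs["units"] = units


def read_traces_h5(path):
    import h5py
    from .cell import TraceSet
    with h5py.File(path, "r") as fh:
        return TraceSet(
            float(fh.attrs["dt_ms"]), float(fh.attrs["dt_rec_ms"]),
            fh["comp_ids"][...],
            np.array([s.decode() for s in fh["region"][...]], dtype=object),
            np.array([s.decode() for s in fh["subtree"][...]], dtype=object),
            fh["path_dist_um"][...],
            fh["v"][...], fh["gna"][...], fh["i_nmda"][...],
            fh["i_ca"][...], fh["v_soma"][...],
            float(fh.attrs["duration_ms"]))
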