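"""Readers and writers for the package's typed objects.

Traces round-trip through CSV (``time_s, cell_0001, ...``) and HDF5
(datasets ``/traces``, ``/clean``, ``/fs``); events, spike truth, ROI
tables and edge lists through CSV; image stacks through multi-page TIFF
with an optional per-frame voltage CSV sidecar (``frame, volts``).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .events import DetectionParams, Event, EventList
from .netdyn import FunctionalGraph
from .tracesim import SpikeTruth, TraceSet
from .volumescan import RoiMap

__all__ = [
    "write_traces_h5", "read_traces_h5", "write_traces_csv", "read_traces_csv",
    "write_spikes_csv", "read_spikes_csv", "write_events_csv", "read_events_csv",
    "write_rois_csv", "write_graph_csv", "read_graph_csv",
    "write_stack", "read_stack", "write_voltages_csv", "read_voltages_csv",
]


def write_traces_h5(path, traces: TraceSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=traces.values)
        if traces.clean is not None:
            f.create_dataset("clean", data=traces.clean)
        f.create_dataset("fs", data=traces.fs)


def read_traces_h5(path) -> TraceSet:
    with h5py.File(path, "r") as f:
        clean = f["clean"][()] if "clean" in f else None
        return TraceSet(f["traces"][()], float(f["fs"][()]), clean=clean)


def write_traces_csv(path, traces: TraceSet) -> None:
    cols = {f"cell_{c + 1:04d}": traces.values[:, c] for c in range(traces.n_cells)}
    pd.DataFrame({"time_s": traces.time, **cols}).to_csv(path, index=False)


def read_traces_csv(path) -> TraceSet:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples to infer fs")
    fs = 1.0 / np.median(np.diff(t))
    return TraceSet(df.drop(columns="time_s").to_numpy(), float(fs))


def write_spikes_csv(path, truth: SpikeTruth) -> None:
    rows = [(c, t) for c, ts in enumerate(truth.times) for t in ts]
    pd.DataFrame(rows, columns=["cell", "spike_time_s"]).to_csv(path, index=False)


def read_spikes_csv(path, duration: float, n_cells: int | None = None) -> SpikeTruth:
    df = pd.read_csv(path)
    n = int(df["cell"].max()) + 1 if n_cells is None else n_cells
    times = [df.loc[df["cell"] == c, "spike_time_s"].to_numpy() for c in range(n)]
    return SpikeTruth(times, duration)


def write_events_csv(path, events: EventList) -> None:
    events.to_dataframe().to_csv(path, index=False)


def read_events_csv(path, fs: float) -> EventList:
    df = pd.read_csv(path)
    n = int(df["cell"].max()) + 1 if len(df) else 0
    per_cell: list[list[Event]] = [[] for _ in range(n)]
    for _, r in df.iterrows():
        ev = Event(
            int(round(r["onset_s"] * fs)), int(round(r["offset_s"] * fs)),
            r["onset_s"], r["offset_s"], r["peak_dff"],
            r.get("half_decay_s", np.nan),
            bool(r.get("half_decay_unresolved", False)),
        )
        per_cell[int(r["cell"])].append(ev)
    return EventList(per_cell, fs, DetectionParams())


def write_rois_csv(path, rois: RoiMap) -> None:
    rois.table.to_csv(path, index=False)


def write_rois_h5(path, rois: RoiMap) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["height"], f.attrs["width"] = rois.shape
        f.attrs["pixel_um"] = rois.pixel_um
        for i, fp in enumerate(rois.footprints):
            f.create_dataset(f"footprints/{i:05d}", data=fp)


def write_graph_csv(path, graph: FunctionalGraph) -> None:
    graph.edges.to_csv(path, index=False)


def read_graph_csv(path) -> FunctionalGraph:
    return FunctionalGraph(pd.read_csv(path))


def write_stack(path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def read_stack(path) -> np.ndarray:
    try:
        return tifffile.imread(path)
    except Exception as exc:  # surface the failing file/page clearly
        raise IOError(f"failed to read TIFF stack {path}: {exc}") from exc


def write_voltages_csv(path, voltages: np.ndarray) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(voltages)), "volts": voltages}
    ).to_csv(path, index=False)


def read_voltages_csv(path) -> np.ndarray:
    return pd.read_csv(path)["volts"].to_numpy()


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
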