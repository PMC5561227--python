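"""End-to-end orchestration of the synthetic experiment.

A single seeded configuration drives: trace simulation -> synthetic
volume rendering -> z-stack segmentation and 3D localization -> EDOF
trace extraction -> ΔF/F0 normalization, modified Perona-Malik smoothing
and event detection -> network analysis (synchronization, communities,
transfer-entropy connectivity, link/cluster geometry).  Every stage
persists its output and the whole run is reproducible from the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io, netdyn, volumescan
from .diffusion import DiffusionParams
from .events import DetectionParams, detect_all, event_stats, normalize_dff
from .netdyn import Raster
from .tracesim import SimConfig, simulate
from .volumescan import ScanConfig, SegmentationParams

log = logging.getLogger("caltrace")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Nested configuration for a full synthetic run."""

    sim: SimConfig = field(default_factory=SimConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    detection: DetectionParams | None = None   # None -> auto-select
    n_cells: int = 50
    volume_um: tuple[float, float, float] = (400.0, 400.0, 150.0)
    n_shuffles: int = 200
    te_max_cells: int = 20      # cap on the all-pairs TE stage
    seed: int = 0
    outdir: str = "caltrace_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        sections = dict(sim=SimConfig, scan=ScanConfig,
                        segmentation=SegmentationParams,
                        diffusion=DiffusionParams, detection=DetectionParams)
        for key, val in raw.items():
            if key in sections:
                kwargs[key] = sections[key](**val) if val is not None else None
            elif key == "volume_um":
                kwargs[key] = tuple(val)
            elif key in {f.name for f in dataclasses.fields(cls)}:
                kwargs[key] = val
            else:
                raise ValueError(f"unknown config key: {key}")
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["volume_um"] = list(self.volume_um)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    version: str = "0.1.0"
    timings_s: dict = field(default_factory=dict)
    status: str = "running"

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str))


def _stage_seeds(seed: int, names: list[str]) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic pipeline; returns the paths of the
    persisted artifacts.  Deterministic under ``config.seed``."""
    out = io.ensure_dir(config.outdir)
    seeds = _stage_seeds(config.seed, ["sim", "volume", "network"])
    manifest = RunManifest(config=json.loads(json.dumps(asdict(config), default=str)),
                           seeds=seeds)
    manifest.write(out / "manifest.json")
    artifacts = {"manifest": str(out / "manifest.json")}
    t_start = time.time()

    def _stage(name):
        log.info("stage %s starting", name)
        return time.time()

    try:
        # --- simulate ground-truth activity -----------------------------
        t0 = _stage("simulate")
        sim_cfg = dataclasses.replace(config.sim, n_traces=config.n_cells,
                                      seed=seeds["sim"])
        traces, truth = simulate(sim_cfg)
        io.write_traces_h5(out / "sim_traces.h5", traces)
        io.write_spikes_csv(out / "sim_spikes.csv", truth)
        manifest.timings_s["simulate"] = time.time() - t0

        # --- render and scan the synthetic volume -----------------------
        t0 = _stage("volume")
        zstack, tstack, positions, voltages = volumescan.synth_volume(
            config.n_cells, config.volume_um, config.scan,
            traces=traces, seed=seeds["volume"],
        )
        io.write_stack(out / "zstack.tif", zstack)
        io.write_voltages_csv(out / "voltages.csv", voltages)
        rois = volumescan.project_and_segment(
            zstack, config.segmentation, config.scan.pixel_um)
        rois = volumescan.locate_axial(zstack, rois, config.scan, voltages)
        io.write_rois_csv(out / "rois.csv", rois)
        raw = volumescan.extract_traces(tstack, rois, config.scan.f_ccd)
        io.write_traces_h5(out / "raw_traces.h5", raw)
        manifest.timings_s["volume"] = time.time() - t0

        # --- denoise and detect ------------------------------------------
        t0 = _stage("events")
        dff = normalize_dff(raw)
        events = detect_all(dff, config.diffusion, config.detection,
                            auto_params=config.detection is None)
        io.write_events_csv(out / "events.csv", events)
        event_stats(events, dff.n_samples / dff.fs).drop(columns="iei").to_csv(
            out / "event_stats.csv", index=False)
        manifest.timings_s["events"] = time.time() - t0

        # --- network analysis --------------------------------------------
        t0 = _stage("network")
        raster = Raster.from_events(events, dff.n_samples)
        active = [c for c in range(raster.n_cells) if raster.onsets[c].size]
        results = {}
        if len(active) >= 2:
            results["spike_sync"] = netdyn.spike_sync(
                [raster.onsets[c] for c in active])
            assign = netdyn.cluster_trains(raster)
            np.savetxt(out / "clusters.csv",
                       np.column_stack([np.arange(raster.n_cells), assign.labels]),
                       fmt="%d", header="cell,cluster", comments="", delimiter=",")
            sub = active[: config.te_max_cells]
            sub_raster = Raster(raster.matrix[sub], raster.fs,
                                [raster.onsets[c] for c in sub])
            graph = netdyn.functional_connectivity(
                sub_raster, n_shuffles=config.n_shuffles, seed=seeds["network"])
            pos = rois.positions_um()[sub]
            # re-index edges to original cell ids before attaching geometry
            graph.edges["src"] = np.asarray(sub)[graph.edges["src"].to_numpy()]
            graph.edges["dst"] = np.asarray(sub)[graph.edges["dst"].to_numpy()]
            idx = {c: k for k, c in enumerate(sub)}
            local = netdyn.FunctionalGraph(graph.edges.assign(
                src=[idx[s] for s in graph.edges["src"]],
                dst=[idx[d] for d in graph.edges["dst"]]))
            if local.significant().shape[0]:
                edges, _ = netdyn.link_angles(local, pos)
                edges = edges.assign(
                    src=np.asarray(sub)[edges["src"].to_numpy()],
                    dst=np.asarray(sub)[edges["dst"].to_numpy()])
                io.write_graph_csv(out / "graph.csv", netdyn.FunctionalGraph(edges))
            else:
                io.write_graph_csv(out / "graph.csv", graph)
            results["n_significant_links"] = int(graph.edges["significant"].sum())
        manifest.timings_s["network"] = time.time() - t0

        manifest.status = "ok"
        manifest.timings_s["total"] = time.time() - t_start
        manifest.write(out / "manifest.json")
    except Exception as exc:
        manifest.status = f"failed: {exc}"
        manifest.write(out / "manifest.json")
        raise
    artifacts.update({
        "rois": str(out / "rois.csv"), "events": str(out / "events.csv"),
        "graph": str(out / "graph.csv"), "traces": str(out / "raw_traces.h5"),
    })
    return artifacts
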