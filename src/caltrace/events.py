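"""ΔF/F0 normalization and rule-based calcium-event detection.

Events are detected on traces already smoothed by the modified
Perona-Malik filter.  An event must satisfy four conditions:

(i)   at the onset the first derivative stays above a fixed positive
      threshold throughout a short right interval (the fluorescence
      rises with increasing slope);
(ii)  the ΔF between onset and offset exceeds an amplitude threshold set
      to the standard deviation of (original - smoothed), the per-cell
      residual noise removed by the filter;
(iii) at the offset the first derivative stays below a fixed negative
      threshold throughout the right interval (the fluorescence
      decreases after the event);
(iv)  the gap between the last supra-threshold-derivative sample after
      the onset and the offset stays below a maximum width, rejecting
      slow drifts.

Events are scanned greedily left to right, so they never overlap.  The
half-decay time of an event is the time the trace takes to fall below
half its peak value counted from the offset sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .diffusion import DiffusionParams, SmoothedTrace, linear_baseline, pm_modified
from .tracesim import TraceSet

__all__ = [
    "DetectionParams",
    "Event",
    "EventList",
    "normalize_dff",
    "auto_select_params",
    "detect_events",
    "detect_all",
    "half_decay_time",
    "event_stats",
]


@dataclass
class DetectionParams:
    onset_deriv_thresh: float = 1e-3
    offset_deriv_thresh: float = -1e-4
    max_width: int = 300          # samples
    right_interval: int = 5       # samples over which the derivative must hold

    def __post_init__(self) -> None:
        if self.onset_deriv_thresh <= 0:
            raise ValueError("onset_deriv_thresh must be positive")
        if self.offset_deriv_thresh >= 0:
            raise ValueError("offset_deriv_thresh must be negative")
        if self.max_width <= 0:
            raise ValueError("max_width must be positive")
        if self.right_interval < 1:
            raise ValueError("right_interval must be >= 1")


@dataclass
class Event:
    onset: int               # sample index
    offset: int              # sample index (end of the rise)
    onset_s: float
    offset_s: float
    peak_amp: float          # max trace value in [onset, offset]
    half_decay_s: float = np.nan
    half_decay_unresolved: bool = False

    def __post_init__(self) -> None:
        if self.onset >= self.offset:
            raise ValueError("onset must precede offset")


@dataclass
class EventList:
    """Ordered events per cell plus provenance."""

    events: list[list[Event]]
    fs: float
    params: DetectionParams | None = None
    trace_ids: list[str] | None = None

    @property
    def n_cells(self) -> int:
        return len(self.events)

    def onsets_s(self, cell: int) -> np.ndarray:
        return np.array([e.onset_s for e in self.events[cell]])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c, evs in enumerate(self.events):
            for e in evs:
                rows.append(
                    dict(cell=c, onset_s=e.onset_s, offset_s=e.offset_s,
                         peak_dff=e.peak_amp, half_decay_s=e.half_decay_s,
                         half_decay_unresolved=e.half_decay_unresolved)
                )
        return pd.DataFrame(
            rows, columns=["cell", "onset_s", "offset_s", "peak_dff",
                           "half_decay_s", "half_decay_unresolved"]
        )


def normalize_dff(raw: TraceSet, window: float = 30.0) -> TraceSet:
    """ΔF/F0 = (F - F0)/F0 with F0 the slow linear-diffusion baseline.

    Raises (naming the cell) if the estimated baseline is not strictly
    positive anywhere.
    """
    out = np.empty_like(raw.values)
    for c in range(raw.n_cells):
        f0 = linear_baseline(raw.values[:, c], raw.fs, window)
        if np.any(f0 <= 0):
            raise ValueError(f"non-positive baseline F0 in cell {c}")
        out[:, c] = (raw.values[:, c] - f0) / f0
    return TraceSet(out, raw.fs)


def _hold_masks(d: np.ndarray, params: DetectionParams) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks: derivative above onset (below offset) threshold at
    every sample of the forward right interval."""
    r = params.right_interval
    dmin = minimum_filter1d(d, size=r, origin=-(r // 2), mode="nearest")
    dmax = maximum_filter1d(d, size=r, origin=-(r // 2), mode="nearest")
    return dmin > params.onset_deriv_thresh, dmax < params.offset_deriv_thresh


def detect_events(
    smoothed: SmoothedTrace | np.ndarray,
    residual_std: float | None = None,
    params: DetectionParams | None = None,
    fs: float = 65.0,
) -> list[Event]:
    """Detect calcium events on one smoothed trace.

    ``residual_std`` defaults to the value recorded on the SmoothedTrace.
    Returns time-ordered, non-overlapping events; an empty list for flat
    or too-short traces.
    """
    params = params or DetectionParams()
    if isinstance(smoothed, SmoothedTrace):
        u = smoothed.values
        if residual_std is None:
            residual_std = smoothed.residual_std
    else:
        u = np.asarray(smoothed, dtype=float)
        if residual_std is None:
            raise ValueError("residual_std required when passing a bare array")
    if u.size < params.right_interval + 2:
        return []

    d = np.diff(u)
    rise_ok, fall_ok = _hold_masks(d, params)
    events: list[Event] = []
    i, nd = 0, d.size
    while i < nd:
        if not rise_ok[i]:
            i += 1
            continue
        onset = i
        off_candidates = np.flatnonzero(fall_ok[onset + 1:])
        if off_candidates.size == 0:
            break
        offset = onset + 1 + off_candidates[0]
        supra = np.flatnonzero(d[onset:offset] > params.onset_deriv_thresh)
        last_supra = onset + (supra[-1] if supra.size else 0)
        rise = u[offset] - u[onset]
        if rise > 0 and rise > residual_std and (offset - last_supra) < params.max_width:
            peak = float(u[onset:offset + 1].max())
            ev = Event(onset, offset, onset / fs, offset / fs, peak)
            half_decay_time(u, ev, fs)
            events.append(ev)
        i = offset + 1
    return events


def half_decay_time(smoothed: np.ndarray, event: Event, fs: float) -> float:
    """Time from the event offset until the trace first falls below half the
    event's peak value.  Stores the result (and the unresolved flag, if the
    end of the trace is reached first) on the event and returns it."""
    u = np.asarray(smoothed, dtype=float)
    half = event.peak_amp / 2.0
    tail = u[event.offset:]
    below = np.flatnonzero(tail < half)
    if below.size == 0:
        event.half_decay_s = np.nan
        event.half_decay_unresolved = True
        return np.nan
    event.half_decay_s = float(below[0] / fs)
    event.half_decay_unresolved = False
    return event.half_decay_s


def auto_select_params(
    population_mean_trace: np.ndarray,
    fs: float,
    base: DetectionParams | None = None,
    slow_onset_s: float = 5.0,
) -> DetectionParams:
    """Select the onset threshold and maximum event width from a provisional
    detection pass on the population-mean trace.

    Simultaneous activation of many ROIs shows up as transients of the mean
    trace; in that case the onset threshold is raised from 1e-3 to 1e-2.
    If those global events rise slower than ``slow_onset_s`` seconds the
    maximum width is doubled from 300 to 600 samples.
    """
    base = base or DetectionParams()
    u = np.asarray(population_mean_trace, dtype=float)
    sm = pm_modified(u) if u.size >= DiffusionParams().delta + 2 else None
    if sm is None:
        return base
    evs = detect_events(sm, params=base, fs=fs)
    if not evs:
        return replace(base, onset_deriv_thresh=1e-3, max_width=300)
    rise_times = np.array([e.offset_s - e.onset_s for e in evs])
    width = 600 if rise_times.mean() > slow_onset_s else 300
    return replace(base, onset_deriv_thresh=1e-2, max_width=width)


def detect_all(
    traces: TraceSet,
    diffusion: DiffusionParams | None = None,
    params: DetectionParams | None = None,
    auto_params: bool = False,
) -> EventList:
    """Smooth every trace with the modified Perona-Malik filter and detect
    events.  With ``auto_params`` the detection thresholds are selected from
    the population-mean trace first."""
    diffusion = diffusion or DiffusionParams()
    if auto_params and params is None:
        params = auto_select_params(traces.values.mean(axis=1), traces.fs)
    params = params or DetectionParams()
    per_cell = []
    for c in range(traces.n_cells):
        sm = pm_modified(traces.values[:, c], diffusion)
        per_cell.append(detect_events(sm, params=params, fs=traces.fs))
    return EventList(per_cell, traces.fs, params)


def event_stats(events: EventList, duration: float) -> pd.DataFrame:
    """Per-cell mean firing rate (events/s) and inter-event intervals (s)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rows = []
    for c in range(events.n_cells):
        onsets = events.onsets_s(c)
        rows.append(
            dict(cell=c, n_events=len(onsets), mfr=len(onsets) / duration,
                 iei=np.diff(onsets).tolist())
        )
    return pd.DataFrame(rows, columns=["cell", "n_events", "mfr", "iei"])
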