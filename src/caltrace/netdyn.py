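"""Network-level analysis of calcium event rasters and 3D soma positions.

Covers: the multivariate SPIKE-synchronization index (fraction of
quasi-simultaneous events under an adaptive coincidence window), spike
train community detection (binned count vectors, cosine similarity,
modularity-maximizing partition with the bin size self-selected by
modularity), transfer-entropy (TE) functional connectivity with an
inter-event-interval-preserving shuffled null and per-pair Z-scores, and
geometry statistics of the inferred links and clusters (azimuth/polar
link angles, transverse vs coronal-sagittal convex-hull area ratios,
silhouette test against label permutations, intra- vs inter-cluster
connection strength).

Angle conventions follow volumetric-imaging usage: "azimuth" is the
angle to the z-axis in [0, π]; "polar" is the angle within the x-y
plane in (-π, π].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.metrics import silhouette_score

from .events import EventList

__all__ = [
    "Raster",
    "FunctionalGraph",
    "ClusterAssignment",
    "spike_sync",
    "cluster_trains",
    "transfer_entropy",
    "iei_preserving_shuffle",
    "te_significance",
    "functional_connectivity",
    "link_angles",
    "cluster_geometry",
    "silhouette_test",
    "intra_inter_strength",
]


@dataclass
class Raster:
    """Binary event raster (cells x samples) at frame resolution, plus the
    per-cell onset times in seconds."""

    matrix: np.ndarray
    fs: float
    onsets: list[np.ndarray]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("raster entries must be 0/1")

    @classmethod
    def from_events(cls, events: EventList, n_samples: int) -> "Raster":
        mat = np.zeros((events.n_cells, n_samples), dtype=np.uint8)
        onsets = []
        for c, evs in enumerate(events.events):
            idx = np.array([e.onset for e in evs], dtype=int)
            mat[c, idx[idx < n_samples]] = 1
            onsets.append(np.array([e.onset_s for e in evs]))
        return cls(mat, events.fs, onsets)

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]


@dataclass
class FunctionalGraph:
    """Directed weighted links between cells: TE (bits), Z-score against the
    shuffled null, significance flag and, once positions are attached,
    the 3D orientation angles."""

    edges: pd.DataFrame   # src, dst, te_bits, z, significant [, azimuth_rad, polar_rad]

    def significant(self) -> pd.DataFrame:
        return self.edges[self.edges["significant"]]


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    bin_size: float
    modularity: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


# ---------------------------------------------------------------------------
# SPIKE-synchronization


def _adaptive_tau(ti: np.ndarray, k: int, tj: np.ndarray, l: int) -> float:
    """Half the minimum of the up-to-four inter-event intervals surrounding
    spike k of train i and spike l of train j."""
    intervals = []
    if k > 0:
        intervals.append(ti[k] - ti[k - 1])
    if k < ti.size - 1:
        intervals.append(ti[k + 1] - ti[k])
    if l > 0:
        intervals.append(tj[l] - tj[l - 1])
    if l < tj.size - 1:
        intervals.append(tj[l + 1] - tj[l])
    if not intervals:
        return np.inf
    return 0.5 * min(intervals)


def _pair_coincidences(ti: np.ndarray, tj: np.ndarray) -> int:
    """Number of spikes of train i coincident with their nearest spike in
    train j under the adaptive window."""
    count = 0
    for k in range(ti.size):
        l = int(np.argmin(np.abs(tj - ti[k])))
        if np.abs(ti[k] - tj[l]) < _adaptive_tau(ti, k, tj, l):
            count += 1
    return count


def spike_sync(onsets: list[np.ndarray]) -> float:
    """Multivariate SPIKE-synchronization index in [0, 1].

    For every event of every train, a partner train contributes a
    coincidence when its nearest event lies within the adaptive window
    τ = ½ · min of the surrounding inter-event intervals.  The index is
    the mean coincidence fraction over all events and ordered pairs; it
    is 1 when all trains are identical and 0 when no two events are
    quasi-simultaneous.
    """
    trains = [np.asarray(t, dtype=float) for t in onsets]
    if len(trains) < 2:
        raise ValueError("need at least two trains")
    total, coincident = 0, 0
    for i, ti in enumerate(trains):
        if ti.size == 0:
            continue
        for j, tj in enumerate(trains):
            if i == j or tj.size == 0:
                continue
            coincident += _pair_coincidences(ti, tj)
            total += ti.size
    if total == 0:
        warnings.warn("all trains empty: SPIKE-synchronization undefined",
                      stacklevel=2)
        return np.nan
    return coincident / total


# ---------------------------------------------------------------------------
# spike-train communities


def _bin_counts(onsets: list[np.ndarray], bin_size: float, duration: float) -> np.ndarray:
    edges = np.arange(0.0, duration + bin_size, bin_size)
    return np.stack([np.histogram(t, bins=edges)[0] for t in onsets]).astype(float)


def _cosine_similarity(counts: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(counts, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    unit = counts / safe[:, None]
    sim = unit @ unit.T
    np.fill_diagonal(sim, 0.0)
    return np.clip(sim, 0.0, None)


def cluster_trains(
    raster: Raster,
    bin_sizes: np.ndarray | None = None,
    duration: float | None = None,
) -> ClusterAssignment:
    """Cluster event trains by modularity maximization on the cosine
    similarity of binned event counts, scanning bin sizes (default: a
    logarithmic grid from 0.01 s to 1 s) and keeping the bin with the
    highest modularity.  The number of communities is an output.
    """
    onsets = raster.onsets
    active = [t for t in onsets if t.size]
    if len(active) < 2:
        warnings.warn("fewer than two active cells: single community",
                      stacklevel=2)
        return ClusterAssignment(np.zeros(len(onsets), dtype=int), np.nan, np.nan)
    if bin_sizes is None:
        bin_sizes = np.geomspace(0.01, 1.0, 10)
    if duration is None:
        duration = raster.matrix.shape[1] / raster.fs

    best: tuple[float, float, list] | None = None
    for b in bin_sizes:
        counts = _bin_counts(onsets, float(b), duration)
        sim = _cosine_similarity(counts)
        g = nx.from_numpy_array(sim)
        comms = nx.community.greedy_modularity_communities(g, weight="weight")
        q = nx.community.modularity(g, comms, weight="weight")
        if best is None or q > best[0]:
            best = (q, float(b), comms)
    q, b, comms = best
    labels = np.empty(len(onsets), dtype=int)
    for lab, members in enumerate(sorted(comms, key=min)):
        for m in members:
            labels[m] = lab
    return ClusterAssignment(labels, b, q)


# ---------------------------------------------------------------------------
# transfer entropy


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    """Integer encoding of the m-sample history ending at each time n."""
    n = x.size
    code = np.zeros(n - m + 1, dtype=np.int64)
    for k in range(m):
        code = code * 2 + x[k: n - m + 1 + k]
    return code


def transfer_entropy(x: np.ndarray, y: np.ndarray, m: int = 1) -> float:
    """Plug-in transfer entropy TE(Y→X) in bits for binary trains.

    TE(Y→X) = Σ p(x_{n+1}, x_n^m, y_n^m) log2 [ p(x_{n+1} | x_n^m, y_n^m)
    / p(x_{n+1} | x_n^m) ], estimated from empirical joint frequencies
    with the 0·log 0 := 0 convention.  Non-negative; 0 for constant x.
    """
    x = np.asarray(x).astype(np.int64)
    y = np.asarray(y).astype(np.int64)
    if x.shape != y.shape:
        raise ValueError("trains must have equal length")
    if x.size < m + 2:
        raise ValueError("trains too short for the embedding order")
    xh = _embed(x[:-1], m)          # x_n^m for n = m-1 .. N-2
    yh = _embed(y[:-1], m)
    xf = x[m:]                      # x_{n+1}
    # joint state: (x_{n+1}, x_hist, y_hist)
    base = 2**m
    joint = (xf * base + xh) * base + yh
    n = joint.size
    p_xyz = np.bincount(joint, minlength=2 * base * base) / n
    p_xy = np.bincount(xf * base + xh, minlength=2 * base) / n      # (x+, xh)
    p_hh = np.bincount(xh * base + yh, minlength=base * base) / n   # (xh, yh)
    p_h = np.bincount(xh, minlength=base) / n

    te = 0.0
    nz = np.flatnonzero(p_xyz)
    for s in nz:
        yh_s = s % base
        xh_s = (s // base) % base
        xf_s = s // (base * base)
        num = p_xyz[s] / p_hh[xh_s * base + yh_s]
        den = p_xy[xf_s * base + xh_s] / p_h[xh_s]
        te += p_xyz[s] * np.log2(num / den)
    return max(float(te), 0.0)


def iei_preserving_shuffle(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Surrogate train with the event count and the multiset of inter-event
    intervals preserved exactly: the gaps between successive events are
    randomly permuted while the first event time is kept."""
    y = np.asarray(y).astype(np.int64)
    idx = np.flatnonzero(y)
    out = np.zeros_like(y)
    if idx.size == 0:
        return out
    gaps = np.diff(idx)
    new_idx = np.concatenate(([idx[0]], idx[0] + np.cumsum(rng.permutation(gaps))))
    out[new_idx] = 1
    return out


def te_significance(
    x: np.ndarray,
    y: np.ndarray,
    n_shuffles: int = 200,
    m: int = 1,
    seed: int = 0,
) -> tuple[float, float, bool]:
    """TE(Y→X) with a shuffled null: the source train y is replaced by
    ``n_shuffles`` IEI-preserving surrogates; Z = (TE - mean_null)/std_null
    and the link is significant when TE exceeds the 95th percentile of the
    null sample.  A degenerate null (zero spread) yields Z = NaN, not
    significant."""
    if n_shuffles < 20:
        raise ValueError("need at least 20 shuffles")
    rng = np.random.default_rng(seed)
    te = transfer_entropy(x, y, m)
    null = np.array([
        transfer_entropy(x, iei_preserving_shuffle(y, rng), m)
        for _ in range(n_shuffles)
    ])
    sd = null.std()
    if sd == 0:
        return te, np.nan, False
    z = (te - null.mean()) / sd
    return te, float(z), bool(te > np.percentile(null, 95))


def functional_connectivity(
    raster: Raster,
    n_shuffles: int = 200,
    m: int = 1,
    seed: int = 0,
) -> FunctionalGraph:
    """All-pairs directed TE graph with per-pair shuffled-null Z-scores."""
    n = raster.n_cells
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n * n)]
    rows = []
    for j in range(n):          # source
        for i in range(n):      # target
            if i == j:
                continue
            te, z, sig = te_significance(
                raster.matrix[i], raster.matrix[j],
                n_shuffles=n_shuffles, m=m, seed=seeds[j * n + i],
            )
            rows.append(dict(src=j, dst=i, te_bits=te, z=z, significant=sig))
    return FunctionalGraph(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# geometry


def link_angles(
    graph: FunctionalGraph,
    positions: np.ndarray,
    n_bins: int = 18,
) -> tuple[pd.DataFrame, dict]:
    """Orientation of each significant link: azimuth = angle to the z-axis
    (arccos(d_z/|d|) in [0, π]); polar = atan2(d_y, d_x) in the x-y plane.
    Zero-length links (identical positions) are skipped with a warning.
    Returns the annotated edge table and normalized angle histograms."""
    positions = np.asarray(positions, dtype=float)
    edges = graph.significant().copy()
    az, po, keep = [], [], []
    for _, e in edges.iterrows():
        d = positions[int(e["dst"])] - positions[int(e["src"])]
        norm = np.linalg.norm(d)
        if norm == 0:
            warnings.warn("zero-length link skipped", stacklevel=2)
            keep.append(False)
            az.append(np.nan)
            po.append(np.nan)
            continue
        keep.append(True)
        az.append(np.arccos(np.clip(d[2] / norm, -1, 1)))
        po.append(np.arctan2(d[1], d[0]))
    edges["azimuth_rad"] = az
    edges["polar_rad"] = po
    edges = edges[np.array(keep, dtype=bool)] if len(keep) else edges
    az_vals = edges["azimuth_rad"].dropna()
    po_vals = edges["polar_rad"].dropna()
    dens = len(az_vals) > 0
    hists = {
        "azimuth": np.histogram(az_vals, bins=n_bins, range=(0, np.pi),
                                density=dens or None),
        "polar": np.histogram(po_vals, bins=n_bins, range=(-np.pi, np.pi),
                              density=dens or None),
    }
    return edges, hists


def _hull_area(points: np.ndarray) -> float:
    return ConvexHull(points).volume  # in 2D, .volume is the area


def cluster_geometry(assign: ClusterAssignment, positions: np.ndarray) -> pd.DataFrame:
    """Per-cluster convex-hull area per cell in the transverse (x-y) view and
    the coronal-sagittal view (mean of the x-z and y-z hull areas), plus
    their ratio.  Clusters with fewer than 3 cells or collinear positions
    in a view are skipped and reported with NaNs."""
    positions = np.asarray(positions, dtype=float)
    rows = []
    for lab in np.unique(assign.labels):
        pts = positions[assign.labels == lab]
        row = dict(cluster=int(lab), n_cells=len(pts), transverse_per_cell=np.nan,
                   coronal_sagittal_per_cell=np.nan, ratio=np.nan)
        if len(pts) >= 3:
            def view_area(cols):
                try:
                    return _hull_area(pts[:, cols]) / len(pts)
                except QhullError:
                    return np.nan
            t = view_area([0, 1])
            cs = 0.5 * (view_area([0, 2]) + view_area([1, 2]))
            row.update(transverse_per_cell=t, coronal_sagittal_per_cell=cs,
                       ratio=t / cs if cs > 0 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def silhouette_test(
    assign: ClusterAssignment,
    positions_xy: np.ndarray,
    n_randomizations: int = 200,
    seed: int = 0,
) -> tuple[float, float, bool]:
    """Mean silhouette coefficient of the transverse positions under the
    cluster labels, against a null of label permutations.  ``segregated``
    when the coefficient exceeds the null's 95th percentile."""
    labels = assign.labels
    if len(np.unique(labels)) < 2:
        warnings.warn("single cluster: silhouette undefined", stacklevel=2)
        return np.nan, np.nan, False
    xy = np.asarray(positions_xy, dtype=float)
    coef = float(silhouette_score(xy, labels))
    rng = np.random.default_rng(seed)
    null = np.array([
        silhouette_score(xy, rng.permutation(labels))
        for _ in range(n_randomizations)
    ])
    p95 = float(np.percentile(null, 95))
    return coef, p95, bool(coef > p95)


def intra_inter_strength(
    graph: FunctionalGraph, assign: ClusterAssignment
) -> tuple[float, float, float]:
    """Mean Z-weighted strength of significant links within vs between
    communities, and the intra excess in percent: (intra/inter - 1)·100.
    Undefined (NaN) when one of the groups has no links."""
    edges = graph.significant()
    if edges.empty:
        raise ValueError("graph has no significant links")
    labels = assign.labels
    same = labels[edges["src"].to_numpy()] == labels[edges["dst"].to_numpy()]
    intra = edges.loc[same, "z"]
    inter = edges.loc[~same, "z"]
    intra_mean = float(intra.mean()) if len(intra) else np.nan
    inter_mean = float(inter.mean()) if len(inter) else np.nan
    if not len(inter) or not len(intra) or inter_mean == 0:
        warnings.warn("intra/inter excess undefined", stacklevel=2)
        return intra_mean, inter_mean, np.nan
    return intra_mean, inter_mean, (intra_mean / inter_mean - 1.0) * 100.0
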