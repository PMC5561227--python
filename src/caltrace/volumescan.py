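"""Tunable extended-depth-of-field (TEDOF) acquisition geometry and image
processing.

A tunable lens driven at frequency f_TL sweeps the in-focus plane through
the sample while a CCD acquires frames at f_CCD.  With f_CCD >> f_TL each
half-period yields a z-stack of floor((f_CCD/f_TL)/2) frames whose axial
positions follow the recorded lens voltage through a linear µm/V
calibration.  With f_TL >> f_CCD every exposure integrates the whole
axial excursion, producing a hardware-projected extended-depth-of-field
(EDOF) t-stack from which per-cell fluorescence traces are read.

Somata are segmented on the standard-deviation z-projection (morphological
background subtraction, binarization, erosion/dilation to discard thin
neurites, connected components) and localized axially at the frame where
their mean ROI intensity peaks; profiles with multiple prominent maxima
(axially aligned cells) are flagged and assigned to the highest maximum.

A synthetic volume generator renders Gaussian somata with
defocus-dependent lateral widening for end-to-end validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks
from skimage import measure, morphology, segmentation
from skimage.feature import peak_local_max

from .tracesim import TraceSet

__all__ = [
    "ScanConfig",
    "SegmentationParams",
    "RoiMap",
    "frames_per_halfscan",
    "voltage_to_um",
    "fit_calibration",
    "project_and_segment",
    "locate_axial",
    "extract_traces",
    "synth_volume",
]


@dataclass
class ScanConfig:
    """Acquisition geometry: CCD frame rate, lens drive frequency, voltage
    range, µm-per-volt calibration and pixel size."""

    f_ccd: float = 65.0
    f_tl: float = 0.140
    v_min: float = 0.0
    v_max: float = 5.0
    cal: float = 60.0        # µm per volt
    pixel_um: float = 3.75

    def __post_init__(self) -> None:
        if self.f_ccd <= 0 or self.f_tl <= 0:
            raise ValueError("frame and lens rates must be positive")
        if self.v_max <= self.v_min:
            raise ValueError("v_max must exceed v_min")
        if self.cal <= 0 or self.pixel_um <= 0:
            raise ValueError("cal and pixel_um must be positive")


@dataclass
class SegmentationParams:
    bin_thresh: float = 0.4      # fraction of the normalized projection
    min_roi_px: int = 3
    morph_px: int = 2            # erosion/dilation square element side (px)
    open_disk_px: int = 4        # background-opening disk radius (px)
    norm_percentile: float = 99.9  # histogram anchor for normalization
    split_touching: bool = True    # watershed-split merged somata
    peak_min_distance: int = 1     # px, marker separation for the split

    def __post_init__(self) -> None:
        if not 0 < self.bin_thresh < 1:
            raise ValueError("bin_thresh must be in (0, 1)")
        if self.min_roi_px < 1 or self.morph_px < 1 or self.open_disk_px < 1:
            raise ValueError("pixel parameters must be >= 1")


@dataclass
class RoiMap:
    """Detected somata: footprints (flat pixel indices into H x W), transverse
    centroids, axial positions and per-ROI axial intensity profiles."""

    table: pd.DataFrame              # roi_id, x_um, y_um, z_um, n_px, multi_peak
    footprints: list[np.ndarray]     # flat indices per ROI
    shape: tuple[int, int]
    pixel_um: float
    profiles: list[np.ndarray] = field(default_factory=list)

    @property
    def n_rois(self) -> int:
        return len(self.footprints)

    def positions_um(self) -> np.ndarray:
        return self.table[["x_um", "y_um", "z_um"]].to_numpy()


def frames_per_halfscan(f_ccd: float, f_tl: float) -> int:
    """Number of frames acquired during one half-period of the lens drive:
    floor((f_ccd/f_tl)/2).  A value of 0 indicates a misconfiguration
    (lens as fast as the camera)."""
    if f_ccd <= 0 or f_tl <= 0:
        raise ValueError("rates must be positive")
    return int((f_ccd / f_tl) / 2.0)


def voltage_to_um(v, config: ScanConfig):
    """Axial displacement for a lens voltage: (v - v_min) * cal."""
    return (np.asarray(v, dtype=float) - config.v_min) * config.cal


def fit_calibration(pairs) -> float:
    """Least-squares slope (µm per volt) through (volts, µm) calibration
    pairs.  Requires at least two distinct voltages."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 2 or pairs.shape[1] != 2:
        raise ValueError("need at least two (volts, um) pairs")
    v, z = pairs[:, 0], pairs[:, 1]
    if np.ptp(v) == 0:
        raise ValueError("degenerate calibration: all voltages identical")
    slope = np.polyfit(v, z, 1)[0]
    return float(slope)


def project_and_segment(
    zstack: np.ndarray,
    params: SegmentationParams | None = None,
    pixel_um: float = 3.75,
) -> RoiMap:
    """Detect soma ROIs on the standard-deviation z-projection.

    Pipeline: SD projection -> background estimate by morphological opening
    (disk smaller than a soma) subtracted -> normalize to [0, 1] ->
    threshold at ``bin_thresh`` -> binary erosion then dilation (removes
    thin/sharp components such as neurites) -> connected components ->
    drop components smaller than ``min_roi_px``.  Centroids are
    intensity-weighted and reported in µm.
    """
    params = params or SegmentationParams()
    zstack = np.asarray(zstack, dtype=float)
    if zstack.ndim != 3 or zstack.shape[0] < 2:
        raise ValueError("zstack must be frames x H x W with >= 2 frames")

    proj = zstack.std(axis=0)
    background = morphology.opening(proj, morphology.disk(params.open_disk_px))
    net = proj - background
    # robust intensity normalization: anchor the histogram at a high
    # percentile so a single bright outlier (e.g. axially stacked somata)
    # does not drag every other cell below the binarization threshold
    peak = np.percentile(net, params.norm_percentile)
    if peak <= 0:
        peak = net.max()
    if peak <= 0:
        return RoiMap(_empty_table(), [], proj.shape, pixel_um)
    # no upper clip: a hard ceiling would flatten the brightest somata into
    # plateaus and break peak detection
    net = net / peak
    binary = net > params.bin_thresh
    selem = np.ones((params.morph_px, params.morph_px), dtype=bool)
    binary = ndi.binary_dilation(ndi.binary_erosion(binary, selem), selem)
    if params.split_touching:
        # somata packed closer than their footprints bridge into single
        # components.  The SD projection blurs each soma with its defocused
        # frames, so neighbouring peaks fuse there; the max projection shows
        # every soma at its in-focus sharpness and separates them.  Markers
        # from the max projection, basins carved within the binary mask.
        mx = zstack.max(axis=0)
        mx = mx - morphology.opening(mx, morphology.disk(params.open_disk_px))
        anchor = np.percentile(mx, params.norm_percentile)
        if anchor > 0:
            mx = mx / anchor
        peaks = peak_local_max(
            mx, min_distance=params.peak_min_distance,
            threshold_abs=params.bin_thresh, labels=binary,
        )
        markers = np.zeros_like(binary, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = segmentation.watershed(-mx, markers, mask=binary)
    else:
        labels = measure.label(binary, connectivity=2)

    rows, footprints = [], []
    for region in measure.regionprops(labels, intensity_image=net):
        if region.area < params.min_roi_px:
            continue
        cy, cx = region.centroid_weighted
        flat = np.ravel_multi_index(
            (region.coords[:, 0], region.coords[:, 1]), proj.shape
        )
        footprints.append(flat)
        rows.append(
            dict(roi_id=len(rows), x_um=cx * pixel_um, y_um=cy * pixel_um,
                 z_um=np.nan, n_px=int(region.area), multi_peak=False)
        )
    table = pd.DataFrame(rows) if rows else _empty_table()
    return RoiMap(table, footprints, proj.shape, pixel_um)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["roi_id", "x_um", "y_um", "z_um", "n_px", "multi_peak"]
    )


def locate_axial(
    zstack: np.ndarray,
    rois: RoiMap,
    config: ScanConfig,
    voltages: np.ndarray,
    n_excursions: int = 1,
    multi_peak_rel_height: float = 0.5,
    profile_smooth_frames: int = 5,
) -> RoiMap:
    """Assign each ROI an axial position from its mean-intensity profile.

    z is the voltage (converted to µm) of the frame where the profile is
    maximal.  Profiles with more than one local maximum above
    ``multi_peak_rel_height`` of the global maximum — axially aligned
    cells — are flagged ``multi_peak`` and assigned to the highest
    maximum.  With ``n_excursions`` > 1 repeated back-and-forth sweeps are
    folded (odd sweeps reversed) and averaged before the argmax.
    """
    zstack = np.asarray(zstack, dtype=float)
    voltages = np.asarray(voltages, dtype=float)
    if voltages.size != zstack.shape[0]:
        raise ValueError("one voltage per frame required")

    flat_stack = zstack.reshape(zstack.shape[0], -1)
    zs, flags, profiles = [], [], []
    for fp in rois.footprints:
        profile = flat_stack[:, fp].mean(axis=1)
        volts = voltages
        if n_excursions > 1:
            per = profile.size // n_excursions
            folded = profile[: per * n_excursions].reshape(n_excursions, per)
            folded[1::2] = folded[1::2, ::-1]
            profile = folded.mean(axis=0)
            volts = voltages[:per]
        if profile_smooth_frames > 1:
            profile = uniform_filter1d(profile, size=profile_smooth_frames,
                                       mode="nearest")
        k = int(np.argmax(profile))
        zs.append(float(voltage_to_um(volts[k], config)))
        span = profile.max() - profile.min()
        peaks, _ = find_peaks(
            profile,
            height=multi_peak_rel_height * profile.max(),
            prominence=0.2 * span if span > 0 else None,
        )
        n_max = peaks.size
        # a maximum at the profile edge is not seen by find_peaks
        if profile[0] >= profile[1] and profile[0] >= multi_peak_rel_height * profile.max():
            n_max += 1
        if profile[-1] >= profile[-2] and profile[-1] >= multi_peak_rel_height * profile.max():
            n_max += 1
        flags.append(n_max > 1)
        profiles.append(profile)

    table = rois.table.copy()
    table["z_um"] = zs
    table["multi_peak"] = flags
    return RoiMap(table, rois.footprints, rois.shape, rois.pixel_um, profiles)


def extract_traces(tstack: np.ndarray, rois: RoiMap, fs: float) -> TraceSet:
    """Per-frame mean fluorescence within each ROI footprint of an EDOF
    t-stack."""
    tstack = np.asarray(tstack, dtype=float)
    npx = tstack.shape[1] * tstack.shape[2]
    flat = tstack.reshape(tstack.shape[0], -1)
    traces = np.empty((tstack.shape[0], rois.n_rois))
    for i, fp in enumerate(rois.footprints):
        if fp.max() >= npx:
            raise ValueError(f"ROI {i} footprint outside image bounds")
        traces[:, i] = flat[:, fp].mean(axis=1)
    return TraceSet(traces, fs)


def _render_frame(
    shape: tuple[int, int],
    xy_px: np.ndarray,
    amps: np.ndarray,
    sigmas_px: np.ndarray,
    cutoff: float = 4.0,
) -> np.ndarray:
    """Sum of 2D Gaussians, each rendered only inside a ±cutoff·sigma patch."""
    H, W = shape
    img = np.zeros((H, W))
    for (cx, cy), a, s in zip(xy_px, amps, sigmas_px):
        if a <= 0:
            continue
        r = int(np.ceil(cutoff * s))
        x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, W)
        y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, H)
        if x0 >= x1 or y0 >= y1:
            continue
        gx = np.exp(-0.5 * ((np.arange(x0, x1) - cx) / s) ** 2)
        gy = np.exp(-0.5 * ((np.arange(y0, y1) - cy) / s) ** 2)
        img[y0:y1, x0:x1] += a * np.outer(gy, gx)
    return img


def synth_volume(
    n_cells: int,
    volume_um: tuple[float, float, float] = (800.0, 800.0, 300.0),
    config: ScanConfig | None = None,
    traces: TraceSet | None = None,
    seed: int = 0,
    soma_sigma_um: float = 4.5,
    defocus_slope: float = 0.4,
    amp_range: tuple[float, float] = (0.7, 1.0),
    baseline: float = 0.2,
    photons: float | None = None,
    n_neurites: int = 0,
):
    """Render a synthetic z-stack, EDOF t-stack and ground-truth positions.

    Somata are Gaussian blobs (in-focus lateral sigma ``soma_sigma_um``)
    whose lateral width grows with defocus as
    sigma(dz) = sqrt(sigma0² + (defocus_slope·dz)²) while the peak
    amplitude falls as sigma0²/sigma(dz)² (photon conservation).  The
    z-stack samples ``frames_per_halfscan`` focal planes across the axial
    extent; the EDOF footprint of a cell is the mean of its defocused
    images over those planes.  If ``traces`` is given (clean fluorescence
    per cell) the t-stack renders baseline + trace through the EDOF
    footprints.  ``photons`` > 0 adds Poisson photon noise at that
    expected peak count.  Optional 1-px-wide straight neurites can be
    added to exercise the erosion step.

    Returns ``(zstack, tstack, positions_um, voltages)``; ``tstack`` is
    None when no traces are supplied.
    """
    config = config or ScanConfig()
    if any(v <= 0 for v in volume_um):
        raise ValueError("volume dimensions must be positive")
    rng = np.random.default_rng(seed)
    X, Y, Z = volume_um
    H = int(round(Y / config.pixel_um))
    W = int(round(X / config.pixel_um))
    n_frames = frames_per_halfscan(config.f_ccd, config.f_tl)
    z_planes = np.linspace(0.0, Z, n_frames)
    voltages = config.v_min + z_planes / config.cal

    pos = np.column_stack([
        rng.uniform(0, X, n_cells),
        rng.uniform(0, Y, n_cells),
        rng.uniform(0, Z, n_cells),
    ]) if n_cells else np.empty((0, 3))
    amps = rng.uniform(*amp_range, n_cells)
    xy_px = pos[:, :2] / config.pixel_um
    s0 = soma_sigma_um / config.pixel_um

    zstack = np.empty((n_frames, H, W), dtype=np.float32)
    edof = np.zeros((H, W))
    cell_foot = np.zeros((n_cells, H, W), dtype=np.float32) if traces is not None else None
    for k, zf in enumerate(z_planes):
        dz = pos[:, 2] - zf if n_cells else np.empty(0)
        sig_um = np.sqrt(soma_sigma_um**2 + (defocus_slope * dz) ** 2)
        a_k = amps * (soma_sigma_um / sig_um) ** 2
        frame = _render_frame((H, W), xy_px, a_k, sig_um / config.pixel_um)
        zstack[k] = frame
        edof += frame / n_frames
        if cell_foot is not None:
            for c in range(n_cells):
                patch = _render_frame(
                    (H, W), xy_px[c:c + 1], a_k[c:c + 1],
                    np.array([sig_um[c] / config.pixel_um]),
                )
                cell_foot[c] += patch / n_frames

    for _ in range(n_neurites):
        # 1-px-wide bright line: thin neurite surrogate
        r0 = rng.integers(0, H)
        zstack[:, r0, :] += 1.0
        edof[r0, :] += 1.0

    if photons is not None:
        zstack = rng.poisson(np.maximum(zstack, 0) * photons).astype(np.float32) / photons

    tstack = None
    if traces is not None:
        if traces.n_cells != n_cells:
            raise ValueError("one trace per cell required")
        vals = traces.clean if traces.clean is not None else traces.values
        drive = baseline + vals  # samples x cells
        flat_foot = cell_foot.reshape(n_cells, -1)
        tstack = (drive @ flat_foot).reshape(vals.shape[0], H, W).astype(np.float32)
        if photons is not None:
            tstack = rng.poisson(np.maximum(tstack, 0) * photons).astype(np.float32) / photons

    return zstack, tstack, pos, voltages
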