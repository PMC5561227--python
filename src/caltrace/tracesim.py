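"""Synthetic GCaMP-like fluorescence traces for detector benchmarking.

Calcium transients are modelled as the impulse response of a second-order
autoregressive (AR(2)) process whose two poles encode the rise and decay
time constants of the indicator.  Spikes are drawn from a homogeneous
Poisson process and unit-amplitude transients are superposed linearly;
white Gaussian noise is added with a variance calibrated to a target
signal-to-noise ratio (SNR), defined operationally as the maximum of the
slow (signal) component divided by the standard deviation of the residual
after low-pass filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import brentq
from scipy.signal import lfilter

__all__ = [
    "SimConfig",
    "SpikeTruth",
    "TraceSet",
    "ar2_coefficients",
    "ar2_from_time_constants",
    "ar2_impulse_response",
    "calibrate_decay_constant",
    "simulate",
    "estimate_snr",
]


@dataclass
class TraceSet:
    """Matrix of fluorescence traces, samples x cells, plus sampling rate.

    ``clean`` optionally carries the noiseless counterpart with the same
    shape.  Values are ΔF/F0 or arbitrary fluorescence units depending on
    provenance.
    """

    values: np.ndarray
    fs: float
    clean: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TraceSet values must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.clean is not None:
            self.clean = np.asarray(self.clean, dtype=float)
            if self.clean.ndim == 1:
                self.clean = self.clean[:, None]
            if self.clean.shape != self.values.shape:
                raise ValueError("clean and noisy traces must share a shape")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class SpikeTruth:
    """Ground-truth spike times (seconds) per cell."""

    times: list[np.ndarray]
    duration: float

    def __post_init__(self) -> None:
        clean = []
        for t in self.times:
            t = np.asarray(t, dtype=float)
            if t.size and (np.any(np.diff(t) <= 0) or t.min() < 0 or t.max() > self.duration):
                raise ValueError(
                    "spike times must be strictly increasing within [0, duration]"
                )
            clean.append(t)
        self.times = clean

    @property
    def n_cells(self) -> int:
        return len(self.times)

    def counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.times])


@dataclass
class SimConfig:
    """Parameters of the trace simulator.

    Defaults are the benchmark conditions: 0.05 Hz Poisson spiking, a
    0.5 s rise and 1 s half-decay GCaMP6s-like transient, SNR 9, 65 Hz
    sampling.  Trace duration defaults to 300 s (about 15 events per
    trace at the default rate).
    """

    rate: float = 0.05
    rise_tau: float = 0.5
    half_decay: float = 1.0
    snr_target: float = 9.0
    fs: float = 65.0
    duration: float = 300.0
    n_traces: int = 30
    seed: int = 0
    lowpass_window: float = 0.5  # seconds, for estimate_snr

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        for name in ("rise_tau", "half_decay", "fs", "duration", "snr_target"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_traces < 1:
            raise ValueError("n_traces must be >= 1")


def _continuous_peak_to_half(tau_d: float, tau_r: float) -> float:
    """Peak-to-half-peak time of h(t) = exp(-t/tau_d) - exp(-t/tau_r)."""
    t_peak = np.log(tau_d / tau_r) / (1.0 / tau_r - 1.0 / tau_d)

    def h(t: float) -> float:
        return np.exp(-t / tau_d) - np.exp(-t / tau_r)

    half = h(t_peak) / 2.0
    return brentq(lambda t: h(t) - half, t_peak, t_peak + 50.0 * tau_d) - t_peak


def calibrate_decay_constant(rise_tau: float, half_decay: float) -> float:
    """Decay time constant tau_d such that the double-exponential kernel
    exp(-t/tau_d) - exp(-t/rise_tau) falls from its peak to half the peak
    in exactly ``half_decay`` seconds.

    In the fast-rise limit (rise_tau -> 0) this reduces to the familiar
    single-exponential relation tau_d = half_decay / ln 2.  For a finite
    rise the rising exponential still subtracts from the tail near the
    peak, so tau_d must be found numerically.
    """
    if rise_tau <= 0 or half_decay <= 0:
        raise ValueError("time constants must be positive")

    def objective(tau_d: float) -> float:
        return _continuous_peak_to_half(tau_d, rise_tau) - half_decay

    lo = rise_tau * (1.0 + 1e-9)
    if objective(lo) > 0:
        raise ValueError(
            f"half_decay={half_decay} s is shorter than achievable with "
            f"rise_tau={rise_tau} s"
        )
    hi = max(2.0 * rise_tau, half_decay / np.log(2))
    while objective(hi) < 0:
        hi *= 2.0
    return brentq(objective, lo, hi)


def ar2_from_time_constants(tau_d: float, tau_r: float, fs: float) -> tuple[float, float]:
    """AR(2) coefficients whose impulse response samples the kernel
    exp(-t/tau_d) - exp(-t/tau_r) at rate ``fs``.

    The poles are p1 = exp(-1/(fs tau_d)) and p2 = exp(-1/(fs tau_r)),
    giving gamma1 = p1 + p2 and gamma2 = -p1 p2.
    """
    if tau_d <= 0 or tau_r <= 0 or fs <= 0:
        raise ValueError("time constants and sampling rate must be positive")
    p1 = np.exp(-1.0 / (fs * tau_d))
    p2 = np.exp(-1.0 / (fs * tau_r))
    return p1 + p2, -p1 * p2


def ar2_coefficients(rise_tau: float, half_decay: float, fs: float) -> tuple[float, float]:
    """AR(2) coefficients for a transient with the given rise time constant
    and half-decay time (peak to half-peak), sampled at ``fs`` Hz.

    Raises for non-positive or sub-sample time constants.
    """
    if rise_tau <= 0 or half_decay <= 0:
        raise ValueError("time constants must be positive")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if rise_tau <= 1.0 / fs or half_decay <= 1.0 / fs:
        raise ValueError("time constants must exceed one sample period")
    tau_d = calibrate_decay_constant(rise_tau, half_decay)
    return ar2_from_time_constants(tau_d, rise_tau, fs)


def ar2_impulse_response(
    gamma1: float, gamma2: float, n: int, normalize: bool = True
) -> np.ndarray:
    """Impulse response of the AR(2) recursion, optionally peak-normalized."""
    imp = np.zeros(n)
    imp[0] = 1.0
    h = lfilter([1.0], [1.0, -gamma1, -gamma2], imp)
    if normalize:
        peak = h.max()
        if peak <= 0:
            raise ValueError("impulse response has non-positive peak")
        h = h / peak
    return h


def _kernel_peak(gamma1: float, gamma2: float, fs: float, half_decay: float) -> float:
    # peak of the unnormalized AR(2) impulse response; 20 half-decays is
    # comfortably past the maximum
    n = max(16, int(20 * half_decay * fs))
    return ar2_impulse_response(gamma1, gamma2, n, normalize=False).max()


def simulate(config: SimConfig) -> tuple[TraceSet, SpikeTruth]:
    """Simulate noisy fluorescence traces and their ground-truth spikes.

    Each cell receives Poisson spike times at ``config.rate``; the clean
    trace superposes unit-amplitude AR(2) transients at the spike samples;
    white Gaussian noise is added with sigma = max(clean)/snr_target
    (falling back to the unit event amplitude for spikeless traces).
    Identical configs (including the seed) give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.fs))
    g1, g2 = ar2_coefficients(config.rise_tau, config.half_decay, config.fs)
    peak = _kernel_peak(g1, g2, config.fs, config.half_decay)

    clean = np.empty((n, config.n_traces))
    noisy = np.empty((n, config.n_traces))
    spikes: list[np.ndarray] = []
    for c in range(config.n_traces):
        k = rng.poisson(config.rate * config.duration)
        t = np.sort(rng.uniform(0.0, config.duration, size=k))
        # collapse (vanishingly rare) duplicate draws to keep times strictly
        # increasing
        t = np.unique(t)
        drive = np.zeros(n)
        idx = np.minimum((t * config.fs).astype(int), n - 1)
        np.add.at(drive, idx, 1.0)
        tr = lfilter([1.0 / peak], [1.0, -g1, -g2], drive)
        ref = tr.max() if t.size else 1.0
        sigma = ref / config.snr_target
        clean[:, c] = tr
        noisy[:, c] = tr + rng.normal(0.0, sigma, size=n)
        spikes.append(t)

    traces = TraceSet(noisy, config.fs, clean=clean)
    return traces, SpikeTruth(spikes, config.duration)


def estimate_snr(trace: np.ndarray, fs: float, window: float = 0.5) -> float:
    """Operational SNR of a trace: the slow (signal) component is a centred
    moving average of length ``window`` seconds, and

        SNR = max(lowpass(x)) / std(x - lowpass(x)).

    Constant traces have zero residual; ``inf`` is returned with a warning.
    """
    trace = np.asarray(trace, dtype=float)
    w = int(round(window * fs))
    w = max(w, 1) | 1  # odd, centred
    if trace.size < w:
        raise ValueError("trace shorter than the low-pass window")
    low = uniform_filter1d(trace, size=w, mode="nearest")
    resid = trace - low
    sd = resid.std()
    if sd == 0.0:
        warnings.warn("zero residual: SNR undefined, returning inf", stacklevel=2)
        return np.inf
    return float(low.max() / sd)
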