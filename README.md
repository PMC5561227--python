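# caltrace

Analysis toolkit for functional calcium imaging of three-dimensional
neuronal cultures: trace denoising with a modified Perona–Malik filter,
rule-based calcium-event detection, a calibrated GCaMP-like trace
simulator with a detection benchmark, tunable extended-depth-of-field
(TEDOF) z-stack soma localization, and network-level analysis
(SPIKE-synchronization, spike-train communities, transfer-entropy
connectivity, 3D link and cluster geometry).

## Who this is for

Labs imaging hydrogel-embedded 3D neuronal networks (or any dense
preparation recorded at tens of Hz with slow genetically encoded
indicators such as GCaMP6s) who need to go from raw image stacks to a
directed functional connectivity graph with 3D cell positions — and want
every step reproducible and benchmarkable against synthetic ground truth.

## The core methods

**Denoising.** The classical Perona–Malik filter evolves a trace u(x, t)
under ∂u/∂t = ∇·(g(|∇u|) ∇u) with the edge-stopping diffusivity

    g(s) = ½ (1 − (s/λ)²)²  for |s| < λ,   0 otherwise,

so smoothing stops where the local gradient exceeds the contrast
parameter λ. On fluorescence traces whose *noise* gradients exceed the
*signal* gradients this fails: large noise jumps freeze while genuine
slow transients diffuse. The modified filter replaces the pointwise
gradient by a non-local monotony measure over a forward window of δ
samples,

    LV_δ/(TV_δ + ε) = |u(x+δ) − u(x)| / (Σ |u(x_{i+1}) − u(x_i)| + ε),

which is ≈1 on monotone stretches (edges — diffusion stops) and ≪1 on
oscillatory noise (diffusion proceeds at full strength no matter how
large individual jumps are). Defaults: λ = 0.447, δ = 15, T = 10
explicit flux-form iterations; no-flux boundaries conserve the signal
sum, so ΔF/F0 normalization is unaffected.

**Event detection.** On the smoothed trace, an event requires (i) a
sustained positive derivative at the onset, (ii) a rise ΔF exceeding the
per-cell residual noise std(original − smoothed), (iii) a sustained
negative derivative at the offset, and (iv) a bounded gap between the end
of the rise and the offset. Peak amplitude and half-decay time (time
from the offset for the trace to fall below half the peak) are reported
per event.

**Simulator.** Transients are impulse responses of an AR(2) process whose
poles encode a 0.5 s rise constant and a 1 s half-decay; spikes follow a
homogeneous 0.05 Hz Poisson process; white Gaussian noise is calibrated
so the operational SNR — max of the low-pass component over the residual
std — hits a target (default 9). Detection sensitivity S = TP/(TP+FN)
of both filters is compared across SNR 8–11.

**Volumetric localization.** A tunable lens at f_TL sweeps focus while a
CCD at f_CCD acquires floor((f_CCD/f_TL)/2) frames per half-period
(232 frames at 65 Hz / 140 mHz, ≈300 µm). Somata are segmented on the
SD z-projection (opening-based background subtraction, binarization,
erosion/dilation against neurites, watershed splitting of touching
cells) and located axially at the frame of maximum mean ROI intensity;
profiles with several prominent maxima (axially stacked cells) are
flagged and assigned to the highest maximum.

**Network analysis.** Event rasters feed the multivariate
SPIKE-synchronization index, bin-size-scanned modularity clustering of
event trains, and pairwise transfer entropy TE(Y→X) (order m = 1, bits)
tested against 200 inter-event-interval-preserving shuffles with a
per-pair 95th-percentile rule; significant links get azimuth/polar
orientation angles and clusters get transverse vs coronal-sagittal
convex-hull area ratios plus a silhouette permutation test.

## Worked example

```python
from caltrace import (SimConfig, simulate, pm_classic, pm_modified,
                      detect_events, estimate_snr, match_events)

cfg = SimConfig(rate=0.05, snr_target=9.0, fs=65.0, duration=300.0,
                n_traces=1, seed=42)
traces, truth = simulate(cfg)
x = traces.values[:, 0]
print(f"simulated {len(truth.times[0])} events, estimated SNR = "
      f"{estimate_snr(x, cfg.fs):.2f}")

for name, filt in [("classic", pm_classic), ("modified", pm_modified)]:
    sm = filt(x)
    events = detect_events(sm, fs=cfg.fs)
    m = match_events(truth.times[0], [e.onset_s for e in events], tolerance=0.5)
    print(f"{name:>8}: TP={m.tp} FP={m.fp} FN={m.fn}  S={m.tp/(m.tp+m.fn):.3f}")
```

prints

```
simulated 18 events, estimated SNR = 8.79
 classic: TP=17 FP=143 FN=1  S=0.944
modified: TP=17 FP=182 FN=1  S=0.944
```

The simulator hit its SNR target (8.79 ≈ 9), and on this single trace
both filters recover 17 of 18 events. The FP counts look large because
the detection thresholds are deliberately permissive (10⁻³ per sample at
65 Hz) and the rise threshold sits at one residual-noise standard
deviation, so segments at the noise floor pass occasionally; sensitivity
S, the benchmark quantity, only scores recovered true events. Averaged
over 30 traces per SNR (`caltrace benchmark` or
`caltrace.benchmark.run_sweep`) the modified filter's sensitivity is
consistently at least the classical filter's at every SNR in 8–11.

A full synthetic experiment — volume rendering, segmentation, axial
localization, trace extraction, ΔF/F0, detection, network statistics —
runs end to end with:

```bash
caltrace pipeline --seed 1 --outdir run1
```

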