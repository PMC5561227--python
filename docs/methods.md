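# Methods

This note records the models, parameter choices and numerical decisions
behind `caltrace`, what the synthetic data do and do not emulate, and the
known limitations.

## Trace simulator (`caltrace.tracesim`)

Calcium transients are modelled as the impulse response of an AR(2)
recursion u_n = γ₁u_{n−1} + γ₂u_{n−2} + s_n driven by a spike indicator
s. The two poles p₁ = exp(−1/(f_s τ_d)) and p₂ = exp(−1/(f_s τ_r)) give
γ₁ = p₁ + p₂, γ₂ = −p₁p₂, i.e. the sampled double exponential
e^{−t/τ_d} − e^{−t/τ_r}. The user specifies the rise constant τ_r
(default 0.5 s) and the *half-decay time* (default 1 s), defined as the
time the transient takes to fall from its peak to half the peak. Because
the rising exponential still subtracts from the tail near the peak,
τ_d is **calibrated numerically** (Brent root-finding on the continuous
kernel) so the measured half-decay equals the requested one; the
closed form τ_d = t_half/ln 2 is recovered only in the fast-rise limit
τ_r → 0. With (0.5 s, 1 s) the calibration yields τ_d ≈ 0.699 s and the
65 Hz sampled kernel falls to half peak in 66 samples (1.015 s).

Spikes are homogeneous Poisson (default 0.05 Hz); events superpose
linearly with unit amplitude (no amplitude distribution is modelled).
Noise is white Gaussian with σ = max(clean)/SNR_target (unit reference
for spikeless traces). Defaults 65 Hz and 300 s give ≈15 events per
trace; the duration is a package choice made once to provide adequate
event statistics.

**Operational SNR.** SNR = max(lowpass(x)) / std(x − lowpass(x)) with a
centred 0.5 s moving average. The maximum is taken over the *low-pass
(signal) component*, not the raw trace: the raw maximum rides on the
noise excursions at transient peaks and overestimates SNR by ≈20% at
SNR 9, which would break the simulate→estimate calibration loop. With
this definition the loop closes to within a few percent for targets
8–11.

## Diffusion filters (`caltrace.diffusion`)

Explicit flux-form Euler on a unit grid: u_i ← u_i + dt·(F_{i+1/2} −
F_{i−1/2}), F = g·Δu, with replicate (no-flux) boundaries, dt = 1, and
T = 10 meaning 10 iterations. Stability and a discrete maximum principle
hold because g ≤ ½ so dt·(g_L + g_R) ≤ 1. Diffusivities are recomputed
from the current iterate each step (scale-space semantics). For the
modified filter, the edge between samples i and i+1 takes g at the LV/TV
ratio anchored at the left node with a *forward* window [i, i+δ] clipped
at the right boundary; ε = 10⁻¹² guards the division. For a sampled
signal the total variation over the window is the sum of absolute
successive differences (the supremum over partitions is attained by the
finest partition).

Numerical notes:

- Both filters conserve the trace sum to ~10⁻¹⁰ relative (flux form), so
  ΔF/F0 normalization commutes with smoothing.
- The modified filter is idempotent on traces whose every δ-window is
  strictly monotone (ratio ≈ 1 ≥ λ ⇒ g = 0).
- Total smoothing is **not** monotone in λ for the iterated filter: as λ
  grows past ≈0.45 the early iterations also erode edges, which lowers
  subsequent LV/TV ratios and reduces net transport. Only the
  single-update transported mass Σ g(·, λ)|Δu| is monotone in λ, and
  that is the property the tests assert.

The baseline estimator F0(t) is heavy *linear* diffusion, implemented as
Gaussian smoothing with σ = window/4 (window 30 s by default), replicate
boundaries. ΔF/F0 = (F − F0)/F0 requires a strictly positive baseline
and names the offending cell otherwise.

## Event detection (`caltrace.events`)

The four acceptance rules on the smoothed trace:

1. **Onset**: every forward difference in a right interval of
   `right_interval` samples (default 5, ≈77 ms at 65 Hz) exceeds the
   onset threshold (10⁻³ ΔF/F0 per sample by default).
2. **Amplitude**: u(offset) − u(onset) > std(original − smoothed),
   computed per cell over the whole trace.
3. **Offset**: every forward difference in the right interval falls
   below the offset threshold (−10⁻⁴ per sample).
4. **Width**: the gap between the last supra-threshold derivative sample
   after the onset and the offset stays below `max_width` (300 samples;
   600 for populations with slow global onsets).

The *sustained* (all-samples) reading of rules 1 and 3 is deliberate: a
mean-derivative reading makes the 10⁻³ threshold vacuous against the
derivative noise of a smoothed 65 Hz trace (≈0.06 of its standard
deviation), floods the benchmark with noise-floor detections and lets
coincidental matches mask the difference between the two filters. With
the sustained reading the filter comparison is stable across seeds.
Scanning is greedy left-to-right, so events never overlap. The
population-level parameter selection runs a provisional detection on the
mean trace: transients present ⇒ onset threshold 10⁻², and mean rise
times above 5 s ⇒ max_width 600.

Residual false positives at the noise floor remain (the amplitude
threshold sits at one residual standard deviation); they scale with
trace length and are the reason benchmark matching uses a 0.5 s
tolerance — wide enough for the ≲0.2 s detection latency, narrow enough
that coincidences do not dominate. A consequence worth knowing: at low
SNR the classical filter's higher false-positive rate *raises* its
measured sensitivity through chance matches, so S-versus-SNR trends per
filter are confounded and are not treated as a result.

## Detection benchmark (`caltrace.benchmark`)

Per SNR ∈ {8, 9, 10, 11}: 30 simulated traces, both filters, identical
detection parameters (so differences isolate the diffusivity), greedy
one-to-one chronological matching within ±0.5 s, sensitivity
S = TP/(TP+FN), and ΔS = S_modified − S_classic. The full sweep runs in
well under a minute on one CPU. ΔS ≥ 0 at every SNR across seeds; the
classical filter loses sensitivity mainly by freezing large noise jumps
(its edge-stop argument is the raw gradient) which fragments rises and
pushes event segments under the amplitude threshold.

## Synthetic volumes and TEDOF scanning (`caltrace.volumescan`)

The generator plants n somata uniformly in an X × Y × Z µm box (default
800 × 800 × 300, 3.75 µm pixels) as Gaussian blobs with in-focus lateral
σ₀ = 4.5 µm (FWHM ≈ 10.6 µm, a realistic soma) and brightness uniform in
[0.7, 1]. Defocus widens the blob as σ(dz) = √(σ₀² + (0.4·dz)²) while
the peak falls as σ₀²/σ(dz)² (photon conservation); Poisson photon noise
is optional. The z-stack samples floor((f_CCD/f_TL)/2) focal planes
across Z; the EDOF footprint of a cell is the mean of its defocused
images over those planes, and the t-stack renders baseline + trace
through the footprints. The generator does **not** model neurite
morphology (beyond optional 1-px test lines), scattering, bleaching,
non-Gaussian PSF structure, or motion — recovery results certify the
pipeline's geometry handling, not robustness to those effects.

Segmentation follows SD-projection → background subtraction by
morphological opening (disk radius 4 px, smaller than a soma) →
normalization anchored at the 99.9th intensity percentile → threshold
(0.4 of the normalized range) → erosion/dilation with a 2×2 square
(removes 1-px neurites; implemented with scipy morphology, which keeps
even footprints shift-free) → watershed splitting of touching
components with markers from the background-subtracted *max* projection
(each soma appears there at in-focus sharpness; in the SD projection
neighbouring somata blur together) → components ≥ 3 px. Two choices
depart from the plainest reading of the workflow and are worth
flagging: the percentile normalization (a raw-max anchor lets one
axially stacked bright pair drag every other cell below threshold) and
the watershed split (at 400 cells per volume ~30% of somata bridge
transversally; without the split, recovery saturates near 70%). Both
are exposed as `SegmentationParams` knobs.

Axial localization: per-ROI mean-intensity profile over frames,
optionally folded over repeated back-and-forth excursions, smoothed with
a 5-frame moving average; z is the voltage of the argmax frame mapped
through the linear µm/V calibration. Profiles with >1 local maximum
above half the global maximum (prominence ≥ 0.2 of the span, to ignore
noise ripples) are flagged `multi_peak` and assigned to the highest
maximum. At 400 cells per volume this pipeline recovers ≥ 90% of planted
somata with sub-µm transverse and ≈1 µm median 3D error; multi-peak
flags sit at a few percent.

## Network analysis (`caltrace.netdyn`)

- **SPIKE-synchronization**: for each event and each partner train, a
  coincidence counts when the nearest partner event lies within
  τ = ½·min of the up-to-four surrounding inter-event intervals; the
  index averages coincidences over all events and ordered pairs. Trains
  with no surrounding intervals fall back to τ = ∞.
- **Communities**: event counts binned at each of 10 log-spaced bin
  sizes in [0.01, 1] s; cosine similarity between cells;
  modularity-maximizing partition (greedy agglomeration, deterministic);
  the bin size with the highest modularity wins and the number of
  communities is an output. On small instances the chosen partition
  attains the exhaustive-search optimum.
- **Transfer entropy**: plug-in estimate on the binary frame-resolution
  raster, order m = 1, base-2 logarithm (bits), 0·log 0 = 0. The null
  shuffles the source train by permuting its inter-event gaps (IEI
  multiset preserved exactly, first event fixed); Z = (TE − μ_null)/σ_null
  and significance is per-pair: TE above the null's 95th percentile
  (one-sided p < 0.05). False-positive calibration on independent
  trains lands at the nominal 5%.
- **Geometry**: azimuth = angle to the z-axis ∈ [0, π], polar = angle in
  the x-y plane (the axial-scanning community's naming, kept here);
  cluster areas are convex hulls per view divided by member count, with
  the coronal-sagittal view taken as the mean of the x-z and y-z hull
  areas; the silhouette test compares the labelled transverse silhouette
  coefficient against the 95th percentile of label permutations.

## Pipeline (`caltrace.pipeline`)

One seed fans out to per-stage child seeds through
`numpy.random.SeedSequence`, so stages are independently reproducible
and a rerun with the same configuration is byte-identical. Every stage
persists its output (HDF5/CSV/TIFF) and a JSON manifest records the
configuration, seeds, timings and status. The all-pairs transfer-entropy
stage is capped at `te_max_cells` (default 20) cells because it costs
O(n²·shuffles·samples); the cap is a configuration value, not a
correctness constraint.

## Problem sizes used in validation

Tests and the acceptance script use the generator defaults (300 s
traces at 65 Hz, 30 traces per SNR, 1000 traces for the rate check,
400 somata in an 800 × 800 × 300 µm volume) except where a smaller
instance suffices to pin an exact property (oracle equivalences on
traces of length ~100, 6-node community graphs, 20-sample TE
histograms). The end-to-end pipeline test runs a reduced 25-cell,
40 s configuration; it exercises every stage, not the statistics.

## Known limitations

- The event detector's thresholds are per-sample quantities; at sampling
  rates far from 65 Hz they need rescaling, which `auto_select_params`
  does not do automatically.
- Detection at the noise floor produces false positives at ~0.1–1 Hz on
  pure-noise stretches at SNR 8–11; downstream network statistics on
  *real* data should use the amplitude field to filter if a stricter
  event list is needed.
- The TE estimator is a plug-in estimator without bias correction;
  with very sparse rasters the shuffled null absorbs most of the bias
  but short recordings will under-detect weak links.
- The silhouette permutation test on very small clusters (≲4 cells per
  group) is degenerate because the true labelling reappears among
  permutations.
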