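# Methods

This document describes the models implemented in `stonebeam`: how the
synthetic phantoms and raw channel data are generated, how each beamformer is
defined, how stone and shadow metrics are computed, and what the statistical
pipeline does. It also states the assumptions and the known limitations of
the simulation.

## 1. Acquisition model

A 1-D linear array of `n_elements` point-like elements (default 128) with
pitch `pitch` (default 0.298 mm) lies on the `z = 0` line. A plane-wave
acquisition fires one unfocused wave per steering angle θ and records the
backscattered field on all elements simultaneously. Two presets mirror the
two experimental settings of the study:

| preset | f0 | angles | c | depth | use |
|---|---|---|---|---|---|
| `in_vitro_preset` | 5.2 MHz | −30°…30° in 1° steps (61) | 1480 m/s | 10 cm | water-bath stone phantoms |
| `in_vivo_preset` | 3.0 MHz | −15°…15° in 1° steps (31) | 1540 m/s | 12 cm | tissue-depth configuration |

The sample rate defaults to 12 samples per carrier period; configurations
below 4·f0 are rejected (`ConfigurationError`).

### Pulse

The transmit pulse is a two-cycle cosine under a Hann window,
`p(t) = cos(2π f0 t) · hann(t)` for `|t| ≤ n_cycles/(2 f0)`. This pulse has
zero area, so the analytic envelope of summed echoes carries no DC pedestal —
a property the Rayleigh speckle statistics below rely on.

### Scattering and echo synthesis

Scenes are collections of point scatterers `(x, z, amplitude)`. Under the
first-order Born approximation each scatterer contributes, on receive element
`i` for steering angle θ:

```
echo(t) = a · T(x, z) · p(t − τ_tx − τ_rx,i)
τ_tx    = (z cosθ + x sinθ) / c
τ_rx,i  = sqrt((x − x_i)² + z²) / c
```

`T(x, z)` is the shadow transmission factor (see below). Spikes are deposited
onto the sample grid with a Keys cubic fractional-delay kernel and the result
is convolved with the pulse (FFT convolution). Channel data are stored as
`float32`; the time origin `t0` is floored to the sample grid. Receiver noise
is i.i.d. Gaussian per sample, seeded from the acquisition seed.

Geometric spreading, frequency-dependent attenuation, and element directivity
are deliberately omitted (see Limitations); amplitudes are therefore
depth-independent, which keeps region statistics comparable across depths.

### Phantoms

`make_stone_phantom(width_mm, ...)` builds the in vitro scene:

- **Background speckle**: uniformly distributed scatterers with unit-variance
  Gaussian amplitudes at `density` scatterers per squared wavelength
  (default 10/λ²) over the field of view.
- **Stone**: a rough, strongly reflecting slab of the requested width
  (thickness `min(width, 1.5)` mm, centred at `depth_cm`, default 8 cm),
  realised as a λ/4 grid of strong scatterers jittered by ±λ/8 so the surface
  scatters like a rough rigid body rather than a specular mirror.
- **Shadow**: every background scatterer geometrically behind the stone
  (inside the straight-edge occlusion region) has its echo multiplied by
  `shadow_transmission` (default 0.1), i.e. the stone transmits 10% pressure
  amplitude. This is a ray-acoustics shadow; edge diffraction is not
  modelled.

`make_speckle_phantom` builds a stone-free speckle block for calibration
experiments.

## 2. Beamformers

All beamformers share the same delay model. For pixel `(x, z)`, angle θ and
element `i`, the round-trip delay is `τ_tx(θ; x, z) + τ_rx,i(x, z)` and
traces are read with linear fractional-delay interpolation (the residual
interpolation error scales as `(f0/fs)²`; at the default 12 samples per cycle
it is ≈2% RMS).

- **B-mode (`das_bmode`)**: conventional delay-and-sum with a *fixed* receive
  focus: receive delays are computed for the focal depth (default 40 mm;
  the study display uses 65 mm) at every pixel, emulating a fixed-focus
  system. Envelope via Hilbert transform, then coherent compounding over
  angles happens before envelope detection.
- **PWSF (`pwsf`)**: plane-wave synthetic focusing — dynamic-receive
  delay-and-sum at every pixel, coherently compounded over all angles. This
  is the synthetic-aperture reference image.
- **SLSC (`slsc_image`)**: for each pixel, traces from all elements are
  delay-aligned (after coherent compounding over angles, "coherent prefocus")
  into a patch of `kernel_samples` axial samples; the normalised spatial
  coherence `R̂(m)` is averaged over all element pairs at lag `m`, and the
  pixel value is `Σ_{m=1}^{Q} R̂(m)` clipped at 0. `Q = max(2, round(0.05 N))`
  (Q = 6 for 128 elements) — the *short-lag* region.
- **MLSC (`mlsc_image`)**: the same coherence curve evaluated *per steering
  angle* (incoherent compounding: the per-angle band sums are added), summed
  over the *mid-lag* band `[M1, M2] = [round(0.2 N), round(0.5 N)]`
  (lags 26–64 for 128 elements). Mid lags suppress diffuse speckle (whose
  coherence has fallen off) while a rough coherent stone retains long-range
  coherence, which raises stone contrast; because the diffuse background —
  including the shadow — is suppressed toward the same low level, MLSC
  largely *removes* the posterior shadow. MLSC requires ≥ 2 angles.

SLSC/MLSC pixel values are bounded by `Q` and `n_angles · (M2 − M1 + 1)`
respectively and are invariant to overall gain.

### Coherence theory used for validation

For fully developed speckle and a uniformly weighted transmit aperture, the
van Cittert–Zernike theorem predicts a triangular receive coherence,
`R(m) ≈ 1 − m/N`. Two simulation caveats matter and are handled in the
validation experiments rather than by changing the study configuration:

- The −1/N slope requires the *synthesized transmit* aperture (set by the
  angle span, `D_tx ≈ 2 z tan θ_max`) to match the receive aperture. The in
  vitro preset (±30°, 128 elements at 40 mm depth) satisfies this.
- A discrete angle set replicates the synthetic transmit beam at lateral
  period λ/Δθ (≈16 mm for 1° steps at 5.2 MHz). Speckle blocks used for
  coherence calibration are kept narrower than this so the replicas carry no
  scatterers.
- Rayleigh envelope statistics (SNR = mean/std = 1.91) require enough
  scatterers per *compounded* resolution cell; compounding shrinks the cell
  ≈3× relative to a single plane wave, so speckle-statistics experiments use
  `density = 30/λ²` while the study phantoms keep the default.

## 3. Metrics

All region statistics are computed on linear (not log-compressed) images over
rectangular ROIs derived from the simulation truth:

- **Stone contrast**: `20 log10(μ_stone / μ_background)` (positive = bright).
- **Shadow contrast**: `−20 log10(μ_shadow / μ_gel)` (positive = dark
  shadow).
- **CNR**: `20 log10(|μ_stone − μ_bg| / sqrt(σ_stone² + σ_bg²))`.
- **SNR**: `μ_bg / σ_bg` (speckle SNR; 1.91 for Rayleigh speckle).
- **Stone width**: lateral extent of the −6 dB contour around the brightest
  pixel in a search band at the stone depth; sizing error is
  `measured − reference` in mm.

Zero-mean regions yield `−inf` sentinels; degenerate inputs raise
`UndefinedMetricError`.

## 4. Shadow segmentation

Shadows are measured without access to the simulation truth:

1. The log-compressed display image is normalised to [0, 1] and segmented
   into 3 classes by an iterated-conditional-modes Markov random field
   (`segment_classes`): k-means-style class means plus a Potts smoothness
   term with weight β (default 1.0), swept until the labelling is stable.
2. `extract_shadow` looks for the dark class in a band below the known stone
   depth. A shadow is *detected* only if (a) a straight vertical band fits
   the dark region within tolerance, (b) the dark rows cover ≥ 40% of the
   band (`min_row_coverage = 0.4`), and (c) the band is at least 2 dB darker
   than its surroundings (`min_depth_dB = 2.0`). Detected shadows report a
   width (median dark-run length across rows); undetected ones report
   `width_mm = NaN`.

The segmenter never sees scene parameters other than the stone depth used to
position the search band (blinding is enforced by the function signature).

## 5. Study pipeline and statistics

`run_phantom(width_mm, seed)` simulates one phantom at the study operating
point and measures all four beamformers; `run_cohort(seed=...)` runs the
default cohort of 10 phantoms with stone widths 2–18 mm (phantom *i* uses
seed `seed + i`).

**Study operating point** (frozen defaults): receiver noise RMS 76.0 (sets a
realistic channel SNR for the unit-amplitude speckle model), B-mode display
focus 65 mm (deliberately off the 80 mm stone depth, as for a fixed-focus
clinical system), shadow acceptance thresholds as above.

`build_report` produces paired comparisons of each method against a baseline
(default B-mode): per-phantom deltas of stone contrast, CNR, SNR, sizing
error and shadow contrast, tested with two-sided paired t-tests at a
Bonferroni-corrected level (α = 0.05 / number of comparisons; 0.0125 for 4
stone comparisons, 0.01 when sizing is included). Shadow deltas use only
phantoms where both methods detected a shadow; methods whose shadow-detection
rate is too low are reported as "n/a" rather than tested. An exact/Monte
Carlo sign-flip permutation test (`sign_flip_permutation_p`) is provided as a
small-sample cross-check of the t-test.

`pilot_cohort()` ships the six-subject pilot measurements (skin-to-stone
distance, BMI, CT stone size) and `cohort_summary` reproduces their
mean/SD/min/max table at display rounding.

## 6. Command-line interface

`stonebeam` exposes the pipeline as subcommands driven by an INI
configuration: `simulate` (phantoms → HDF5 channel data + JSON manifest),
`beamform` (→ float TIFF images + display PNGs), `measure` (→ metrics CSV),
`report` (→ summary/comparison CSVs), and `run-all`. Only the four
implemented beamformers are accepted; requesting `admire` explains that
model-based aperture-domain decomposition is out of scope (see Limitations).

## 7. Limitations

- **2-D, linear, lossless medium.** No elevation dimension, no attenuation,
  no phase aberration, no multiple scattering, no geometric spreading, and
  no element directivity. Consequently absolute contrast values are not
  calibrated against any physical scanner; only *relative* method
  comparisons are meaningful.
- **Ray-acoustics shadow.** The straight-edge occlusion with a single
  pressure-transmission factor ignores edge diffraction, refraction, and
  reverberation, which in practice soften shadow boundaries.
- **Rigid rough stone model.** The stone is a jittered grid of strong point
  scatterers; internal structure, absorption, and twinkling artefacts are
  not modelled.
- **No ADMIRE.** The model-based aperture-domain filtering method discussed
  alongside coherence beamforming in the literature requires a fitted
  aperture-domain signal model and is qualitatively different from the
  coherence measures implemented here; it is explicitly out of scope, and
  the CLI rejects it with an explanatory message rather than approximating
  it.
- **Fixed ROIs from truth.** Stone/background/shadow/gel ROIs come from the
  known geometry. This isolates beamformer differences but is more
  favourable than fully manual or fully automated clinical ROI placement
  (shadow *detection*, in contrast, is fully automated and blinded).
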