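# Methods

`vtsr` reconstructs super-resolved isotropic dynamic 3D volumes of a
vocal-tract-like object from overlapping thick-slice 2D dynamic image
series that were acquired in separate, temporally misaligned repetitions.
This note documents the models, the choices made where the design was
genuinely open, and what the synthetic phantom does and does not show.

## Acquisition model

The geometry mirrors a real-time multi-slice speech MRI protocol: 25
sagittal slice positions, 8 mm slab thickness, 1.6 mm shift between
positions, 1.6 × 1.6 mm² in-plane resolution, 50 frames/s (20 ms frame
period), and 16 kHz audio recorded simultaneously with marker indices
standing in for the scanner's TTL event log. Because the slab thickness is
five times the shift, the 25 positions regroup into five anisotropic
stacks whose slabs tile the volume at five sub-thickness offsets — the
redundancy the super-resolution inversion exploits.

Two protocols are simulated: `S1_single` (one slice per repetition,
acquired center → right laterals → left laterals) and `S2_grouped`
(5 groups of 5 slices 8 mm apart, groups shifted by 1.6 mm, slices within
a group sharing one repetition's timing and motion state).

## Synthetic phantom

No public data set exists for this kind of acquisition, so all validation
runs on a parametric phantom (`vtsr.phantom`) built to reproduce the
*statistical* structure the pipeline must handle, not anatomy:

- a bright elliptic-cylinder "tissue" slab (intensity 0.75). The static
  in-plane profile is identical on every slice-direction plane so that
  neighboring 8 mm slabs agree on static anatomy — a property real heads
  have to good approximation over 1.6 mm and that chained registration
  needs;
- an airway-like cavity carved into the tissue whose aperture along all
  three axes follows a smooth scalar motion state `s(t) ∈ [0, 1]`. The
  trajectory is a sum of two incommensurate sinusoids (1.1 Hz and
  0.47 Hz): strictly periodic motion would make time alignment ambiguous
  up to whole cycles. Cavity boundaries get a ≈1-voxel partial-volume
  ramp, matching the band-limited appearance of reconstructed MR frames;
- a one-voxel-thick bright septum plane (intensity 1.0) perpendicular to
  the slice direction: inside an 8 mm slab it contributes 1/5 of its
  contrast, so it is unresolvable in any single stack and probes genuine
  sub-slice-thickness recovery;
- a static "nose" analog: two apodized patches of smooth seeded texture
  spread across the image. They give the registration ROI rich gradients
  and a long rotation lever arm; their texture seed is fixed (anatomy is
  not an experiment variable). The patches sit away from the image border
  so rigid jitter cannot drag zero-fill into the ROI;
- per-repetition perturbations: a random monotone piecewise-linear time
  warp with segment slopes in `1 ± warp_strength` (default 0.2), a random
  in-plane rigid offset bounded by `rigid_jitter` (default 2 mm / 2°), and
  i.i.d. Gaussian pixel noise;
- synthetic audio per repetition: a frequency-modulated tone
  (300–2500 Hz) whose instantaneous frequency tracks the motion state
  under that repetition's warp, over a small fixed noise floor. The FM
  tone gives the cepstrogram the time-localizable structure that speech
  provides in real recordings.

Default noise is `noise_sigma = 0.0125` relative to the ~1 foreground
intensity. With the phantom's foreground mean of 0.75 this puts the
native-stack SNR near 60, inside the 47–76 range measured on the two
in-vivo subjects this protocol was developed with.

What the phantom does *not* emulate: MRI contrast physics and k-space
sampling artifacts, articulator-specific shapes, imperfect speech
reproducibility beyond a global time warp (a speaker never repeats motion
exactly even after perfect alignment), out-of-plane motion, and spatially
correlated reconstruction noise. Passing tests therefore demonstrate the
pipeline's correctness and its behavior under the modeled perturbations,
not clinical image quality.

## Temporal alignment

Per repetition, a short-time real cepstrum is computed with a 1024-sample
Hann window hopped by 64 samples and a log-floor of 1e-10; the first 64
quefrency coefficients are kept. The hop of 64 yields one feature frame
per 64 audio samples (250 Hz at 16 kHz), realized as hop-64 short-time
analysis rather than literal decimation of a per-sample cepstrum — the
same rate at a fraction of the cost. A single PCA is fitted on the
concatenated cepstra of one alignment task (reference plus all queries) —
a shared basis is required for comparable distances — and each track keeps
the first 20 components.

Dynamic time warping uses Euclidean frame distance, steps
{(0,1), (1,0), (1,1)}, full-path boundary conditions, and deterministic
diagonal-preferring tie-breaks. Full-rate audio is warped piecewise: the
waveform is cut into 64-sample pieces, pieces are repeated or dropped per
the path, and samples inside a piece are never altered or resampled.

The warp path is projected onto image frames (5 feature slots per 20 ms
frame) by taking, per reference image frame, the median matched query
feature index over its slots and assigning the query image frame that owns
that slot. The median absorbs single-frame path jitter. On synthetic
audio pairs with slopes in [0.7, 1.3] this recovers the true frame
correspondence within ±1 image frame for ≈99 % of frames.

## Rigid registration

Each lateral slice is registered to its medially adjacent,
already-registered neighbor by maximizing Pearson correlation inside the
static-anatomy ROI; the right chain runs center → lateral, then the left
chain, and the central slice is never moved. One global transform per
slice is estimated from the temporal-mean image (the ROI anatomy does not
move during speech, so temporal averaging only suppresses noise); a
per-frame variant exists behind a flag. Rotation is about the image
center — any fixed center is equivalent up to translation.

The optimizer is BFGS with numerical gradients, seeded by a coarse grid
scan over integer-pixel shifts (±4 px) and whole-degree rotations (±4°),
and both images are Gaussian pre-smoothed (σ = 1 px) before correlating.
The pre-smoothing matters: bilinear resampling imprints a subpixel ripple
on the correlation objective whose bias (~0.1 px) would otherwise exceed
the chained error budget. With these choices, injected per-slice motion up
to 3 mm / 3° at noise σ = 0.05 is recovered so that the composition
(injected ∘ estimated) stays within 0.2 mm and 0.2° of identity across
the whole chain. Recovery is always measured by that composition — the
exact inverse of a rotation+translation is not parameter negation.

## Super-resolution inversion

Per time point, the aligned 25-slice volume is regrouped into 5 shifted
stacks and the isotropic volume `x` (29 × H × W; the SR grid covers the
union of all slabs, so edge voxels with partial coverage are reconstructed
rather than cropped) solves

    x = argmin_x  Σ_i ‖D_i B_i M_i x − ρ_i‖²  +  λ C(x)

with `M_i` a shift by `i` SR voxels (zero fill), `B_i` a 5-voxel box mean
(the ideal slab profile; no Gaussian profile option in v1), and `D_i`
keep-every-5th-plane downsampling. In-plane resolution is unchanged, so
`D_i` acts only along the slice axis.

- **Tikhonov** (`C(x) = ‖x‖²`, default λ = 1e-6): conjugate gradients on
  the normal equations from zero initialization.
- **Beltrami** (`C(x) = Σ √(1 + β²|∇x|²)`, defaults λ = 5e-5, β = 1):
  forward-difference gradients with Neumann boundaries and a Condat–Vũ
  primal-dual iteration using the exact dual representation
  `√(1+β²|g|²) = max_{q²+|p|²≤1} (q + β p·g)`, with per-voxel projection
  of `(q, p)` onto the unit ball and explicit gradient steps on the smooth
  data term. Step sizes come from power-iteration operator-norm estimates,
  which guarantees convergence.

Both solvers stop when the relative ℓ2 change of `x` stays below
`tol = 1e-3` for two consecutive iterations (a single small conjugate step
is not convergence) or after 256 iterations; zero initialization makes
both deterministic. On the default phantom Tikhonov converges in ~20
iterations and Beltrami in ~60–150.

Numerical structure worth knowing: per in-plane pixel the data give 25
equations for 29 unknowns, and the combined operator is a deconvolution by
a 5-voxel box whose spectrum vanishes at frequencies 2πk/5 — the 1D system
keeps 4 singular values in 0.054–0.114. Exact inversion at the small
default λ therefore amplifies slice-noise that lands on these modes by
roughly 6×. This is inherent to ideal-box shifted-stack super-resolution,
not a solver defect; the dedicated oracle test confirms the CG solution
matches a dense direct solve to 1e-6. Consequences for the quality
metrics are discussed below. The default λ values are kept as published
for this protocol; `RegularizerConfig` exposes both λ and β.

## Quality metrics

- **SNR** = mean(foreground) / std(background), sample std (n−1).
- **Sharpness index**: the global-phase-coherence sharpness score,
  computed in closed form: with `U` a random-phase field sharing the
  image's power spectrum, the anisotropic periodic total variation of `U`
  is approximately Gaussian with mean and variance obtained from the
  FFT autocorrelations of the image's gradient fields, and the index is
  `−log10 P(TV(U) ≤ TV(u))`. Deterministic, invariant to positive
  intensity scaling, and strictly decreasing under Gaussian blur on the
  phantom. Only ordinal comparisons are asserted anywhere.
- **Smoothness S**: per Canny edge pixel of the mid-sagittal image (edges
  from percentile-thresholded Canny, σ = 1.4, shared across methods per
  time point so distributions are paired), the 25-point slice-direction
  intensity curve is fitted with a cubic smoothing spline — smoothing
  parameter chosen per curve by generalized cross-validation, with a
  fixed-λ override — and `S = Σ(fit − curve)² / Σ curve²`. SR volumes are
  sampled at the 25 slab-center planes; the registered native volume is
  used as-is (both sampling conventions are available).

## Problem sizes

Validation experiments use a 64 × 64 in-plane grid (29-voxel slice axis),
2 s of motion at 50 frames/s, and reconstruct 8 evenly spaced time points
for the method-comparison study; recovery studies use 20 audio-warp
replicates and 10 rigid-jitter replicates. A full simulate → evaluate run
at these sizes completes in about two minutes on one CPU core.

## Known limitations

- The registered-native volumes on the phantom are *smoother* along the
  slice direction than the reconstructions at the published λ defaults:
  after successful DTW alignment and rigid registration the phantom's
  residual inter-slice inconsistency is small, while exact inversion
  amplifies pixel noise on the near-null box-spectrum modes (see above).
  On in-vivo data, where articulation reproducibility — not pixel noise —
  dominates inter-slice inconsistency and background noise statistics
  differ, the relative standing of the methods can differ accordingly.
  Raising λ suppresses the amplification at the cost of
  sub-slice-thickness contrast; the package reports both regimes honestly
  rather than hard-coding a preference.
- Out-of-plane motion is not modeled and cannot be corrected by in-plane
  rigid registration.
- The Beltrami solver's iterates are monotone in objective only up to
  first-order-method tolerance; the dedicated test tracks the objective
  along the trajectory.
- `S2_grouped` alignment treats every repetition independently against the
  reference; within-group coupling beyond shared timing is not exploited.
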