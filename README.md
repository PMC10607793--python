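# vtsr — super-resolved dynamic 3D vocal-tract reconstruction

Real-time 2D MRI can film speech at 50 frames/s, but a single 8 mm-thick
sagittal slice cannot describe the full three-dimensional shape of the
vocal tract. `vtsr` implements the multi-slice route to dynamic 3D: the
speaker repeats the utterance once per slice position, the 25 positions
(1.6 mm apart, 8 mm thick) are recorded together with the microphone
signal, and the toolkit

1. **aligns** the repetitions in time using the audio — short-time real
   cepstra at 250 Hz, reduced to 20 principal components, matched to the
   mid-sagittal reference by dynamic time warping and projected onto
   image frames;
2. **registers** each lateral slice to its medial neighbor by maximizing
   correlation over static anatomy (rigid in-plane motion only);
3. **reconstructs**, per 20 ms time point, a 1.6 mm isotropic volume `x`
   from the five shifted anisotropic stacks `ρ_i` by solving

   ```
   x = argmin_x  Σ_i ‖D_i B_i M_i x − ρ_i‖² + λ C(x)
   ```

   with `M_i` a sub-thickness shift, `B_i` the 8 mm box slab profile and
   `D_i` through-plane downsampling — with either Tikhonov
   (`C(x)=‖x‖²`, conjugate gradients) or Beltrami
   (`C(x)=Σ√(1+β²|∇x|²)`, primal-dual projected gradient)
   regularization;
4. **evaluates** the result with a no-reference sharpness index, ROI SNR,
   and a slice-direction smoothness metric built on Canny edges and
   smoothing splines.

Because in-vivo recordings of this kind are not redistributable, the
package ships a first-class dynamic phantom (`vtsr.phantom`) that
simulates the whole acquisition — thick-slice sampling, per-repetition
monotone time warps, rigid jitter, noise, and motion-tracking synthetic
audio — so every stage is testable end to end. It is aimed at researchers
building or evaluating multi-slice super-resolution pipelines for dynamic
imaging.

## Worked example

```python
import numpy as np
from vtsr import (PhantomConfig, RegularizerConfig, simulate_protocol,
                  compute_cepstrogram, fit_reduce_features, dtw_align,
                  map_frames, assemble_aligned, register_chain,
                  reconstruct_series, AudioTrack)
from vtsr.phantom import make_default_rois

cfg = PhantomConfig(seed=1)                      # 25 slices, 64x64, 2 s
series, audios, truth = simulate_protocol(cfg)

# audio-based temporal alignment to the mid-sagittal repetition
ref = next(k for k, s in enumerate(series) if s.slice_index == 12)
ceps = [compute_cepstrogram(AudioTrack(a.samples, a.rate_hz)) for a in audios]
_, tracks = fit_reduce_features(ceps)
maps = [None if k == ref else
        map_frames(dtw_align(tracks[ref], t), 250.0, 50.0)
        for k, t in enumerate(tracks)]
aligned = assemble_aligned(series, maps, n_frames=series[ref].n_frames)

# chained rigid registration, then super-resolution at t = 0
registered, transforms = register_chain(aligned, make_default_rois(cfg))
vol = reconstruct_series(registered, RegularizerConfig(kind="tikhonov"),
                         frame_indices=[0])[0]
print(vol.data.shape, vol.iterations_used, round(vol.final_residual, 4))
```

```
(29, 64, 64) 20 0.0001
```

The reconstruction is a 29-plane isotropic volume (25 slice positions plus
slab margins) produced in 20 conjugate-gradient iterations; the data
residual is tiny because per in-plane pixel the 25 slab equations
under-determine the 29 unknowns, so a consistent fit exists. The phantom
contains a one-voxel bright septum along the slice axis whose contrast is
~4 % of truth in any single thick-slice stack; this full dynamic pipeline
(alignment and registration residuals included) returns it at

```python
from vtsr.phantom import septum_location
zs, ys, xs = septum_location(cfg)
step = vol.data[zs, ys, xs].mean() - vol.data[zs - 1, ys, xs].mean()
print(f"septum contrast recovered: {step / 0.25:.0%}")
```

```
septum contrast recovered: 79%
```

(the clean static-phantom recovery study in `scripts/acceptance.py`
measures ~91 % for Tikhonov and ~83 % for Beltrami).

A command-line interface wraps the same stages:

```bash
vtsr run --out out/ --seed 1          # simulate -> ... -> evaluate
vtsr simulate --out out/ --seed 1     # individual stages, cached
```

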