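"""Dynamic vocal-tract phantom and multi-slice acquisition simulator.

In-vivo multi-slice speech MRI data cannot be redistributed, so every
downstream stage is exercised on a parametric phantom that reproduces the
*statistical* structure of the acquisition: a bright tissue slab containing
an airway-like cavity whose aperture follows a smooth scalar motion state, a
single-voxel bright septum that is unresolvable within any one thick slice,
a static nose-like landmark for rigid registration, per-repetition monotone
time warps (the speaker reading faster or slower), per-repetition rigid
in-plane offsets (head motion), additive Gaussian noise, and a synthetic
audio signal whose instantaneous spectral content tracks the motion state.

The acquisition geometry follows the real protocol: 25 sagittal slice
positions, 8 mm slab thickness, 1.6 mm shift between positions, 50 frames/s,
audio at 16 kHz; a single-slice-per-repetition protocol (center -> right
laterals -> left laterals) and a grouped protocol (5 groups of 5 slices,
8 mm apart within a group, groups shifted by 1.6 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from vtsr.core import SliceTimeSeries
from vtsr.registration import ROISet, RigidTransform2D, apply_rigid

__all__ = [
    "PhantomConfig",
    "MonotoneWarp",
    "GroundTruthSeries",
    "SyntheticAudio",
    "make_ground_truth",
    "simulate_slice_series",
    "simulate_protocol",
    "make_default_rois",
    "motion_state_fn",
    "septum_location",
    "acquisition_order",
]

AUDIO_RATE_HZ = 16_000


@dataclass
class PhantomConfig:
    """Geometry, timing and perturbation levels of the simulated study.

    Defaults mirror the acquisition protocol: 1.6 mm isotropic target grid,
    25 slice positions of 8 mm thickness shifted by 1.6 mm, 50 frames/s.
    ``motion_amplitude`` scales the airway aperture excursion as a fraction
    of the grid; ``warp_strength`` bounds the slope deviation of the
    per-repetition monotone time warps; ``rigid_jitter`` bounds per-repetition
    in-plane head motion; ``noise_sigma`` is the additive Gaussian noise
    standard deviation relative to the foreground intensity (~1).
    """

    grid_shape: tuple[int, int, int] = (29, 64, 64)
    voxel_mm: float = 1.6
    n_slices: int = 25
    slice_thickness_mm: float = 8.0
    slice_shift_mm: float = 1.6
    frame_rate_hz: float = 50.0
    duration_s: float = 2.0
    motion_amplitude: float = 0.15
    warp_strength: float = 0.2
    rigid_jitter: tuple[float, float, float] = (2.0, 2.0, 2.0)
    # sets the native-stack SNR to ~60, inside the 47-76 range measured on
    # the two in-vivo subjects
    noise_sigma: float = 0.0125
    protocol: str = "S1_single"
    seed: int = 0

    def __post_init__(self) -> None:
        w = self.slice_thickness_mm / self.voxel_mm
        if abs(w - round(w)) > 1e-9 or round(w) < 1:
            raise ValueError("slice_thickness_mm / voxel_mm must be a positive integer")
        if abs(self.slice_shift_mm - self.voxel_mm) > 1e-9:
            raise ValueError("slice_shift_mm must equal voxel_mm")
        nz = self.grid_shape[0]
        if (self.n_slices - 1) + self.sr_factor > nz:
            raise ValueError(
                "grid does not cover the slice range: need nz >= (n_slices-1) + thickness/voxel"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.protocol not in ("S1_single", "S2_grouped"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("duration_s and frame_rate_hz must be positive")

    @property
    def sr_factor(self) -> int:
        """Super-resolution factor f = thickness / voxel (5 for defaults)."""
        return int(round(self.slice_thickness_mm / self.voxel_mm))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.frame_rate_hz


@dataclass
class MonotoneWarp:
    """Strictly increasing piecewise-linear time map ``[0, T] -> [0, *]``.

    Models a repetition spoken slower or faster: the warped repetition at
    time ``t`` shows the reference motion state at time ``warp(t)``.
    """

    knot_times: np.ndarray
    knot_values: np.ndarray

    def __post_init__(self) -> None:
        self.knot_times = np.asarray(self.knot_times, dtype=float)
        self.knot_values = np.asarray(self.knot_values, dtype=float)
        if self.knot_times.ndim != 1 or self.knot_times.shape != self.knot_values.shape:
            raise ValueError("knot arrays must be 1D and of equal length")
        if np.any(np.diff(self.knot_times) <= 0) or np.any(np.diff(self.knot_values) <= 0):
            raise ValueError("warp must be strictly increasing")

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.interp(t, self.knot_times, self.knot_values)

    def inverse(self) -> "MonotoneWarp":
        return MonotoneWarp(self.knot_values.copy(), self.knot_times.copy())

    @property
    def duration(self) -> float:
        return float(self.knot_times[-1])

    @classmethod
    def identity(cls, duration: float) -> "MonotoneWarp":
        return cls(np.array([0.0, duration]), np.array([0.0, duration]))

    @classmethod
    def random(
        cls, duration: float, strength: float, seed: int, n_segments: int = 6
    ) -> "MonotoneWarp":
        """Random monotone warp with segment slopes within ``1 +/- strength``
        and fixed endpoints ``0 -> 0``, ``duration -> duration``."""
        if strength < 0:
            raise ValueError("strength must be >= 0")
        if strength == 0:
            return cls.identity(duration)
        rng = np.random.default_rng(seed)
        times = np.linspace(0.0, duration, n_segments + 1)
        for _ in range(200):
            slopes = 1.0 + rng.uniform(-strength, strength, size=n_segments)
            slopes = slopes * n_segments / slopes.sum()  # renormalize to fixed endpoint
            if np.all(np.abs(slopes - 1.0) <= strength + 1e-12):
                break
        values = np.concatenate([[0.0], np.cumsum(slopes * np.diff(times))])
        values[-1] = duration
        return cls(times, values)


@dataclass
class GroundTruthSeries:
    """Time-indexed isotropic ground-truth volumes with the scalar motion
    trajectory that drives the deforming structures."""

    frames: np.ndarray  # (T, nz, ny, nx), intensities in [0, 1]
    times_s: np.ndarray
    motion_state: np.ndarray
    voxel_mm: float

    def __post_init__(self) -> None:
        if self.frames.ndim != 4:
            raise ValueError("frames must be (time, z, y, x)")
        if not (self.frames.min() >= 0 and self.frames.max() <= 1):
            raise ValueError("intensities must lie in [0, 1]")


@dataclass
class SyntheticAudio:
    """Mono waveform with acquisition-boundary markers (TTL stand-in)."""

    samples: np.ndarray
    rate_hz: int = AUDIO_RATE_HZ
    markers: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.markers = np.asarray(self.markers, dtype=int)
        if self.rate_hz % 64 != 0:
            raise ValueError("rate_hz must be divisible by 64")
        if self.markers.size:
            if np.any(np.diff(self.markers) <= 0):
                raise ValueError("markers must be strictly increasing")
            if self.markers.min() < 0 or self.markers.max() >= self.samples.size:
                raise ValueError("markers out of range")


def motion_state_fn(t: np.ndarray | float) -> np.ndarray | float:
    """Smooth aperiodic scalar trajectory in [0, 1] driving the phantom.

    Two incommensurate sinusoids: aperiodicity keeps the audio/DTW
    correspondence unambiguous (a strictly periodic trajectory would make
    cycle-skipping warps equally good alignments).
    """
    s = 0.5 + 0.25 * np.sin(2 * np.pi * 1.1 * np.asarray(t)) + 0.25 * np.sin(
        2 * np.pi * 0.47 * np.asarray(t) + 1.0
    )
    return np.clip(s, 0.0, 1.0)


def _soft_ellipsoid(
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    center: tuple[float, float, float],
    radii: tuple[float, float, float],
    edge: float = 0.08,
) -> np.ndarray:
    """Soft-edged ellipsoid mask in [0, 1]; ``edge`` is the relative ramp width."""
    z, y, x = coords
    r = np.sqrt(
        ((z - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((x - center[2]) / radii[2]) ** 2
    )
    return np.clip((1.0 - r) / edge, 0.0, 1.0)


# fixed phantom layout (fractions of the grid); see docs/methods.md
_TISSUE_VAL = 0.75
_SEPTUM_VAL = 1.0
# static textured patches (y0, y1, x0, x1 fractions): the nose analog.  Two
# patches spread across x give the rigid registration rich gradients and a
# long rotation lever arm; both sit clear of the image border so jitter
# cannot drag zero-fill into the ROI, and clear of the moving cavity.
_STATIC_PATCHES = ((0.08, 0.22, 0.10, 0.35), (0.08, 0.22, 0.60, 0.88))
_TEXTURE_SEED = 98765  # anatomy, not an experiment variable: never reseeded


def _septum_index(nz: int) -> int:
    return nz // 2 + 3


def _static_texture(ny: int, nx: int) -> np.ndarray:
    """Static nose-analog texture: smooth seeded noise inside fixed patches.

    The texture is anatomy -- identical for every repetition, time point and
    z plane -- so the registration ROI sees the same content in any two
    adjacent slabs.
    """
    from scipy.ndimage import distance_transform_edt, gaussian_filter

    rng = np.random.default_rng(_TEXTURE_SEED)
    noise = gaussian_filter(rng.standard_normal((ny, nx)), sigma=2.0)
    noise = (noise - noise.min()) / max(float(np.ptp(noise)), 1e-12)
    mask = np.zeros((ny, nx), dtype=bool)
    for y0, y1, x0, x1 in _STATIC_PATCHES:
        mask[int(y0 * ny) : int(y1 * ny), int(x0 * nx) : int(x1 * nx)] = True
    # apodize the patch borders so resampling near the step edge does not
    # ripple the registration objective
    apod = np.clip(distance_transform_edt(mask) / 3.0, 0.0, 1.0)
    return (0.35 + 0.55 * noise) * apod


def septum_location(cfg: PhantomConfig) -> tuple[int, slice, slice]:
    """SR-grid location (z index, y slice, x slice) of the one-voxel bright
    septum plane; used to probe sub-slice-thickness recovery."""
    nz, ny, nx = cfg.grid_shape
    return (
        _septum_index(nz),
        slice(int(0.14 * ny), int(0.26 * ny)),
        slice(int(0.46 * nx), int(0.60 * nx)),
    )


def make_ground_truth(
    cfg: PhantomConfig, warp: MonotoneWarp | None = None
) -> GroundTruthSeries:
    """Generate the deterministic dynamic phantom.

    The phantom is a bright tissue ellipsoid containing an airway-like
    cavity whose aperture (along all three axes) follows the motion state; a
    one-voxel bright septum plane along the slice direction provides
    sub-slice-thickness structure; a static Gaussian nose-like landmark
    anchors rigid registration.  ``warp`` reparameterizes time, simulating a
    repetition spoken slower or faster.
    """
    if warp is not None:
        if warp.knot_times[0] > 0 or warp.duration < cfg.duration_s - 1e-9:
            raise ValueError("warp must cover the full duration [0, duration_s]")
    nz, ny, nx = cfg.grid_shape
    times = np.arange(cfg.n_frames) / cfg.frame_rate_hz
    warped_t = warp(times) if warp is not None else times
    state = np.asarray(motion_state_fn(warped_t), dtype=float)

    z, y, x = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij", sparse=True
    )
    coords = (z, y, x)

    # elliptic cylinder: the static in-plane profile is identical on every
    # z plane, so thick slabs at different positions agree on static anatomy
    r_inplane = np.sqrt(
        ((y - 0.5 * (ny - 1)) / (0.44 * ny)) ** 2
        + ((x - 0.5 * (nx - 1)) / (0.44 * nx)) ** 2
    )
    tissue = _TISSUE_VAL * np.clip((1.0 - r_inplane) / 0.08, 0.0, 1.0) * np.ones((nz, 1, 1))

    zs, ys, xs = septum_location(cfg)
    septum = np.zeros((nz, ny, nx))
    septum[zs, ys, xs] = _SEPTUM_VAL

    nose = _static_texture(ny, nx)[None] * np.ones((nz, 1, 1))

    amp = cfg.motion_amplitude
    frames = np.empty((cfg.n_frames, nz, ny, nx))
    for k, s in enumerate(state):
        # edge=0.25 gives the cavity a ~1-voxel partial-volume transition,
        # matching the band-limited appearance of reconstructed MR frames
        cavity = _soft_ellipsoid(
            coords,
            center=(0.5 * (nz - 1), 0.58 * ny, 0.42 * nx),
            radii=(
                (0.10 + 0.8 * amp * s) * nz,
                (0.06 + 1.2 * amp * s) * ny,
                (0.10 + 0.6 * amp * s) * nx,
            ),
            edge=0.25,
        )
        vol = tissue * (1.0 - cavity)
        vol = np.maximum(vol, septum)
        vol = np.maximum(vol, nose)
        frames[k] = np.clip(vol, 0.0, 1.0)
    return GroundTruthSeries(frames=frames, times_s=times, motion_state=state, voxel_mm=cfg.voxel_mm)


def simulate_slice_series(
    gt: GroundTruthSeries,
    cfg: PhantomConfig,
    slice_index: int,
    rep_transform: RigidTransform2D | None = None,
    seed: int = 0,
) -> SliceTimeSeries:
    """Simulate one slice position's dynamic 2D acquisition.

    For every frame the ground-truth volume is box-averaged over the
    ``f = thickness / voxel`` SR voxels of the slab starting at the slice
    position (the same blur the reconstruction forward model assumes), the
    repetition's rigid in-plane offset is applied, and i.i.d. Gaussian noise
    is added.
    """
    w = cfg.sr_factor
    nz = gt.frames.shape[1]
    if not 0 <= slice_index < cfg.n_slices:
        raise ValueError("slice_index out of range")
    if slice_index + w > nz:
        raise ValueError("slice slab exceeds the ground-truth grid")
    if rep_transform is None:
        rep_transform = RigidTransform2D()
    rng = np.random.default_rng(seed)
    data = gt.frames[:, slice_index : slice_index + w].mean(axis=1)
    if not rep_transform.is_identity:
        data = np.stack([apply_rigid(f, rep_transform, cfg.voxel_mm) for f in data])
    else:
        data = data.copy()
    if cfg.noise_sigma > 0:
        data += rng.normal(0.0, cfg.noise_sigma, size=data.shape)
    position_mm = (slice_index + (w - 1) / 2.0) * cfg.voxel_mm
    return SliceTimeSeries(
        data=data,
        slice_position_mm=position_mm,
        thickness_mm=cfg.slice_thickness_mm,
        frame_period_s=cfg.frame_period_s,
        slice_index=slice_index,
        meta={"transform": rep_transform, "seed": seed},
    )


def _synth_audio(cfg: PhantomConfig, warp: MonotoneWarp, noise_seed: int) -> SyntheticAudio:
    """FM tone + noise floor whose instantaneous frequency (hence spectral
    centroid) tracks the motion state under the repetition's warp."""
    n = int(round(cfg.duration_s * AUDIO_RATE_HZ))
    t = np.arange(n) / AUDIO_RATE_HZ
    s = np.asarray(motion_state_fn(warp(t)), dtype=float)
    f_inst = 300.0 + 2200.0 * s
    phase = 2 * np.pi * np.cumsum(f_inst) / AUDIO_RATE_HZ
    rng = np.random.default_rng(noise_seed)
    samples = 0.7 * np.sin(phase) + 0.01 * rng.standard_normal(n)
    samples = np.clip(samples, -1.0, 1.0)
    return SyntheticAudio(samples=samples, markers=np.array([0, n - 1]))


def _random_transform(cfg: PhantomConfig, rng: np.random.Generator) -> RigidTransform2D:
    mx, my, mp = cfg.rigid_jitter
    if mx == 0 and my == 0 and mp == 0:
        return RigidTransform2D()
    return RigidTransform2D(
        tx_mm=float(rng.uniform(-mx, mx)),
        ty_mm=float(rng.uniform(-my, my)),
        phi_deg=float(rng.uniform(-mp, mp)),
    )


def acquisition_order(cfg: PhantomConfig) -> list[int]:
    """Slice-position acquisition order for the single-slice protocol:
    center, then right laterals center -> lateral, then left laterals."""
    c = cfg.n_slices // 2
    return [c] + list(range(c + 1, cfg.n_slices)) + list(range(c - 1, -1, -1))


def simulate_protocol(
    cfg: PhantomConfig,
) -> tuple[list[SliceTimeSeries], list[SyntheticAudio], GroundTruthSeries]:
    """Simulate a full multi-repetition acquisition under ``cfg.protocol``.

    ``S1_single``: one slice per repetition, ordered center -> right
    laterals -> left laterals, each repetition with its own random monotone
    warp and rigid offset.  ``S2_grouped``: 5 groups of 5 slices 8 mm apart,
    groups shifted 1.6 mm; slices within a group share one repetition's warp
    and offset.  The repetition covering the mid-sagittal position is the
    reference: identity warp, zero offset.  Every repetition carries a
    synthetic audio track; audio background noise is a fixed (seeded)
    scanner-noise realization shared by all repetitions.
    """
    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(0, 2**31 - 1, size=2 * cfg.n_slices + 2)
    gt_ref = make_ground_truth(cfg, warp=None)
    center = cfg.n_slices // 2
    f = cfg.sr_factor

    series: list[SliceTimeSeries] = []
    audios: list[SyntheticAudio] = []
    audio_noise_seed = int(seeds[-1])

    if cfg.protocol == "S1_single":
        order = acquisition_order(cfg)
        for rep, pos in enumerate(order):
            if pos == center:
                warp = MonotoneWarp.identity(cfg.duration_s)
                transform = RigidTransform2D()
            else:
                warp = MonotoneWarp.random(cfg.duration_s, cfg.warp_strength, int(seeds[rep]))
                transform = _random_transform(cfg, np.random.default_rng(int(seeds[cfg.n_slices + rep])))
            gt = gt_ref if pos == center else make_ground_truth(cfg, warp)
            s = simulate_slice_series(gt, cfg, pos, transform, seed=int(seeds[rep]) ^ 0x5EED)
            s.repetition = rep
            s.meta["warp"] = warp
            series.append(s)
            audios.append(_synth_audio(cfg, warp, audio_noise_seed))
    else:  # S2_grouped
        n_groups = f
        per_group = cfg.n_slices // f
        ref_group = center % f
        rep = 0
        for g in range(n_groups):
            if g == ref_group:
                warp = MonotoneWarp.identity(cfg.duration_s)
                transform = RigidTransform2D()
            else:
                warp = MonotoneWarp.random(cfg.duration_s, cfg.warp_strength, int(seeds[g]))
                transform = _random_transform(cfg, np.random.default_rng(int(seeds[cfg.n_slices + g])))
            gt = gt_ref if g == ref_group else make_ground_truth(cfg, warp)
            for j in range(per_group):
                pos = g + f * j  # within-group positions are 8 mm (f voxels) apart
                s = simulate_slice_series(gt, cfg, pos, transform, seed=int(seeds[rep]) ^ 0x5EED)
                s.repetition = rep
                s.meta["warp"] = warp
                s.meta["group"] = g
                series.append(s)
                audios.append(_synth_audio(cfg, warp, audio_noise_seed))
                rep += 1
    return series, audios, gt_ref


def make_default_rois(cfg: PhantomConfig) -> ROISet:
    """Phantom-specific ROIs: registration mask over the static textured
    patches (nose analog), foreground inside homogeneous tissue, background
    in signal-free air (top-left corner)."""
    _, ny, nx = cfg.grid_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    registration = np.zeros((ny, nx), dtype=bool)
    for y0, y1, x0, x1 in _STATIC_PATCHES:
        registration[int(y0 * ny) : int(y1 * ny), int(x0 * nx) : int(x1 * nx)] = True
    foreground = (
        (yy >= 0.68 * ny) & (yy <= 0.78 * ny) & (xx >= 0.64 * nx) & (xx <= 0.76 * nx)
    )
    background = (yy <= 0.08 * ny) & (xx <= 0.08 * nx)
    return ROISet(registration, foreground, background)
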