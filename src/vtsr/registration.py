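"""In-plane rigid registration of laterally shifted slices.

Long multi-repetition acquisitions accumulate involuntary head motion.
Out-of-plane motion cannot be corrected in a sagittal multi-slice protocol,
but in-plane rigid motion can: each lateral slice is registered to its
medially adjacent, already-registered neighbor by maximizing the Pearson
correlation inside a region of interest covering static anatomy (the nose,
which does not move during speech). Chaining medial -> lateral propagates
the corrections outward from the mid-sagittal slice, which is never moved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from vtsr.core import AlignedVolumeSeries

__all__ = [
    "RigidTransform2D",
    "ROISet",
    "RegistrationResult",
    "apply_rigid",
    "estimate_rigid",
    "register_chain",
]


@dataclass(frozen=True)
class RigidTransform2D:
    """Global in-plane rigid motion: rotation ``phi_deg`` about the image
    center followed by translation ``(tx_mm, ty_mm)`` (x = columns,
    y = rows)."""

    tx_mm: float = 0.0
    ty_mm: float = 0.0
    phi_deg: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.tx_mm, self.ty_mm, self.phi_deg)
        if not all(np.isfinite(vals)):
            raise ValueError("transform parameters must be finite")
        if abs(self.phi_deg) >= 90.0:
            raise ValueError("|phi_deg| must be < 90")

    @property
    def is_identity(self) -> bool:
        return self.tx_mm == 0.0 and self.ty_mm == 0.0 and self.phi_deg == 0.0

    def _matrix_yx(self) -> np.ndarray:
        """Rotation matrix acting on (y, x) vectors, matching apply_rigid."""
        phi = np.deg2rad(self.phi_deg)
        c, s = np.cos(phi), np.sin(phi)
        return np.array([[c, -s], [s, c]])

    def inverse(self) -> "RigidTransform2D":
        """Exact inverse: rotate back, translate by the back-rotated offset."""
        ty, tx = -(self._matrix_yx().T @ np.array([self.ty_mm, self.tx_mm]))
        return RigidTransform2D(tx_mm=float(tx), ty_mm=float(ty), phi_deg=-self.phi_deg)

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """The transform equivalent to applying ``self`` first, then
        ``other`` (both rotating about the image center)."""
        ty, tx = other._matrix_yx() @ np.array([self.ty_mm, self.tx_mm]) + np.array(
            [other.ty_mm, other.tx_mm]
        )
        return RigidTransform2D(
            tx_mm=float(tx), ty_mm=float(ty), phi_deg=self.phi_deg + other.phi_deg
        )

    @property
    def magnitude(self) -> tuple[float, float]:
        """(translation norm in mm, |rotation| in degrees)."""
        return float(np.hypot(self.tx_mm, self.ty_mm)), abs(self.phi_deg)


@dataclass
class ROISet:
    """In-plane masks: a static-anatomy registration ROI and disjoint
    foreground/background regions for SNR estimation."""

    registration_mask: np.ndarray
    foreground_mask: np.ndarray
    background_mask: np.ndarray

    def __post_init__(self) -> None:
        self.registration_mask = np.asarray(self.registration_mask, dtype=bool)
        self.foreground_mask = np.asarray(self.foreground_mask, dtype=bool)
        self.background_mask = np.asarray(self.background_mask, dtype=bool)
        shapes = {
            self.registration_mask.shape,
            self.foreground_mask.shape,
            self.background_mask.shape,
        }
        if len(shapes) != 1:
            raise ValueError("all ROI masks must share one shape")
        if not self.registration_mask.any():
            raise ValueError("registration_mask is empty")
        if np.any(self.foreground_mask & self.background_mask):
            raise ValueError("foreground and background masks overlap")


@dataclass
class RegistrationResult:
    transform: RigidTransform2D
    corr_before: float
    corr_after: float


def apply_rigid(image: np.ndarray, t: RigidTransform2D, voxel_mm: float = 1.6) -> np.ndarray:
    """Apply an in-plane rigid transform with bilinear interpolation.

    The image content is rotated by ``phi_deg`` about the image center and
    then translated by ``(tx_mm, ty_mm)``; regions moved in from outside the
    field of view are filled with 0.  The identity transform returns a
    bit-exact copy.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("apply_rigid expects a 2D image")
    if t.is_identity:
        return image.copy()
    phi = np.deg2rad(t.phi_deg)
    c, s = np.cos(phi), np.sin(phi)
    # (row, col) coordinates; forward map p' = R (p - ctr) + ctr + t_px
    rot = np.array([[c, -s], [s, c]])
    t_px = np.array([t.ty_mm, t.tx_mm]) / voxel_mm
    ctr = (np.array(image.shape) - 1) / 2.0
    inv = rot.T
    offset = ctr - inv @ (ctr + t_px)
    return ndimage.affine_transform(image, inv, offset=offset, order=1, mode="constant", cval=0.0)


def _masked_pearson(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    av = a[mask]
    bv = b[mask]
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt((av @ av) * (bv @ bv))
    if denom == 0:
        return 0.0
    return float((av @ bv) / denom)


def estimate_rigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    roi: np.ndarray,
    init: RigidTransform2D | None = None,
    voxel_mm: float = 1.6,
    coarse_search_px: int = 4,
    coarse_search_deg: float = 4.0,
    presmooth_sigma: float = 1.0,
) -> RegistrationResult:
    """Estimate the rigid transform maximizing Pearson correlation in a ROI.

    A coarse grid scan over integer-pixel translations and coarse rotations
    seeds a quasi-Newton (BFGS, numerical gradients) refinement of
    ``(tx, ty, phi)``; the grid step keeps the refinement inside the capture
    range of the smooth optimum.  Both images are Gaussian pre-smoothed
    (``presmooth_sigma`` pixels) before correlating, which damps the
    subpixel ripple bilinear resampling imprints on the objective.  The
    returned correlation is guaranteed to be no worse than at the initial
    guess.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    if presmooth_sigma > 0:
        moving = ndimage.gaussian_filter(moving, presmooth_sigma)
        fixed = ndimage.gaussian_filter(fixed, presmooth_sigma)
    if np.ptp(fixed[roi]) == 0 or np.ptp(moving[roi]) == 0:
        raise ValueError("zero-variance ROI")
    if init is None:
        init = RigidTransform2D()

    def corr_of(params: np.ndarray) -> float:
        t = RigidTransform2D(*params)
        return _masked_pearson(apply_rigid(moving, t, voxel_mm), fixed, roi)

    x0 = np.array([init.tx_mm, init.ty_mm, init.phi_deg])
    corr0 = corr_of(x0)

    # coarse grid scan to escape the narrow capture range of BFGS
    best = (corr0, x0.copy())
    if coarse_search_px > 0:
        phis = np.arange(-coarse_search_deg, coarse_search_deg + 1e-9, 1.0)
        for dphi in phis:
            for dy in range(-coarse_search_px, coarse_search_px + 1):
                for dx in range(-coarse_search_px, coarse_search_px + 1):
                    if dx == 0 and dy == 0 and dphi == 0:
                        continue
                    cand = x0 + np.array([dx * voxel_mm, dy * voxel_mm, dphi])
                    c = corr_of(cand)
                    if c > best[0]:
                        best = (c, cand)

    res = optimize.minimize(
        lambda p: -corr_of(p),
        best[1],
        method="BFGS",
        options={"gtol": 1e-7, "eps": 1e-3},
    )
    cand_params = [best[1], res.x]
    cand_corr = [best[0], corr_of(res.x)]
    k = int(np.argmax(cand_corr))
    params, corr = cand_params[k], cand_corr[k]
    if corr < corr0:  # never degrade relative to the initial guess
        params, corr = x0, corr0
    return RegistrationResult(
        transform=RigidTransform2D(*params), corr_before=corr0, corr_after=float(corr)
    )


def register_chain(
    series: AlignedVolumeSeries,
    roi: ROISet,
    per_frame: bool = False,
) -> tuple[AlignedVolumeSeries, list[RegistrationResult]]:
    """Chain-register lateral slices to their medial neighbors.

    One global transform per slice is estimated from the temporal-mean image
    inside the registration ROI (the static anatomy carries no speech motion,
    so averaging over time only suppresses noise).  The right side is chained
    center -> lateral first, then the left side; each slice is registered to
    its already-registered neighbor, so corrections compose implicitly down
    the chain.  The center slice is never transformed.

    With ``per_frame=True`` a transform is estimated for every frame of each
    slice instead (slower; provided as a variant, not the default behavior).
    """
    n = series.n_slices
    if n % 2 == 0:
        raise ValueError("register_chain expects an odd slice count with a central slice")
    center = n // 2
    out = series.copy()
    results: list[RegistrationResult] = [
        RegistrationResult(RigidTransform2D(), 1.0, 1.0) for _ in range(n)
    ]

    def correct_slice(s: int, neighbor: int) -> None:
        fixed = out.frames[:, neighbor].mean(axis=0)
        if per_frame:
            for k in range(out.n_frames):
                try:
                    r = estimate_rigid(out.frames[k, s], fixed, roi.registration_mask,
                                       voxel_mm=series.voxel_mm)
                except ValueError as e:
                    raise ValueError(f"registration failed at slice {s}, frame {k}: {e}") from e
                out.frames[k, s] = apply_rigid(out.frames[k, s], r.transform, series.voxel_mm)
            results[s] = r
            return
        moving = out.frames[:, s].mean(axis=0)
        try:
            r = estimate_rigid(moving, fixed, roi.registration_mask, voxel_mm=series.voxel_mm)
        except ValueError as e:
            raise ValueError(f"registration failed at slice {s}: {e}") from e
        for k in range(out.n_frames):
            out.frames[k, s] = apply_rigid(out.frames[k, s], r.transform, series.voxel_mm)
        results[s] = r

    for s in range(center + 1, n):  # right side, medial -> lateral
        correct_slice(s, s - 1)
    for s in range(center - 1, -1, -1):  # left side
        correct_slice(s, s + 1)
    return out, results
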