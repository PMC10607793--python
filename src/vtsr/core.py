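"""Shared containers for dynamic slice series and assembled volumes.

Axis conventions used throughout the package:

* the slice (left-right) direction is the first spatial axis, ascending
  left -> right;
* in-plane images are ``(y, x)`` row-major;
* positions are in mm at voxel centers, indices are 0-based;
* dynamic arrays carry time as the leading axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SliceTimeSeries", "AlignedVolumeSeries"]


@dataclass
class SliceTimeSeries:
    """One repetition's 2D dynamic frame stack with geometry and timing.

    Parameters
    ----------
    data
        ``(n_frames, H, W)`` array of image frames.
    slice_position_mm
        Center of the excited slab along the slice direction.
    thickness_mm
        Slab thickness (the extent averaged by the acquisition).
    frame_period_s
        Time between consecutive frames (0.020 s at 50 fps).
    slice_index
        Position index on the shifted-slice grid (0-based, left -> right).
    repetition
        Acquisition repetition the series came from.
    """

    data: np.ndarray
    slice_position_mm: float
    thickness_mm: float
    frame_period_s: float
    slice_index: int = 0
    repetition: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected (time, y, x) data, got shape {self.data.shape}")
        if self.frame_period_s <= 0:
            raise ValueError("frame_period_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_rate_hz(self) -> float:
        return 1.0 / self.frame_period_s


@dataclass
class AlignedVolumeSeries:
    """Temporally aligned multi-slice series stacked by slice position.

    ``frames`` has shape ``(n_frames, n_slices, H, W)`` with slices ordered
    by geometric position (left -> right) regardless of acquisition order.
    """

    frames: np.ndarray
    slice_positions_mm: np.ndarray
    voxel_mm: float
    frame_period_s: float
    thickness_mm: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.slice_positions_mm = np.asarray(self.slice_positions_mm, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError("frames must be (time, slice, y, x)")
        if self.frames.shape[1] != self.slice_positions_mm.size:
            raise ValueError("slice count mismatch between frames and positions")
        if np.any(np.diff(self.slice_positions_mm) <= 0):
            raise ValueError("slice positions must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_slices(self) -> int:
        return self.frames.shape[1]

    def copy(self) -> "AlignedVolumeSeries":
        return AlignedVolumeSeries(
            frames=self.frames.copy(),
            slice_positions_mm=self.slice_positions_mm.copy(),
            voxel_mm=self.voxel_mm,
            frame_period_s=self.frame_period_s,
            thickness_mm=self.thickness_mm,
        )
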