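"""Shared fixtures: small phantoms and precomputed stacks.

Session-scoped fixtures keep the expensive simulations (default-geometry
phantom, acquisition protocol) shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from vtsr.phantom import (
    PhantomConfig,
    make_default_rois,
    make_ground_truth,
    simulate_slice_series,
)
from vtsr.superres import SRGeometry, StackSet, apply_forward, group_stacks


@pytest.fixture(scope="session")
def default_cfg() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture(scope="session")
def small_cfg() -> PhantomConfig:
    """Reduced in-plane grid for fast unit tests; full slice geometry."""
    return PhantomConfig(grid_shape=(29, 32, 32), duration_s=0.4)


@pytest.fixture(scope="session")
def toy_geom() -> SRGeometry:
    return SRGeometry(factor=2, n_stacks=2, slices_per_stack=4, sr_len=8, in_plane_shape=(4, 4))


@pytest.fixture(scope="session")
def toy_stacks(toy_geom) -> tuple[StackSet, np.ndarray]:
    rng = np.random.default_rng(7)
    x_true = rng.standard_normal((toy_geom.sr_len, *toy_geom.in_plane_shape))
    stacks = StackSet(
        [
            apply_forward(x_true, toy_geom, i) + 0.01 * rng.standard_normal((4, 4, 4))
            for i in range(toy_geom.n_stacks)
        ],
        toy_geom,
    )
    return stacks, x_true


@pytest.fixture(scope="session")
def static_noisy_stacks():
    """Default geometry, static frame, sigma=0.02, no warp/jitter: the
    sub-slice-thickness recovery setting."""
    cfg = PhantomConfig(noise_sigma=0.02, duration_s=0.1, warp_strength=0.0, rigid_jitter=(0, 0, 0))
    gt = make_ground_truth(cfg)
    vol25 = np.stack(
        [simulate_slice_series(gt, cfg, p, None, seed=p).data[0] for p in range(cfg.n_slices)]
    )
    geom = SRGeometry()
    return cfg, gt.frames[0], group_stacks(vol25, geom), geom


@pytest.fixture(scope="session")
def default_rois(default_cfg):
    return make_default_rois(default_cfg)
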