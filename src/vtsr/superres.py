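r"""Shifted-stack super-resolution along the slice direction.

The 25 slice positions, spaced by one SR voxel (1.6 mm) but 5 SR voxels
(8 mm) thick, regroup into ``f = 5`` anisotropic stacks: stack ``i`` holds
every ``f``-th position starting at ``i``, so consecutive stacks are shifted
by one SR voxel.  Each stack is modeled as

    rho_i = D_i B_i M_i x  =  A_i x

where ``M_i`` shifts the isotropic volume ``x`` by ``i`` SR voxels along the
slice axis (zero fill outside the grid), ``B_i`` box-averages ``f``
consecutive SR voxels (the ideal thick-slice profile), and ``D_i`` keeps
every ``f``-th plane.  The reconstruction solves

    x = argmin_x  sum_i || A_i x - rho_i ||^2  +  lambda C(x)

with either Tikhonov regularization ``C(x) = ||x||^2`` (conjugate gradients
on the normal equations) or Beltrami regularization
``C(x) = sum sqrt(1 + beta^2 |grad x|^2)`` (a convergent primal-dual
projected-gradient scheme).  Per in-plane pixel the data provide 25
equations for 29 unknowns, so the regularizer also selects the null-space
component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from vtsr.core import AlignedVolumeSeries

__all__ = [
    "SRGeometry",
    "StackSet",
    "RegularizerConfig",
    "SRVolume",
    "group_stacks",
    "apply_forward",
    "apply_adjoint",
    "solve_tikhonov",
    "solve_beltrami",
    "reconstruct_series",
]


@dataclass(frozen=True)
class SRGeometry:
    """Geometry of the shifted-stack inverse problem.

    ``factor`` is the SR factor f = thickness / voxel; stack ``i`` (of
    ``n_stacks == factor``) is shifted by ``i`` SR voxels.  ``sr_len`` is the
    SR-grid length along the slice axis and must cover the union of all
    slabs: ``(n_stacks * slices_per_stack - 1) + factor`` voxels (29 for the
    default 25 positions at factor 5).
    """

    factor: int = 5
    n_stacks: int = 5
    slices_per_stack: int = 5
    sr_len: int = 29
    in_plane_shape: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if self.n_stacks != self.factor:
            raise ValueError("n_stacks must equal the SR factor")
        if self.sr_len < (self.slices_per_stack - 1) * self.factor + self.factor:
            raise ValueError("sr_len does not cover the slice slabs")

    @property
    def shifts(self) -> tuple[int, ...]:
        return tuple(range(self.factor))

    @property
    def n_slices(self) -> int:
        return self.n_stacks * self.slices_per_stack

    @classmethod
    def for_slices(
        cls, n_slices: int, factor: int, in_plane_shape: tuple[int, int]
    ) -> "SRGeometry":
        if n_slices % factor != 0:
            raise ValueError("n_slices must be a multiple of the SR factor")
        spp = n_slices // factor
        return cls(
            factor=factor,
            n_stacks=factor,
            slices_per_stack=spp,
            sr_len=(n_slices - 1) + factor,
            in_plane_shape=in_plane_shape,
        )


@dataclass
class StackSet:
    """The ``n_stacks`` shifted anisotropic stacks rho_i for one time point."""

    stacks: list[np.ndarray]
    geometry: SRGeometry

    def __post_init__(self) -> None:
        if len(self.stacks) != self.geometry.n_stacks:
            raise ValueError("stack count does not match geometry")
        shp = {s.shape for s in self.stacks}
        if len(shp) != 1:
            raise ValueError("all stacks must share one shape")
        expect = (self.geometry.slices_per_stack, *self.geometry.in_plane_shape)
        if self.stacks[0].shape != expect:
            raise ValueError(f"stack shape {self.stacks[0].shape} != expected {expect}")


@dataclass
class RegularizerConfig:
    """Regularizer choice and solver settings.

    Default weights are the values used for vocal-tract reconstruction:
    ``lam = 1e-6`` for Tikhonov and ``lam = 5e-5`` with ``beta = 1`` for
    Beltrami; convergence is declared when the relative l2 change of the
    solution between outer iterations falls below ``tol`` (1e-3), with at
    most ``max_iter`` (256) iterations.
    """

    kind: str = "tikhonov"
    lam: float | None = None
    beta: float = 1.0
    tol: float = 1e-3
    max_iter: int = 256

    def __post_init__(self) -> None:
        if self.kind not in ("tikhonov", "beltrami"):
            raise ValueError(f"unknown regularizer {self.kind!r}")
        if self.lam is None:
            self.lam = 1e-6 if self.kind == "tikhonov" else 5e-5
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not 0 < self.tol < 1:
            raise ValueError("tol must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class SRVolume:
    """Isotropic reconstruction with solver diagnostics."""

    data: np.ndarray  # (sr_len, H, W)
    voxel_mm: float = 1.6
    iterations_used: int = 0
    final_residual: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("reconstruction contains non-finite values")


def group_stacks(volume: np.ndarray, geom: SRGeometry) -> StackSet:
    """Regroup an ``(n_slices, H, W)`` aligned volume into shifted stacks.

    Position ``p`` (0-based, uniformly spaced by one SR voxel) goes to stack
    ``p mod f`` at within-stack index ``p // f``; stack ``i`` carries shift
    ``i``.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3 or volume.shape[0] != geom.n_slices:
        raise ValueError(
            f"expected ({geom.n_slices}, H, W) volume, got shape {volume.shape}"
        )
    f = geom.factor
    stacks = [volume[i::f] for i in range(f)]
    return StackSet(stacks=stacks, geometry=geom)


def _padded(x: np.ndarray, geom: SRGeometry, i: int) -> np.ndarray:
    """View of x padded with zeros so the shifted slabs fit (M_i zero fill)."""
    need = i + geom.slices_per_stack * geom.factor
    if need <= x.shape[0]:
        return x
    pad = need - x.shape[0]
    return np.concatenate([x, np.zeros((pad, *x.shape[1:]))], axis=0)


def apply_forward(x: np.ndarray, geom: SRGeometry, i: int) -> np.ndarray:
    """A_i x = D_i B_i M_i x: shift by ``i`` SR voxels, box-mean over ``f``
    voxels, keep every ``f``-th plane."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != geom.sr_len or x.shape[1:] != geom.in_plane_shape:
        raise ValueError(f"volume shape {x.shape} does not match geometry")
    if not 0 <= i < geom.n_stacks:
        raise ValueError("stack index out of range")
    f, spp = geom.factor, geom.slices_per_stack
    xp = _padded(x, geom, i)
    out = xp[i : i + spp * f].reshape(spp, f, *x.shape[1:]).mean(axis=1)
    return out


def apply_adjoint(stack: np.ndarray, geom: SRGeometry, i: int) -> np.ndarray:
    """Exact adjoint A_i^T: spread each slice value as value/f over its f SR
    planes, then unshift (discarding what fell outside the grid)."""
    stack = np.asarray(stack, dtype=float)
    f, spp = geom.factor, geom.slices_per_stack
    if stack.shape != (spp, *geom.in_plane_shape):
        raise ValueError(f"stack shape {stack.shape} does not match geometry")
    need = max(geom.sr_len, i + spp * f)
    out = np.zeros((need, *geom.in_plane_shape))
    spread = np.repeat(stack / f, f, axis=0)  # (spp*f, H, W)
    out[i : i + spp * f] = spread
    return out[: geom.sr_len]


def _normal_apply(x: np.ndarray, geom: SRGeometry, lam: float) -> np.ndarray:
    """(sum_i A_i^T A_i + lam I) x."""
    out = lam * x
    for i in range(geom.n_stacks):
        out += apply_adjoint(apply_forward(x, geom, i), geom, i)
    return out


def _rhs(stacks: StackSet) -> np.ndarray:
    geom = stacks.geometry
    b = np.zeros((geom.sr_len, *geom.in_plane_shape))
    for i, rho in enumerate(stacks.stacks):
        b += apply_adjoint(rho, geom, i)
    return b


def _data_residual(x: np.ndarray, stacks: StackSet) -> float:
    geom = stacks.geometry
    num = 0.0
    den = 0.0
    for i, rho in enumerate(stacks.stacks):
        num += float(np.sum((apply_forward(x, geom, i) - rho) ** 2))
        den += float(np.sum(rho**2))
    return np.sqrt(num / den) if den > 0 else np.sqrt(num)


def solve_tikhonov(stacks: StackSet, cfg: RegularizerConfig) -> SRVolume:
    """Conjugate gradients on the Tikhonov normal equations
    ``(sum_i A_i^T A_i + lam I) x = sum_i A_i^T rho_i`` from zero
    initialization; stops when the relative l2 change of ``x`` falls below
    ``cfg.tol`` or after ``cfg.max_iter`` iterations."""
    if cfg.kind != "tikhonov":
        raise ValueError("config kind must be 'tikhonov'")
    geom = stacks.geometry
    for rho in stacks.stacks:
        if not np.all(np.isfinite(rho)):
            raise ValueError("non-finite stack data")
    b = _rhs(stacks)
    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rs = float(np.sum(r * r))
    iters = 0
    below = 0  # consecutive sub-tol steps; one small CG step is not convergence
    for iters in range(1, cfg.max_iter + 1):
        Np = _normal_apply(p, geom, cfg.lam)
        alpha = rs / float(np.sum(p * Np))
        x += alpha * p
        xn = float(np.linalg.norm(x))
        below = below + 1 if xn > 0 and abs(alpha) * float(np.linalg.norm(p)) / xn < cfg.tol else 0
        if below >= 2:
            break
        r -= alpha * Np
        rs_new = float(np.sum(r * r))
        if rs_new == 0.0:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return SRVolume(
        data=x,
        iterations_used=iters,
        final_residual=_data_residual(x, stacks),
        meta={"kind": "tikhonov", "lam": cfg.lam, "tol": cfg.tol},
    )


def _grad(x: np.ndarray) -> np.ndarray:
    """Forward differences with Neumann boundaries; shape (3, nz, H, W)."""
    g = np.zeros((3, *x.shape))
    g[0, :-1] = x[1:] - x[:-1]
    g[1, :, :-1] = x[:, 1:] - x[:, :-1]
    g[2, :, :, :-1] = x[:, :, 1:] - x[:, :, :-1]
    return g


def _div(p: np.ndarray) -> np.ndarray:
    """Negative adjoint of ``_grad``: backward-difference divergence."""
    out = np.zeros(p.shape[1:])
    out[:-1] += p[0, :-1]
    out[1:] -= p[0, :-1]
    out[:, :-1] += p[1, :, :-1]
    out[:, 1:] -= p[1, :, :-1]
    out[:, :, :-1] += p[2, :, :, :-1]
    out[:, :, 1:] -= p[2, :, :, :-1]
    return out


def _normal_operator_norm(geom: SRGeometry, n_iter: int = 30) -> float:
    """Largest eigenvalue of sum_i A_i^T A_i by power iteration
    (deterministic start)."""
    rng = np.random.default_rng(12345)
    v = rng.standard_normal((geom.sr_len, *geom.in_plane_shape))
    v /= np.linalg.norm(v)
    lam = 1.0
    for _ in range(n_iter):
        w = _normal_apply(v, geom, 0.0)
        lam = float(np.linalg.norm(w))
        if lam == 0:
            return 0.0
        v = w / lam
    return lam


def beltrami_objective(x: np.ndarray, stacks: StackSet, lam: float, beta: float) -> float:
    """sum_i ||A_i x - rho_i||^2 + lam * sum sqrt(1 + beta^2 |grad x|^2)."""
    geom = stacks.geometry
    data = sum(
        float(np.sum((apply_forward(x, geom, i) - rho) ** 2))
        for i, rho in enumerate(stacks.stacks)
    )
    g = _grad(x)
    reg = float(np.sum(np.sqrt(1.0 + beta**2 * np.sum(g**2, axis=0))))
    return data + lam * reg


def solve_beltrami(stacks: StackSet, cfg: RegularizerConfig) -> SRVolume:
    r"""Primal-dual projected-gradient solver for Beltrami regularization.

    Uses the exact dual representation
    ``sqrt(1 + beta^2 |g|^2) = max_{q^2 + |p|^2 <= 1} (q + beta p . g)``,
    giving the saddle problem

        min_x max_{||(q,p)|| <= 1}  sum_i ||A_i x - rho_i||^2
                                    + lam sum_v (q_v + beta p_v . (grad x)_v)

    solved with a Condat-Vu primal-dual iteration: dual ascent on ``(q, p)``
    followed by per-voxel projection onto the unit ball (the "projected
    gradient" step), explicit gradient descent on the smooth data term, and
    primal extrapolation.  Step sizes come from power-iteration estimates of
    the operator norms, which guarantees convergence.  Stopping matches the
    Tikhonov solver: relative l2 change of ``x`` below ``cfg.tol`` or
    ``cfg.max_iter`` iterations.
    """
    if cfg.kind != "beltrami":
        raise ValueError("config kind must be 'beltrami'")
    geom = stacks.geometry
    for rho in stacks.stacks:
        if not np.all(np.isfinite(rho)):
            raise ValueError("non-finite stack data")
    lam, beta = cfg.lam, cfg.beta
    shape = (geom.sr_len, *geom.in_plane_shape)

    L = 2.0 * _normal_operator_norm(geom)  # Lipschitz constant of grad of data term
    # ||K|| with K = lam * beta * grad; forward-difference grad norm^2 <= 4 * ndim
    K_norm = lam * beta * np.sqrt(4.0 * 3)
    sigma = 1.0 / K_norm if K_norm > 0 else 0.0
    tau = 0.9 / (L / 2.0 + sigma * K_norm**2 + 1e-30)

    x = np.zeros(shape)
    x_bar = x.copy()
    q = np.zeros(shape)
    p = np.zeros((3, *shape))
    iters = 0
    below = 0
    for iters in range(1, cfg.max_iter + 1):
        # dual ascent + projection of (q, p) onto the unit ball per voxel
        q += sigma * lam
        p += sigma * lam * beta * _grad(x_bar)
        norm = np.sqrt(q**2 + np.sum(p**2, axis=0))
        scale = 1.0 / np.maximum(1.0, norm)
        q *= scale
        p *= scale
        # primal descent on the smooth data term + K^T p
        grad_data = np.zeros(shape)
        for i, rho in enumerate(stacks.stacks):
            grad_data += 2.0 * apply_adjoint(apply_forward(x, geom, i) - rho, geom, i)
        x_new = x - tau * (grad_data - lam * beta * _div(p))
        dx = float(np.linalg.norm(x_new - x))
        xn = float(np.linalg.norm(x_new))
        x_bar = 2.0 * x_new - x
        x = x_new
        below = below + 1 if xn > 0 and dx / xn < cfg.tol else 0
        if below >= 2:
            break
    return SRVolume(
        data=x,
        iterations_used=iters,
        final_residual=_data_residual(x, stacks),
        meta={"kind": "beltrami", "lam": lam, "beta": beta, "tol": cfg.tol},
    )


def reconstruct_series(
    series: AlignedVolumeSeries,
    cfg: RegularizerConfig,
    geom: SRGeometry | None = None,
    frame_indices: list[int] | None = None,
) -> list[SRVolume]:
    """Reconstruct an SR volume per time point of an aligned, registered
    series (optionally a subset of frames)."""
    if geom is None:
        f = int(round(series.thickness_mm / series.voxel_mm))
        geom = SRGeometry.for_slices(series.n_slices, f, series.frames.shape[2:])
    solver = solve_tikhonov if cfg.kind == "tikhonov" else solve_beltrami
    idx = range(series.n_frames) if frame_indices is None else frame_indices
    out = []
    for t in idx:
        vol = solver(group_stacks(series.frames[t], geom), cfg)
        vol.meta["frame"] = int(t)
        vol.voxel_mm = series.voxel_mm
        out.append(vol)
    return out
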