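"""Canned validation experiments on the synthetic phantom.

Each function sets up one study condition, runs the relevant pipeline
stages, and returns plain numbers.  They are shared by the test suite and
by ``scripts/acceptance.py`` so that reported figures always come from the
same code paths as the tested ones.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import interp1d

from vtsr.audio_align import (
    AudioTrack,
    assemble_aligned,
    compute_cepstrogram,
    dtw_align,
    fit_reduce_features,
    map_frames,
)
from vtsr.metrics import evaluate_methods, sharpness_index
from vtsr.phantom import (
    MonotoneWarp,
    PhantomConfig,
    _synth_audio,
    make_default_rois,
    make_ground_truth,
    septum_location,
    simulate_protocol,
    simulate_slice_series,
)
from vtsr.registration import RigidTransform2D, register_chain
from vtsr.superres import (
    RegularizerConfig,
    SRGeometry,
    StackSet,
    apply_adjoint,
    apply_forward,
    group_stacks,
    reconstruct_series,
    solve_beltrami,
    solve_tikhonov,
)

__all__ = [
    "toy_solver_oracle_error",
    "adjointness_error",
    "sr_recovery",
    "warp_recovery",
    "rigid_recovery",
    "ordering_study",
    "dtw_bruteforce_error",
]


def toy_solver_oracle_error(seed: int = 7) -> tuple[float, int]:
    """CG Tikhonov vs a dense direct solve of the normal equations on the
    toy geometry (sr_len=8, 4x4 in-plane, f=2, 2 stacks)."""
    geom = SRGeometry(factor=2, n_stacks=2, slices_per_stack=4, sr_len=8, in_plane_shape=(4, 4))
    rng = np.random.default_rng(seed)
    x_true = rng.standard_normal((geom.sr_len, 4, 4))
    stacks = StackSet(
        [
            apply_forward(x_true, geom, i) + 0.01 * rng.standard_normal((4, 4, 4))
            for i in range(2)
        ],
        geom,
    )
    sol = solve_tikhonov(stacks, RegularizerConfig(kind="tikhonov", lam=1e-6, tol=1e-8, max_iter=500))

    n = geom.sr_len * 16
    shape = (geom.sr_len, 4, 4)
    M = np.zeros((n, n))
    for k in range(n):
        e = np.zeros(n)
        e[k] = 1.0
        M[:, k] = sum(
            apply_adjoint(apply_forward(e.reshape(shape), geom, i), geom, i) for i in range(2)
        ).ravel()
    M += 1e-6 * np.eye(n)
    b = sum(apply_adjoint(stacks.stacks[i], geom, i) for i in range(2)).ravel()
    xd = np.linalg.solve(M, b).reshape(shape)
    rel = float(np.linalg.norm(sol.data - xd) / np.linalg.norm(xd))
    return rel, sol.iterations_used


def adjointness_error(seed: int = 0, n_pairs: int = 20) -> float:
    """Max relative dot-product mismatch of (A_i, A_i^T) over random pairs."""
    geom = SRGeometry(in_plane_shape=(16, 16))
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(geom.n_stacks):
        for _ in range(n_pairs):
            x = rng.standard_normal((geom.sr_len, 16, 16))
            y = rng.standard_normal((geom.slices_per_stack, 16, 16))
            lhs = float(np.sum(apply_forward(x, geom, i) * y))
            rhs = float(np.sum(x * apply_adjoint(y, geom, i)))
            worst = max(worst, abs(lhs - rhs) / max(abs(lhs), 1e-300))
    return worst


def sr_recovery(seed: int = 0) -> dict:
    """Sub-slice-thickness recovery at sigma=0.02 on the default geometry.

    Returns the septum contrast (fraction of the true 0.25 step) seen in the
    best single-stack linear interpolation and in both reconstructions, plus
    ground-truth RMSEs.
    """
    cfg = PhantomConfig(noise_sigma=0.02, duration_s=0.1, warp_strength=0.0,
                        rigid_jitter=(0, 0, 0), seed=seed)
    gt = make_ground_truth(cfg)
    rng = np.random.default_rng(seed)
    slice_seeds = rng.integers(0, 2**31 - 1, size=cfg.n_slices)
    vol25 = np.stack(
        [
            simulate_slice_series(gt, cfg, p, None, seed=int(slice_seeds[p])).data[0]
            for p in range(cfg.n_slices)
        ]
    )
    geom = SRGeometry(in_plane_shape=cfg.grid_shape[1:])
    stacks = group_stacks(vol25, geom)
    gt_vol = gt.frames[0]
    zs, ys, xs = septum_location(cfg)

    def contrast(v: np.ndarray) -> float:
        step = v[zs, ys, xs].mean() - 0.5 * (v[zs - 1, ys, xs].mean() + v[zs + 1, ys, xs].mean())
        return float(step / 0.25)

    interp_rmse, interp_con = [], []
    for i in range(geom.n_stacks):
        centers = i + np.arange(geom.slices_per_stack) * geom.factor + geom.factor // 2
        f = interp1d(centers, stacks.stacks[i], axis=0, kind="linear", bounds_error=False,
                     fill_value=(stacks.stacks[i][0], stacks.stacks[i][-1]))
        up = f(np.arange(geom.sr_len))
        interp_rmse.append(float(np.sqrt(np.mean((up - gt_vol) ** 2))))
        interp_con.append(contrast(up))

    out = {
        "stack_contrast_max": max(interp_con),
        "interp_rmse_min": min(interp_rmse),
    }
    for kind, solver in (("tikhonov", solve_tikhonov), ("beltrami", solve_beltrami)):
        sol = solver(stacks, RegularizerConfig(kind=kind))
        out[f"{kind}_contrast"] = contrast(sol.data)
        out[f"{kind}_rmse"] = float(np.sqrt(np.mean((sol.data - gt_vol) ** 2)))
        out[f"{kind}_iterations"] = sol.iterations_used
    return out


def warp_recovery(n_replicates: int = 20, seed: int = 0, warp_strength: float = 0.3) -> dict:
    """Recover known monotone warps from synthetic audio pairs via the
    cepstrum/PCA/DTW chain; fraction of reference frames mapped within one
    image frame of truth."""
    cfg = PhantomConfig(seed=seed)
    rng = np.random.default_rng(seed)
    fractions = []
    for _ in range(n_replicates):
        s_warp = int(rng.integers(0, 2**31 - 1))
        s_noise = int(rng.integers(0, 2**31 - 1))
        q_warp = MonotoneWarp.random(cfg.duration_s, warp_strength, s_warp)
        a_ref = _synth_audio(cfg, MonotoneWarp.identity(cfg.duration_s), s_noise)
        a_qry = _synth_audio(cfg, q_warp, s_noise)
        ceps = [
            compute_cepstrogram(AudioTrack(a.samples, a.rate_hz)) for a in (a_ref, a_qry)
        ]
        _, tracks = fit_reduce_features(ceps)
        path = dtw_align(tracks[0], tracks[1])
        fmap = map_frames(path, a_ref.rate_hz / 64.0, cfg.frame_rate_hz)
        times = np.arange(len(fmap)) / cfg.frame_rate_hz
        truth = np.clip(
            np.round(np.asarray(q_warp.inverse()(times)) * cfg.frame_rate_hz),
            0,
            cfg.n_frames - 1,
        ).astype(int)
        fractions.append(float(np.mean(np.abs(fmap.mapping - truth) <= 1)))
    return {
        "fraction_within_1_frame": float(np.mean(fractions)),
        "worst_replicate": float(np.min(fractions)),
        "n_replicates": n_replicates,
    }


def rigid_recovery(n_replicates: int = 10, seed: int = 0, jitter: float = 3.0,
                   noise_sigma: float = 0.05) -> dict:
    """Chained registration recovery of injected per-slice rigid motion.

    Error per slice is the magnitude of (injected o estimated), which is
    identity under perfect recovery.
    """
    cfg = PhantomConfig(warp_strength=0.0, noise_sigma=noise_sigma, duration_s=1.0, seed=seed)
    gt = make_ground_truth(cfg)
    roi = make_default_rois(cfg)
    rng = np.random.default_rng(seed)
    worst_t, worst_p = 0.0, 0.0
    center = cfg.n_slices // 2
    for _ in range(n_replicates):
        true_t, series = [], []
        for p in range(cfg.n_slices):
            if p == center:
                t = RigidTransform2D()
            else:
                t = RigidTransform2D(
                    float(rng.uniform(-jitter, jitter)),
                    float(rng.uniform(-jitter, jitter)),
                    float(rng.uniform(-jitter, jitter)),
                )
            true_t.append(t)
            series.append(
                simulate_slice_series(gt, cfg, p, t, seed=int(rng.integers(0, 2**31 - 1)))
            )
        aligned = assemble_aligned(series, [None] * cfg.n_slices)
        _, results = register_chain(aligned, roi)
        for ti, r in zip(true_t, results):
            res_t, res_p = ti.compose(r.transform).magnitude
            worst_t = max(worst_t, res_t)
            worst_p = max(worst_p, res_p)
    return {
        "worst_translation_mm": worst_t,
        "worst_rotation_deg": worst_p,
        "n_replicates": n_replicates,
    }


def ordering_study(seed: int = 1, n_eval_frames: int = 8) -> dict:
    """Full pipeline on the default phantom; SNR, sharpness and smoothness
    for the registered-native, Tikhonov-SR and Beltrami-SR volumes."""
    cfg = PhantomConfig(seed=seed)
    series, audios, _ = simulate_protocol(cfg)
    center = cfg.n_slices // 2
    ref_k = next(k for k, s in enumerate(series) if s.slice_index == center)
    ceps = [compute_cepstrogram(AudioTrack(a.samples, a.rate_hz)) for a in audios]
    _, tracks = fit_reduce_features(ceps)
    feature_rate = audios[0].rate_hz / 64.0
    maps = [
        None if k == ref_k else map_frames(dtw_align(tracks[ref_k], tr), feature_rate,
                                           cfg.frame_rate_hz)
        for k, tr in enumerate(tracks)
    ]
    aligned = assemble_aligned(series, maps, n_frames=series[ref_k].n_frames)
    roi = make_default_rois(cfg)
    registered, _ = register_chain(aligned, roi)
    idx = sorted(set(np.linspace(0, cfg.n_frames - 1, n_eval_frames).round().astype(int)))
    recon_t = reconstruct_series(registered, RegularizerConfig(kind="tikhonov"), frame_indices=idx)
    recon_b = reconstruct_series(registered, RegularizerConfig(kind="beltrami"), frame_indices=idx)
    reports = {
        r.method_label: r
        for r in evaluate_methods(registered, recon_t, recon_b, roi, frame_indices=idx)
    }

    cfg0 = PhantomConfig(seed=seed, noise_sigma=0.0, duration_s=0.2)
    noiseless_mid = simulate_slice_series(make_ground_truth(cfg0), cfg0, center, None, seed=0)
    out = {
        "sharpness_native_noiseless": sharpness_index(noiseless_mid.data[0]),
        "max_iterations_tikhonov": max(v.iterations_used for v in recon_t),
        "max_iterations_beltrami": max(v.iterations_used for v in recon_b),
        "n_frames_evaluated": len(idx),
    }
    for name, r in reports.items():
        out[f"snr_{name}"] = r.snr_mean
        out[f"sharpness_{name}"] = float(r.sharpness.mean())
        out[f"smoothness_median_{name}"] = float(np.median(r.smoothness_values))
    return out


def _brute_force_dtw_cost(dist: np.ndarray) -> float:
    n, m = dist.shape
    best = [np.inf]

    def walk(i: int, j: int, acc: float) -> None:
        acc += dist[i, j]
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


def dtw_bruteforce_error(max_size: int = 8, seed: int = 0) -> float:
    """Max |DTW cost - exhaustive-enumeration cost| over all grid sizes up
    to ``max_size`` x ``max_size``."""
    from scipy.spatial.distance import cdist

    from vtsr.audio_align import FeatureTrack

    rng = np.random.default_rng(seed)
    worst = 0.0
    for n in range(1, max_size + 1):
        for m in range(1, max_size + 1):
            ref = rng.standard_normal((n, 3))
            qry = rng.standard_normal((m, 3))
            cost = dtw_align(
                FeatureTrack(ref, 250.0), FeatureTrack(qry, 250.0)
            ).cost
            brute = _brute_force_dtw_cost(cdist(ref, qry))
            worst = max(worst, abs(cost - brute))
    return worst
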