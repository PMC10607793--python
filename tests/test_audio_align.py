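import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vtsr.audio_align import (
    HOP,
    AudioTrack,
    FeatureTrack,
    WarpPath,
    compute_cepstrogram,
    dtw_align,
    fit_reduce_features,
    map_frames,
    warp_audio_piecewise,
)


def _track(frames: np.ndarray) -> FeatureTrack:
    return FeatureTrack(frames=np.asarray(frames, dtype=float), frame_rate_hz=250.0)


class TestCepstrogram:
    def test_frame_count_is_rate_over_64(self):
        audio = AudioTrack(samples=np.random.default_rng(0).standard_normal(16000), rate_hz=16000)
        ceps = compute_cepstrogram(audio)
        assert ceps.shape == (250, 64)

    def test_silence_gives_identical_frames(self):
        audio = AudioTrack(samples=np.zeros(6400), rate_hz=16000)
        ceps = compute_cepstrogram(audio)
        assert np.allclose(ceps, ceps[0])

    def test_gain_only_affects_zeroth_coefficient(self):
        t = np.arange(8192) / 16000
        x = np.sin(2 * np.pi * 440 * t)
        c1 = compute_cepstrogram(AudioTrack(samples=x, rate_hz=16000))
        c2 = compute_cepstrogram(AudioTrack(samples=2 * x, rate_hz=16000))
        # log-magnitude: scaling adds a constant => essentially only
        # quefrency 0 moves (tiny leakage where |DFT| ~ the log epsilon)
        interior = slice(20, -20)  # away from zero-padded edges
        d0 = np.abs(c2[interior, 0] - c1[interior, 0]).min()
        rest = np.abs(c2[interior, 1:] - c1[interior, 1:]).max()
        assert d0 > 0.5  # ~ log 2
        assert rest < 0.01 * d0

    def test_empty_audio_rejected(self):
        with pytest.raises(ValueError):
            compute_cepstrogram(AudioTrack(samples=np.array([]), rate_hz=16000))


class TestPCA:
    def test_low_rank_input_has_negligible_tail_variance(self):
        rng = np.random.default_rng(1)
        basis = rng.standard_normal((3, 64))
        frames = rng.standard_normal((200, 3)) @ basis
        proj, tracks = fit_reduce_features([frames], n_components=20)
        assert proj.explained_variance[3:].max() < 1e-10
        assert tracks[0].frames.shape == (200, 20)

    def test_mean_frame_projects_to_zero(self):
        rng = np.random.default_rng(2)
        frames = rng.standard_normal((100, 64))
        proj, _ = fit_reduce_features([frames])
        np.testing.assert_allclose(proj.transform(frames.mean(0)[None]), 0.0, atol=1e-10)

    def test_reconstruction_error_equals_discarded_variance(self):
        rng = np.random.default_rng(3)
        frames = rng.standard_normal((300, 64))
        proj, tracks = fit_reduce_features([frames], n_components=20)
        recon = tracks[0].frames @ proj.basis + proj.mean
        err = np.sum((frames - recon) ** 2) / (300 - 1)
        centered = frames - frames.mean(0)
        all_var = np.linalg.svd(centered, compute_uv=False) ** 2 / (300 - 1)
        np.testing.assert_allclose(err, all_var[20:].sum(), rtol=1e-10)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            fit_reduce_features([np.zeros((5, 64))], n_components=20)


def brute_force_dtw_cost(dist: np.ndarray) -> float:
    """Independent oracle: exhaustive DFS over all monotone full paths."""
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


class TestDTW:
    def test_identical_tracks_give_diagonal_zero_cost(self):
        frames = np.random.default_rng(0).standard_normal((12, 4))
        path = dtw_align(_track(frames), _track(frames))
        assert path.cost == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_array_equal(path.pairs[:, 0], path.pairs[:, 1])

    def test_repeated_frame_maps_to_single_reference(self):
        a, b, c = np.eye(3)
        ref = _track(np.stack([a, b, c]))
        query = _track(np.stack([a, a, b, c]))
        path = dtw_align(ref, query)
        assert path.cost == pytest.approx(0.0, abs=1e-12)
        # both query a's matched to reference frame 0
        matched = path.pairs[path.pairs[:, 1] <= 1, 0]
        assert set(matched.tolist()) == {0}

    def test_cost_symmetric_under_swap(self):
        rng = np.random.default_rng(4)
        a, b = _track(rng.standard_normal((9, 3))), _track(rng.standard_normal((7, 3)))
        assert dtw_align(a, b).cost == pytest.approx(dtw_align(b, a).cost, rel=1e-12)

    @pytest.mark.parametrize("shape", [(2, 3), (4, 4), (5, 7), (8, 8)])
    def test_matches_brute_force(self, shape):
        rng = np.random.default_rng(sum(shape))
        ref = rng.standard_normal((shape[0], 3))
        qry = rng.standard_normal((shape[1], 3))
        from scipy.spatial.distance import cdist

        dist = cdist(ref, qry)
        path = dtw_align(_track(ref), _track(qry))
        assert path.cost == pytest.approx(brute_force_dtw_cost(dist), rel=1e-12)

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            dtw_align(_track(np.zeros((0, 3))), _track(np.zeros((5, 3))))


class TestPiecewiseWarp:
    def test_identity_path_is_bit_identical(self):
        samples = np.random.default_rng(5).standard_normal(10 * HOP)
        audio = AudioTrack(samples=samples, rate_hz=16000)
        pairs = np.stack([np.arange(10), np.arange(10)], axis=1)
        out = warp_audio_piecewise(audio, WarpPath(pairs=pairs, cost=0.0))
        assert np.array_equal(out.samples, samples)

    def test_repeated_query_piece_appears_twice(self):
        samples = np.arange(3 * HOP, dtype=float)
        audio = AudioTrack(samples=samples, rate_hz=16000)
        # query frame 1 matched to reference frames 1 and 2
        pairs = np.array([(0, 0), (1, 1), (2, 1), (3, 2)])
        out = warp_audio_piecewise(audio, WarpPath(pairs=pairs, cost=0.0))
        assert out.samples.size == 4 * HOP
        assert np.array_equal(out.samples[HOP : 2 * HOP], samples[HOP : 2 * HOP])
        assert np.array_equal(out.samples[2 * HOP : 3 * HOP], samples[HOP : 2 * HOP])

    def test_pieces_never_rewritten(self):
        rng = np.random.default_rng(6)
        samples = rng.standard_normal(20 * HOP)
        audio = AudioTrack(samples=samples, rate_hz=16000)
        ref = _track(rng.standard_normal((25, 3)))
        qry = _track(rng.standard_normal((20, 3)))
        out = warp_audio_piecewise(audio, dtw_align(ref, qry))
        src = {samples[k * HOP : (k + 1) * HOP].tobytes() for k in range(20)}
        for k in range(out.samples.size // HOP):
            assert out.samples[k * HOP : (k + 1) * HOP].tobytes() in src

    def test_length_mismatch_rejected(self):
        audio = AudioTrack(samples=np.zeros(5 * HOP), rate_hz=16000)
        pairs = np.stack([np.arange(3), np.arange(3)], axis=1)
        with pytest.raises(ValueError, match="pieces"):
            warp_audio_piecewise(audio, WarpPath(pairs=pairs, cost=0.0))


class TestMapFrames:
    def test_identity_path_gives_identity_map(self):
        n = 50
        pairs = np.stack([np.arange(n), np.arange(n)], axis=1)
        fmap = map_frames(WarpPath(pairs=pairs, cost=0.0), 250.0, 50.0)
        np.testing.assert_array_equal(fmap.mapping, np.arange(n // 5))

    def test_half_speed_path_maps_to_floor_half(self):
        n_ref = 40
        pairs = np.array([(i, i // 2) for i in range(n_ref)])
        # make steps valid: consecutive (0,1)/(1,0)/(1,1) increments hold here
        fmap = map_frames(WarpPath(pairs=pairs, cost=0.0), 250.0, 50.0)
        np.testing.assert_array_equal(fmap.mapping, np.arange(n_ref // 5) // 2)

    def test_rate_mismatch_rejected(self):
        pairs = np.stack([np.arange(10), np.arange(10)], axis=1)
        with pytest.raises(ValueError, match="multiple"):
            map_frames(WarpPath(pairs=pairs, cost=0.0), 250.0, 60.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.sampled_from([(0, 1), (1, 0), (1, 1)]), min_size=10, max_size=120))
    def test_map_is_always_non_decreasing(self, steps):
        pairs = np.cumsum(np.array([(0, 0)] + steps), axis=0)
        path = WarpPath(pairs=pairs, cost=0.0)
        if path.n_ref < 5:
            return
        fmap = map_frames(path, 250.0, 50.0)
        assert np.all(np.diff(fmap.mapping) >= 0)
        assert fmap.mapping.min() >= 0
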