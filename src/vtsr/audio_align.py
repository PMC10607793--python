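"""Audio-driven temporal alignment of repetitions.

Each slice repetition is a separate reading of the same text, so the image
series are temporally misaligned.  The simultaneously recorded audio is the
alignment signal: short-time real cepstra (frame rate = sample rate / 64,
i.e. 250 Hz at 16 kHz) are reduced to 20 principal components, lateral
repetitions are aligned to the mid-sagittal reference by dynamic time
warping on these features, and the warping path is projected onto image
frame indices (5 feature frames per 20 ms image frame at the default rates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hann
from scipy.spatial.distance import cdist

from vtsr.core import AlignedVolumeSeries, SliceTimeSeries

__all__ = [
    "AudioTrack",
    "FeatureTrack",
    "WarpPath",
    "FrameMap",
    "PCAProjection",
    "compute_cepstrogram",
    "fit_reduce_features",
    "dtw_align",
    "warp_audio_piecewise",
    "map_frames",
    "assemble_aligned",
]

HOP = 64  # cepstral undersampling factor: one feature frame per 64 samples
WINDOW = 1024  # analysis window (Hann), chosen for spectral stability
N_QUEFRENCY = 64  # retained low-quefrency coefficients
LOG_EPS = 1e-10


@dataclass
class AudioTrack:
    """Mono waveform with acquisition-boundary markers."""

    samples: np.ndarray
    rate_hz: int
    markers: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        self.markers = np.asarray(self.markers, dtype=int)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.markers.size and (
            np.any(np.diff(self.markers) <= 0)
            or self.markers.min() < 0
            or self.markers.max() >= self.samples.size
        ):
            raise ValueError("markers must be sorted and in range")


@dataclass
class PCAProjection:
    mean: np.ndarray  # (Q,)
    basis: np.ndarray  # (K, Q), rows ordered by decreasing explained variance
    explained_variance: np.ndarray  # (K,)

    def transform(self, cepstrogram: np.ndarray) -> np.ndarray:
        return (np.asarray(cepstrogram) - self.mean) @ self.basis.T


@dataclass
class FeatureTrack:
    """PCA-reduced cepstral features at ``rate_hz / 64``."""

    frames: np.ndarray  # (T, K)
    frame_rate_hz: float
    projection: PCAProjection | None = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class WarpPath:
    """Monotone DTW path at the feature frame rate.

    ``pairs[k] = (ref_frame, query_frame)``; starts at (0, 0), ends at
    (T_ref - 1, T_query - 1), per-step increments in {(0,1), (1,0), (1,1)}.
    """

    pairs: np.ndarray  # (L, 2) int
    cost: float

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise ValueError("pairs must be (L, 2)")
        d = np.diff(self.pairs, axis=0)
        if np.any(d < 0) or np.any(d.sum(axis=1) < 1) or np.any(d > 1):
            raise ValueError("invalid path steps")
        if tuple(self.pairs[0]) != (0, 0):
            raise ValueError("path must start at (0, 0)")

    @property
    def n_ref(self) -> int:
        return int(self.pairs[-1, 0]) + 1

    @property
    def n_query(self) -> int:
        return int(self.pairs[-1, 1]) + 1


@dataclass
class FrameMap:
    """Per reference image frame, the source image frame in the query."""

    mapping: np.ndarray

    def __post_init__(self) -> None:
        self.mapping = np.asarray(self.mapping, dtype=int)
        if np.any(np.diff(self.mapping) < 0):
            raise ValueError("frame map must be non-decreasing")

    def __len__(self) -> int:
        return self.mapping.size

    def __getitem__(self, i: int) -> int:
        return int(self.mapping[i])


def compute_cepstrogram(audio: AudioTrack) -> np.ndarray:
    """Short-time real cepstrum, one frame per 64 samples.

    The signal is zero-padded by half a window on both sides (centered
    frames), windowed with a 1024-sample Hann window hopped by 64 samples,
    and per frame ``c = IDFT(log(|DFT| + eps))``; the first 64 quefrency
    coefficients are retained.  A T-sample track yields ``ceil(T / 64)``
    frames, i.e. the 250 Hz feature rate at 16 kHz.
    """
    x = audio.samples
    if x.size < 1:
        raise ValueError("empty audio")
    n_frames = -(-x.size // HOP)  # ceil
    pad = WINDOW // 2
    xp = np.concatenate([np.zeros(pad), x, np.zeros(pad + WINDOW)])
    idx = np.arange(n_frames)[:, None] * HOP + np.arange(WINDOW)[None, :]
    frames = xp[idx] * hann(WINDOW, sym=False)
    spectrum = np.fft.rfft(frames, axis=1)
    logmag = np.log(np.abs(spectrum) + LOG_EPS)
    ceps = np.fft.irfft(logmag, n=WINDOW, axis=1)
    return ceps[:, :N_QUEFRENCY]


def fit_reduce_features(
    cepstrograms: list[np.ndarray], n_components: int = 20
) -> tuple[PCAProjection, list[FeatureTrack]]:
    """Fit one PCA on the row-concatenation of all cepstrograms of an
    alignment task (reference + queries) and project each track onto the
    first ``n_components`` components.

    A shared basis is required so DTW distances are comparable between the
    reference and every query.
    """
    if not cepstrograms:
        raise ValueError("need at least one cepstrogram")
    qs = {c.shape[1] for c in cepstrograms}
    if len(qs) != 1:
        raise ValueError("cepstrograms must share the quefrency dimension")
    X = np.concatenate(cepstrograms, axis=0)
    if X.shape[0] < n_components:
        raise ValueError("fewer total frames than requested components")
    mean = X.mean(axis=0)
    _, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    var = s**2 / max(X.shape[0] - 1, 1)
    proj = PCAProjection(
        mean=mean, basis=vt[:n_components], explained_variance=var[:n_components]
    )
    tracks = [
        FeatureTrack(frames=proj.transform(c), frame_rate_hz=float("nan"), projection=proj)
        for c in cepstrograms
    ]
    return proj, tracks


def _dtw_matrix(dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Accumulated-cost DP with predecessor bookkeeping.

    Step choice codes: 0 = diagonal, 1 = up (ref advance), 2 = left (query
    advance); ties prefer the diagonal, then up.
    """
    n, m = dist.shape
    D = np.full((n, m), np.inf)
    choice = np.zeros((n, m), dtype=np.int8)
    D[0, 0] = dist[0, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + dist[0, j]
        choice[0, j] = 2
    # row-wise python scan; kept simple and exact (the D[i, j-1] dependency
    # prevents full vectorization)
    for i in range(1, n):
        Dp = D[i - 1]
        row = D[i]
        di = dist[i]
        row[0] = Dp[0] + di[0]
        choice[i, 0] = 1
        prev = row[0]
        dp_list = Dp.tolist()
        di_list = di.tolist()
        ch_row = choice[i]
        row_list = row.tolist()
        for j in range(1, m):
            diag = dp_list[j - 1]
            up = dp_list[j]
            left = prev
            best, c = diag, 0
            if up < best:
                best, c = up, 1
            if left < best:
                best, c = left, 2
            prev = best + di_list[j]
            row_list[j] = prev
            ch_row[j] = c
        D[i] = row_list
    return D, choice


def dtw_align(ref: FeatureTrack, query: FeatureTrack) -> WarpPath:
    """Classic DTW with Euclidean frame distance and symmetric steps
    {(0,1), (1,0), (1,1)}; full-path boundary conditions; diagonal preferred
    on ties."""
    a, b = np.atleast_2d(ref.frames), np.atleast_2d(query.frames)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty feature track")
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimensionality mismatch")
    dist = cdist(a, b, metric="euclidean")
    D, choice = _dtw_matrix(dist)
    i, j = dist.shape[0] - 1, dist.shape[1] - 1
    path = [(i, j)]
    while (i, j) != (0, 0):
        c = choice[i, j]
        if c == 0:
            i, j = i - 1, j - 1
        elif c == 1:
            i -= 1
        else:
            j -= 1
        path.append((i, j))
    path.reverse()
    return WarpPath(pairs=np.array(path), cost=float(D[-1, -1]))


def warp_audio_piecewise(audio: AudioTrack, path: WarpPath) -> AudioTrack:
    """Warp full-rate audio onto the reference timeline without resampling.

    The waveform is cut into 64-sample pieces (one per feature frame);
    following the path, pieces are repeated or dropped so that the output
    holds exactly one piece per reference feature frame, and the samples
    inside each piece are untouched.
    """
    n_pieces = -(-audio.samples.size // HOP)
    if path.n_query != n_pieces:
        raise ValueError(
            f"path covers {path.n_query} query frames but audio has {n_pieces} pieces"
        )
    pieces = [audio.samples[k * HOP : (k + 1) * HOP] for k in range(n_pieces)]
    # first matched query piece per reference frame
    ref_idx = path.pairs[:, 0]
    first = np.searchsorted(ref_idx, np.arange(path.n_ref), side="left")
    out = np.concatenate([pieces[path.pairs[k, 1]] for k in first])
    return AudioTrack(samples=out, rate_hz=audio.rate_hz)


def map_frames(
    path: WarpPath, feature_rate_hz: float = 250.0, image_rate_hz: float = 50.0
) -> FrameMap:
    """Project a feature-rate warp path onto image frame indices.

    Each reference image frame owns ``m = feature_rate / image_rate`` feature
    slots; per slot the matched query feature index is the median of the
    path's matches, the per-frame value is the median over the slots, and the
    query image frame is the one owning that feature slot (floor division by
    ``m``).  Median-of-slots is robust to single-frame path jitter.
    """
    m = feature_rate_hz / image_rate_hz
    if abs(m - round(m)) > 1e-9 or m < 1:
        raise ValueError("feature rate must be an integer multiple of the image rate")
    m = int(round(m))
    if path.n_ref < m:
        raise ValueError("path shorter than one image frame")
    # median matched query index per reference feature frame
    ref_idx = path.pairs[:, 0]
    qry_idx = path.pairs[:, 1]
    bounds = np.searchsorted(ref_idx, np.arange(path.n_ref + 1))
    per_ref = np.array(
        [np.median(qry_idx[bounds[r] : bounds[r + 1]]) for r in range(path.n_ref)]
    )
    n_img = path.n_ref // m
    mapping = np.empty(n_img, dtype=int)
    n_query_img = -(-path.n_query // m)
    for i in range(n_img):
        med = np.median(per_ref[i * m : (i + 1) * m])
        mapping[i] = min(int(med) // m, n_query_img - 1)
    return FrameMap(mapping=mapping)


def assemble_aligned(
    series: list[SliceTimeSeries],
    maps: list[FrameMap | None],
    n_frames: int | None = None,
) -> AlignedVolumeSeries:
    """Stack per-slice series into an aligned anisotropic volume series.

    ``maps[k]`` maps reference image frames to source frames of
    ``series[k]``; ``None`` means identity (the reference slice).  Slices
    are ordered by geometric position regardless of acquisition order.
    """
    if len(series) != len(maps):
        raise ValueError("need one frame map (or None) per series")
    order = np.argsort([s.slice_position_mm for s in series])
    positions = np.array([series[k].slice_position_mm for k in order])
    if np.unique(positions).size != positions.size:
        raise ValueError("duplicate slice positions")
    if n_frames is None:
        n_frames = min(
            len(maps[k]) if maps[k] is not None else series[k].n_frames
            for k in range(len(series))
        )
    H, W = series[0].data.shape[1:]
    frames = np.empty((n_frames, len(series), H, W))
    for out_s, k in enumerate(order):
        s, fmap = series[k], maps[k]
        for t in range(n_frames):
            src = t if fmap is None else fmap[t]
            src = min(src, s.n_frames - 1)
            frames[t, out_s] = s.data[src]
    voxel_mm = float(positions[1] - positions[0]) if positions.size > 1 else 1.6
    return AlignedVolumeSeries(
        frames=frames,
        slice_positions_mm=positions,
        voxel_mm=voxel_mm,
        frame_period_s=series[0].frame_period_s,
        thickness_mm=series[0].thickness_mm,
    )
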