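"""Empirical mode decomposition, its multivariate extension, and the
noise-assisted variant used as the pipeline's EEG filter.

A signal X(t) is decomposed into intrinsic mode functions (IMFs) plus a
residue, X(t) = sum_i C_i(t) + r_n(t), by iteratively subtracting the local
envelope mean (sifting). The multivariate form sifts all channels against a
shared envelope mean: the multichannel signal is projected onto K
well-spread unit direction vectors, the maxima of each projection are
interpolated (per channel, cubic splines with mirrored boundary extrema)
into one envelope per direction, and m(t) is the average of those K
envelopes. Because direction vectors come in near-opposite pairs, projection
maxima cover both the upper and lower envelope structure; with the direction
set collapsed to {+1, -1} on a single channel the procedure reduces exactly
to classic EMD's (max-spline + min-spline)/2.

The noise-assisted variant appends independent white-Gaussian channels to a
single-channel input before the multivariate sifting; the shared envelope
mean inherits the noise channels' dyadic filter-bank structure, which
suppresses mode mixing. Only the original channel's IMFs are returned.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .io_formats import Signal

__all__ = [
    "IMFSet",
    "DirectionSet",
    "SiftConfig",
    "TrendOnlyError",
    "hammersley_directions",
    "sign_directions",
    "envelope_mean",
    "memd",
    "na_memd",
    "reconstruct",
    "filter_signal",
]


class TrendOnlyError(ValueError):
    """Raised when a signal is monotone in every projection direction, i.e.
    it carries no oscillatory component and is pure residue."""


@dataclass
class IMFSet:
    """Ordered IMFs (fast to slow) plus residue for one channel.

    IMF indexing is 1-based throughout, so "IMF 2 + IMF 3" selects
    ``imfs[1] + imfs[2]``.
    """

    imfs: list[np.ndarray]
    residue: np.ndarray
    fs: float

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct_all(self) -> np.ndarray:
        total = self.residue.copy()
        for c in self.imfs:
            total += c
        return total


@dataclass
class DirectionSet:
    """K unit projection vectors on the (n_channels - 1)-sphere."""

    vectors: np.ndarray  # (K, n_channels)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("direction vectors must have unit norm")

    @property
    def K(self) -> int:
        return self.vectors.shape[0]


@dataclass
class SiftConfig:
    """Sifting parameters.

    ``stop_sd`` is the Cauchy-type threshold on successive sift iterates,
    SD = sum_t |h_prev - h|^2 / sum_t h_prev^2; a proto-IMF is accepted when
    SD falls below it or after ``max_sifts`` iterations. ``noise_channels``
    white-Gaussian channels at ``noise_sd_ratio`` times the signal SD are
    appended for the noise-assisted variant. Long signals are decomposed in
    contiguous blocks of ``block_len`` samples with ``block_overlap`` samples
    of context discarded at the seams.
    """

    K: int = 64
    max_sifts: int = 30
    stop_sd: float = 0.075
    max_imfs: int = 12
    boundary: str = "mirror"
    noise_channels: int = 2
    noise_sd_ratio: float = 0.1
    noise_seed: int = 0
    block_len: int = 10000
    block_overlap: int = 625

    def __post_init__(self) -> None:
        if self.K < 4:
            raise ValueError("need at least 4 projection directions")
        if self.stop_sd <= 0 or self.max_sifts <= 0 or self.max_imfs <= 0:
            raise ValueError("sifting thresholds must be positive")
        if self.boundary != "mirror":
            raise ValueError("only mirror boundary extension is implemented")


# ---------------------------------------------------------------------------
# Direction sets


def _radical_inverse(i: int, base: int) -> float:
    inv, f = 0.0, 1.0 / base
    while i > 0:
        inv += (i % base) * f
        i //= base
        f /= base
    return inv


def hammersley_directions(K: int, n_channels: int) -> DirectionSet:
    """Deterministic, well-spread unit vectors from a Hammersley point set.

    In the plane the 1-D Hammersley sequence k/K maps to equispaced angles.
    In higher dimension the points are pushed through the standard normal
    quantile and normalised, which spreads them uniformly on the sphere.
    """
    if K < 4:
        raise ValueError("K must be at least 4")
    if n_channels < 2:
        raise ValueError("direction sets require at least 2 channels")
    if n_channels == 2:
        theta = 2 * np.pi * np.arange(K) / K
        return DirectionSet(np.column_stack([np.cos(theta), np.sin(theta)]))
    from scipy.stats import norm

    primes = [2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37]
    pts = np.empty((K, n_channels))
    pts[:, 0] = (2 * np.arange(K) + 1) / (2 * K)
    for d in range(1, n_channels):
        base = primes[(d - 1) % len(primes)]
        pts[:, d] = [(_radical_inverse(i + 1, base) + 0.5 / K) % 1.0 for i in range(K)]
    g = norm.ppf(np.clip(pts, 1e-12, 1 - 1e-12))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    return DirectionSet(g)


def sign_directions() -> DirectionSet:
    """The single-channel direction set {+1, -1}, under which the
    multivariate envelope mean degenerates to classic EMD."""
    return DirectionSet(np.array([[1.0], [-1.0]]))


# ---------------------------------------------------------------------------
# Envelopes


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima."""
    return 1 + np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:]))


def _mirror_extend(idx: np.ndarray, vals: np.ndarray, n: int):
    """Reflect up to two extrema across each signal boundary.

    ``idx`` are extremum sample positions, ``vals`` the (multichannel)
    values there. Returns extended (positions, values) ready for spline
    fitting over the full grid [0, n-1].
    """
    left_src = idx[idx > 0][:2]
    right_src = idx[idx < n - 1][-2:]
    t_left = (-left_src)[::-1]
    t_right = (2 * (n - 1) - right_src)[::-1]
    pos = np.concatenate([t_left, idx, t_right])
    sel_left = np.flatnonzero(np.isin(idx, left_src))[:2]
    sel_right = np.flatnonzero(np.isin(idx, right_src))[-2:]
    v = np.concatenate([vals[sel_left][::-1], vals, vals[sel_right][::-1]], axis=0)
    return pos, v


def _direction_envelope(X: np.ndarray, v: np.ndarray, grid: np.ndarray):
    """Envelope through the multichannel samples at the maxima of X·v, or
    None when the projection has fewer than two maxima.

    Directions nearly orthogonal to the signal subspace (projection power
    negligible against the signal) are rejected: their "extrema" are float
    noise, not oscillation structure.
    """
    proj = X @ v
    scale = np.sqrt(np.mean(X**2))
    if scale > 0 and np.std(proj) <= 1e-10 * scale:
        return None
    idx = _local_maxima(proj)
    if idx.size < 2:
        return None
    pos, vals = _mirror_extend(idx, X[idx], X.shape[0])
    if pos.size < 4:
        return None
    return CubicSpline(pos, vals, axis=0)(grid)


def envelope_mean(X: np.ndarray, directions: DirectionSet) -> np.ndarray:
    """Average of the per-direction multivariate envelopes, m(t).

    ``X`` has shape (n_samples, n_channels). Directions whose projection has
    fewer than two local maxima are skipped; if every direction is unusable
    the input carries no oscillation and :class:`TrendOnlyError` is raised.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < X.shape[1]:
        raise ValueError("X must be (n_samples, n_channels) with n_samples >= n_channels")
    n = X.shape[0]
    grid = np.arange(n, dtype=float)
    total = np.zeros_like(X)
    usable = 0
    for v in directions.vectors:
        env = _direction_envelope(X, v, grid)
        if env is not None:
            total += env
            usable += 1
    if usable == 0:
        raise TrendOnlyError("trend only: no projection has two local maxima")
    return total / usable


# ---------------------------------------------------------------------------
# Decomposition


def memd(X: np.ndarray, config: SiftConfig | None = None, fs: float = 1.0,
         directions: DirectionSet | None = None) -> list[IMFSet]:
    """Multivariate EMD via synchronized sifting.

    ``X`` is (n_samples, n_channels). At each sift the shared envelope mean
    is subtracted from the proto-IMF across all channels simultaneously, so
    every channel yields the same number of IMFs (mode alignment). Each
    channel's IMFs-plus-residue sum reconstructs that channel exactly.
    """
    config = config or SiftConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_samples, n_channels)")
    n, d = X.shape
    if n < 16:
        raise ValueError("need at least 16 samples")
    if directions is None:
        directions = (
            hammersley_directions(config.K, d) if d >= 2 else sign_directions()
        )

    residue = X.copy()
    imf_layers: list[np.ndarray] = []
    while len(imf_layers) < config.max_imfs:
        h = residue.copy()
        accepted = False
        for sift in range(config.max_sifts):
            try:
                m = envelope_mean(h, directions)
            except TrendOnlyError:
                if sift == 0:
                    accepted = False
                else:
                    accepted = True
                break
            h_new = h - m
            denom = float((h**2).sum())
            sd = float(((h - h_new) ** 2).sum()) / denom if denom > 0 else 0.0
            h = h_new
            if sd < config.stop_sd:
                accepted = True
                break
        else:
            accepted = True
        if not accepted:
            break
        imf_layers.append(h)
        residue = residue - h

    return [
        IMFSet(
            imfs=[layer[:, c].copy() for layer in imf_layers],
            residue=residue[:, c].copy(),
            fs=fs,
        )
        for c in range(d)
    ]


def na_memd(signal: Signal, config: SiftConfig | None = None) -> IMFSet:
    """Noise-assisted MEMD of a single-channel signal.

    Builds the composite [signal, noise_1, ..., noise_m] with i.i.d. Gaussian
    channels of SD ``noise_sd_ratio`` x SD(signal), runs the multivariate
    decomposition, and returns only the original channel's IMFs. The noise
    channels are seeded by ``noise_seed``, so the decomposition is
    deterministic.
    """
    config = config or SiftConfig()
    x = signal.samples
    sd = float(np.std(x))
    if sd == 0.0:
        raise ValueError("cannot decompose a zero-variance signal")
    rng = np.random.default_rng(config.noise_seed)
    noise = rng.normal(0.0, config.noise_sd_ratio * sd, size=(x.size, config.noise_channels))
    X = np.column_stack([x, noise])
    return memd(X, config, fs=signal.fs)[0]


def reconstruct(imfset: IMFSet, indices, include_residue: bool = False) -> Signal:
    """Pointwise sum of the selected IMFs (1-based indices).

    The pipeline default, indices (2, 3), keeps the mid-frequency modes and
    discards the fastest (noise-dominated) and slowest (trend) ones.
    """
    indices = sorted(set(int(i) for i in indices))
    for i in indices:
        if i < 1 or i > imfset.n_imfs:
            raise IndexError(
                f"IMF index {i} out of range 1..{imfset.n_imfs}"
            )
    out = np.zeros_like(imfset.residue)
    for i in indices:
        out += imfset.imfs[i - 1]
    if include_residue:
        out += imfset.residue
    return Signal(out, imfset.fs)


def filter_signal(signal: Signal, config: SiftConfig | None = None,
                  indices=(2, 3)) -> Signal:
    """Noise-assisted MEMD filtering of an arbitrarily long signal.

    The signal is decomposed in contiguous blocks of ``block_len`` samples;
    each block is extended by ``block_overlap`` samples of context on both
    sides, which are discarded after reconstruction so spline boundary
    effects never reach a seam. Per-block noise channels are seeded from
    ``noise_seed`` plus the block index. IMF indices absent from a block's
    decomposition (short blocks produce fewer modes) are ignored for that
    block.
    """
    config = config or SiftConfig()
    x = signal.samples
    n = x.size
    bl, ov = config.block_len, config.block_overlap
    starts = list(range(0, n, bl))
    # merge a short tail into the previous block
    if len(starts) > 1 and n - starts[-1] < max(2 * ov, 16):
        starts.pop()
    out = np.empty(n)
    for b, s in enumerate(starts):
        e = min(n, s + bl) if b < len(starts) - 1 else n
        s_ext, e_ext = max(0, s - ov), min(n, e + ov)
        seg = Signal(x[s_ext:e_ext], signal.fs)
        block_cfg = replace(config, noise_seed=(config.noise_seed + b) % (2**31))
        imfset = na_memd(seg, block_cfg)
        usable = [i for i in indices if 1 <= i <= imfset.n_imfs]
        rec = reconstruct(imfset, usable).samples if usable else np.zeros(seg.samples.size)
        out[s:e] = rec[s - s_ext : s - s_ext + (e - s)]
    return Signal(out, signal.fs, start_time=signal.start_time)
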