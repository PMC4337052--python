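"""Sample entropy and its windowed application at the monitor cadence.

SampEn(m, r, N) = -ln( C_{m+1}(r) / C_m(r) ), where C_m(r) counts ordered
template pairs (i, j), i != j, whose m-length templates lie within Chebyshev
distance r of each other. Self-matches are excluded, which removes the bias
approximate entropy suffers from. Lower values indicate a more regular
signal — under anesthesia the EEG loses complexity, so SampEn falls with
anesthetic depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import Signal

__all__ = ["SampEnParams", "EntropyTrack", "sample_entropy", "windowed_sampen"]


@dataclass
class SampEnParams:
    """Parameters of the windowed sample-entropy stage.

    m=2 and a tolerance of 0.1 standard deviations are the standard choices
    for physiological series; a 625-sample window at 125 Hz emits one value
    per 5 s, matching the cadence of commercial consciousness monitors.
    """

    m: int = 2
    r_rel: float = 0.1
    window: int = 625
    hop: int = 625
    per_window_sd: bool = True  # tolerance from each window's own SD
    template_universe: str = "shared"  # "shared" (Richman–Moorman) or "full"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r_rel <= 0:
            raise ValueError("relative tolerance must be positive")
        if self.window <= self.m + 1:
            raise ValueError("window must exceed m + 1 samples")
        if self.hop < 1:
            raise ValueError("hop must be >= 1")
        if self.template_universe not in ("shared", "full"):
            raise ValueError("template_universe must be 'shared' or 'full'")


@dataclass
class EntropyTrack:
    """SampEn values (nats) at window-end times; NaN marks windows where the
    statistic is undefined (zero variance or no template matches)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    def __len__(self) -> int:
        return self.times.size


def _pair_count(templates: np.ndarray, r_abs: float) -> int:
    """Ordered pairs (i, j), i != j, with Chebyshev distance strictly < r."""
    n = templates.shape[0]
    if n < 2:
        return 0
    # pairwise Chebyshev distances, blocked to bound memory on long windows
    count = 0
    block = 2048
    for s in range(0, n, block):
        d = np.abs(templates[s : s + block, None, :] - templates[None, :, :]).max(axis=2)
        count += int((d < r_abs).sum())
        count -= min(block, n - s)  # remove the i == j diagonal entries
    return count


def sample_entropy(
    x,
    m: int = 2,
    r_abs: float | None = None,
    template_universe: str = "shared",
) -> float:
    """Sample entropy of a sequence with an absolute tolerance.

    Matching uses the Chebyshev (maximum-coordinate) distance with a strict
    ``< r`` comparison. ``template_universe`` selects which m-length
    templates enter the denominator count: ``"shared"`` restricts both
    template lengths to the indices 1..N-m for which an (m+1)-length
    template also exists (the standard A/B ratio); ``"full"`` counts the
    m-length matches over all N-m+1 templates. The printed normaliser
    (N-m+1)(N-m) is common to both counts and cancels in the ratio.

    Returns NaN when either count is zero — the statistic is undefined and
    never reported as infinite.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"need more than m + 1 = {m + 1} samples, got {n}")
    if r_abs is None or r_abs <= 0:
        raise ValueError("r_abs must be a positive absolute tolerance")

    templates_m = sliding_window_view(x, m)  # (n - m + 1, m)
    templates_m1 = sliding_window_view(x, m + 1)  # (n - m, m + 1)
    if template_universe == "shared":
        count_m = _pair_count(templates_m[: n - m], r_abs)
    elif template_universe == "full":
        count_m = _pair_count(templates_m, r_abs)
    else:
        raise ValueError("template_universe must be 'shared' or 'full'")
    if count_m == 0:
        return float("nan")
    count_m1 = _pair_count(templates_m1, r_abs)
    if count_m1 == 0:
        return float("nan")
    return float(-np.log(count_m1 / count_m))


def windowed_sampen(signal: Signal, params: SampEnParams | None = None) -> EntropyTrack:
    """Sample entropy over sliding (default non-overlapping) windows.

    The tolerance is ``r_rel`` times the standard deviation of each window
    (or of the whole signal when ``per_window_sd`` is off), which makes the
    track invariant to amplitude rescaling. Each window is stamped with its
    end time; a trailing partial window is dropped.
    """
    params = params or SampEnParams()
    x = signal.samples
    if x.size < params.window:
        raise ValueError(
            f"signal ({x.size} samples) shorter than one window ({params.window})"
        )
    global_sd = float(np.std(x))
    times, values = [], []
    for start in range(0, x.size - params.window + 1, params.hop):
        w = x[start : start + params.window]
        sd = float(np.std(w)) if params.per_window_sd else global_sd
        t_end = signal.start_time + (start + params.window) / signal.fs
        if sd == 0.0:
            se = float("nan")
        else:
            se = sample_entropy(
                w, params.m, params.r_rel * sd, params.template_universe
            )
        times.append(t_end)
        values.append(se)
    return EntropyTrack(np.array(times), np.array(values))
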