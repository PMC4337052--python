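"""Synthetic anesthesia sessions with consciousness-dependent irregularity.

The generator does not attempt biophysical EEG realism. It provides exactly
the statistical structure the entropy-based index relies on: a smooth 0-100
consciousness trajectory (awake -> surgical maintenance -> awake), an EEG
whose irregularity decreases monotonically with anesthetic depth, and
transient high-amplitude bursts mimicking electrosurgical interference.

Irregularity is controlled by the MIX(p) process — with probability ``p`` a
sample is i.i.d. uniform noise, otherwise it follows a deterministic
sinusoid. Sample entropy is a monotone function of ``p``, which gives every
downstream stage a ground truth that clinical recordings cannot provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import IndexSeries, SessionBundle, Signal

__all__ = [
    "TrajectorySpec",
    "GeneratorSpec",
    "consciousness_trajectory",
    "mix_signal",
    "generate_session",
]

#: consciousness -> MIX mixing parameter, piecewise linear breakpoints.
#: Chosen so the surgical band (40-60) sits clearly below the awake level in
#: sample entropy, with margin for observation noise.
DEFAULT_COMPLEXITY_MAP: tuple[tuple[float, float], ...] = (
    (0.0, 0.05),
    (45.0, 0.15),
    (100.0, 0.9),
)

#: carrier frequency of the MIX sinusoid, Hz (alpha-band-like at fs=125)
DEFAULT_CARRIER_HZ = 10.0

#: nominal EEG amplitude scale, microvolts (MIX is unit-variance)
EEG_SCALE_UV = 20.0

#: spacing of the consciousness tracks, matching the monitor cadence
TRACK_SPACING_S = 5.0


@dataclass
class TrajectorySpec:
    """Phase layout and levels of a session's consciousness trajectory.

    The defaults describe a desk-scale session: 10 minutes total with one
    minute awake, a two-minute induction, five minutes of surgical
    maintenance and a two-minute emergence. ``transition_smoothness`` is the
    logistic time constant of the induction/emergence transitions in
    seconds.
    """

    duration_s: float = 600.0
    induction_s: float = 60.0
    maintenance_s: float = 180.0
    emergence_s: float = 480.0
    awake_level: float = 97.0
    maintenance_level: float = 45.0
    transition_smoothness: float = 20.0
    wander_amplitude: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.induction_s < self.maintenance_s < self.emergence_s < self.duration_s):
            raise ValueError(
                "phase boundaries must satisfy 0 < induction < maintenance "
                "< emergence < duration"
            )
        for name in ("awake_level", "maintenance_level"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if self.awake_level <= self.maintenance_level:
            raise ValueError("awake level must exceed maintenance level")
        if self.transition_smoothness <= 0:
            raise ValueError("transition_smoothness must be positive")


@dataclass
class GeneratorSpec:
    """Full description of one synthetic session."""

    trajectory: TrajectorySpec = field(default_factory=TrajectorySpec)
    fs: float = 125.0
    complexity_map: tuple[tuple[float, float], ...] = DEFAULT_COMPLEXITY_MAP
    carrier_hz: float = DEFAULT_CARRIER_HZ
    artifact_rate: float = 1.0  # events per minute
    artifact_amplitude: float = 5.0  # multiple of clean-signal SD
    noise_seed: int = 0

    def __post_init__(self) -> None:
        cmap = np.asarray(self.complexity_map, dtype=float)
        if np.any(np.diff(cmap[:, 0]) <= 0):
            raise ValueError("complexity_map consciousness grid must increase")
        if np.any(np.diff(cmap[:, 1]) < 0):
            raise ValueError("complexity_map must be monotone nondecreasing")
        if not cmap[0, 1] < cmap[-1, 1]:
            raise ValueError("complexity_map must satisfy p(0) < p(100)")
        if np.any((cmap[:, 1] < 0) | (cmap[:, 1] > 1)):
            raise ValueError("mixing parameters must lie in [0, 1]")

    def mixing_parameter(self, consciousness) -> np.ndarray:
        """Map consciousness level(s) in [0, 100] to the MIX parameter p."""
        cmap = np.asarray(self.complexity_map, dtype=float)
        return np.interp(consciousness, cmap[:, 0], cmap[:, 1])


def consciousness_trajectory(spec: TrajectorySpec, times) -> IndexSeries:
    """Evaluate the deterministic consciousness curve at ``times``.

    The curve is awake-level before induction, descends sigmoidally to the
    maintenance level, wanders slowly (bounded by ``wander_amplitude``)
    through the plateau, and ascends sigmoidally at emergence. It is C1 by
    construction (sums and products of logistics and sinusoids).
    """
    times = np.asarray(times, dtype=float)
    if times.size and (times.min() < -1e-9 or times.max() > spec.duration_s + 1e-9):
        raise ValueError("times must lie within [0, duration]")
    tau = spec.transition_smoothness
    c_down = 0.5 * (spec.induction_s + spec.maintenance_s)
    c_up = 0.5 * (spec.emergence_s + spec.duration_s)

    def logistic(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

    g_down = logistic((times - c_down) / tau)  # 0 awake -> 1 maintained
    g_up = logistic((times - c_up) / tau)  # 0 -> 1 at emergence
    depth_gate = g_down * (1.0 - g_up)
    level = spec.awake_level - (spec.awake_level - spec.maintenance_level) * depth_gate

    # slow deterministic wander on the plateau, strictly bounded
    w = 0.6 * np.sin(2 * np.pi * times / 240.0) + 0.4 * np.sin(2 * np.pi * times / 97.0)
    level = level + spec.wander_amplitude * w * depth_gate
    return IndexSeries(times, np.clip(level, 0.0, 100.0))


def mix_signal(
    p: float,
    n: int,
    fs: float,
    freq_hz: float = DEFAULT_CARRIER_HZ,
    rng: np.random.Generator | None = None,
) -> Signal:
    """The MIX(p) irregularity process.

    Each sample is, independently with probability ``p``, uniform on
    [-sqrt(3), sqrt(3)] (unit variance), and otherwise the deterministic unit
    variance sinusoid sqrt(2)*sin(2*pi*freq_hz*t). ``p`` interpolates between
    a pure tone (p=0) and white noise (p=1).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"mixing parameter p must lie in [0, 1], got {p}")
    rng = np.random.default_rng(0) if rng is None else rng
    t = np.arange(n) / fs
    tone = np.sqrt(2.0) * np.sin(2 * np.pi * freq_hz * t)
    replace = rng.random(n) < p
    noise = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=n)
    return Signal(np.where(replace, noise, tone), fs)


def _mix_time_varying(p_t: np.ndarray, fs: float, freq_hz: float, rng) -> np.ndarray:
    """MIX with a per-sample mixing parameter (shared draw structure with
    :func:`mix_signal`)."""
    n = p_t.size
    t = np.arange(n) / fs
    tone = np.sqrt(2.0) * np.sin(2 * np.pi * freq_hz * t)
    replace = rng.random(n) < p_t
    noise = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=n)
    return np.where(replace, noise, tone)


def _inject_artifacts(
    eeg: np.ndarray, fs: float, rate_per_min: float, amplitude_sd: float, rng
) -> list[float]:
    """Poisson-timed short broadband bursts; returns the burst onset times."""
    duration_s = eeg.size / fs
    n_events = rng.poisson(rate_per_min * duration_s / 60.0)
    sd = float(np.std(eeg))
    onsets = np.sort(rng.uniform(0.0, duration_s, size=n_events))
    for onset in onsets:
        width = rng.uniform(0.2, 1.0)
        i0 = int(onset * fs)
        i1 = min(eeg.size, i0 + max(1, int(width * fs)))
        m = i1 - i0
        envelope = np.hanning(m)
        burst = amplitude_sd * sd * envelope * rng.standard_normal(m)
        eeg[i0:i1] += burst
    return [float(t) for t in onsets]


def generate_session(spec: GeneratorSpec) -> SessionBundle:
    """Generate one labelled synthetic session.

    All stochastic draws flow from a single ``numpy`` generator seeded with
    ``spec.noise_seed``, so identical specs produce identical bundles.
    """
    rng = np.random.default_rng(spec.noise_seed)
    traj = spec.trajectory
    n = int(round(traj.duration_s * spec.fs))
    sample_times = np.arange(n) / spec.fs

    c_t = consciousness_trajectory(traj, sample_times).values
    p_t = spec.mixing_parameter(c_t)
    eeg = EEG_SCALE_UV * _mix_time_varying(p_t, spec.fs, spec.carrier_hz, rng)

    events: list[tuple[float, str]] = [
        (traj.induction_s, "induction_start"),
        (traj.maintenance_s, "maintenance_start"),
        (traj.emergence_s, "emergence_start"),
    ]
    if spec.artifact_rate > 0:
        for t in _inject_artifacts(
            eeg, spec.fs, spec.artifact_rate, spec.artifact_amplitude, rng
        ):
            events.append((t, "artifact"))
    events.sort(key=lambda ev: ev[0])

    track_times = np.arange(TRACK_SPACING_S, traj.duration_s + 1e-9, TRACK_SPACING_S)
    eacl = consciousness_trajectory(traj, track_times)

    # BIS-like reference: the truth seen through bounded AR(1) observation
    # noise with stationary SD 5, clipped to the index range.
    phi, obs_sd = 0.8, 5.0
    innov_sd = obs_sd * np.sqrt(1 - phi**2)
    noise = np.empty(track_times.size)
    noise[0] = rng.normal(0.0, obs_sd)
    shocks = rng.normal(0.0, innov_sd, size=track_times.size)
    for k in range(1, track_times.size):
        noise[k] = phi * noise[k - 1] + shocks[k]
    bis_values = np.clip(eacl.values + noise, 0.0, 100.0)
    bis_ref = IndexSeries(track_times.copy(), bis_values)

    meta = {
        "seed": int(spec.noise_seed),
        "generator": {
            "fs": spec.fs,
            "duration_s": traj.duration_s,
            "awake_level": traj.awake_level,
            "maintenance_level": traj.maintenance_level,
            "artifact_rate": spec.artifact_rate,
            "artifact_amplitude": spec.artifact_amplitude,
            "carrier_hz": spec.carrier_hz,
            "complexity_map": [list(bp) for bp in spec.complexity_map],
        },
        "session_id": f"synthetic-{spec.noise_seed}",
    }
    return SessionBundle(
        eeg=Signal(eeg, spec.fs),
        eacl=eacl,
        bis_ref=bis_ref,
        events=events,
        meta=meta,
    )
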