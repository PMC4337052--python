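"""Reading, writing and validation of the on-disk session layout.

A surgical session is stored as a directory containing the raw EEG (CSV by
default, single-channel EDF optionally), the consciousness tracks as
two-column CSV files, an events CSV and a JSON manifest ``session.json``
recording the sampling rate, duration, seed and generator parameters.

EEG amplitudes are treated as microvolts but nothing downstream depends on
the unit: the entropy stage uses a tolerance relative to the window standard
deviation, so the pipeline is scale-invariant.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Signal",
    "IndexSeries",
    "SessionBundle",
    "read_eeg",
    "write_eeg_csv",
    "write_edf",
    "read_index_series",
    "write_index_series",
    "write_session",
    "read_session",
]

MANIFEST_NAME = "session.json"
_FORMAT_VERSION = 1


@dataclass
class Signal:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    samples : ndarray
        Sample values (microvolts for EEG; units are carried implicitly).
    fs : float
        Sampling rate in Hz, strictly positive.
    start_time : float
        Offset of the first sample from session start, in seconds.
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("Signal requires a one-dimensional, non-empty sample array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        bad = np.flatnonzero(~np.isfinite(self.samples))
        if bad.size:
            raise ValueError(f"non-finite sample at index {bad[0]}")

    @property
    def duration(self) -> float:
        """Signal duration in seconds (n / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs


@dataclass
class IndexSeries:
    """A 0-100 bounded score track (EACL, BIS-like reference, or predicted
    depth-of-anesthesia index), nominally one value per 5 s."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            k = int(np.flatnonzero(dt <= 0)[0])
            raise ValueError(f"times not strictly increasing at row {k + 1}")
        bad = np.flatnonzero(~((self.values >= 0.0) & (self.values <= 100.0)))
        if bad.size:
            k = int(bad[0])
            raise ValueError(
                f"value out of range [0, 100] at row {k}: {self.values[k]}"
            )

    def __len__(self) -> int:
        return self.times.size


@dataclass
class SessionBundle:
    """One surgical session: raw EEG, ground-truth EACL track, optional
    BIS-like reference, event annotations and free-form metadata."""

    eeg: Signal
    eacl: IndexSeries
    bis_ref: IndexSeries | None = None
    events: list[tuple[float, str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t0 = self.eeg.start_time
        t1 = t0 + self.eeg.duration
        if self.eacl.times[0] < t0 - 1e-9 or self.eacl.times[-1] > t1 + 1e-9:
            raise ValueError(
                "EACL time span must be contained within the EEG time span"
            )

    @property
    def session_id(self) -> str:
        return str(self.meta.get("session_id", "session"))


# ---------------------------------------------------------------------------
# EEG readers / writers


def read_eeg(path, format_hint: str | None = None, fs: float | None = None) -> Signal:
    """Read an EEG signal from an EDF file or a single-column CSV.

    For CSV input the sampling rate cannot be inferred and must be passed via
    ``fs``; for EDF it is taken from the header (an explicit ``fs`` that
    disagrees with the header is an error).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        samples, header_fs = _read_edf_first_channel(path)
        if fs is not None and abs(fs - header_fs) > 1e-9:
            raise ValueError(
                f"fs argument ({fs}) disagrees with EDF header ({header_fs})"
            )
        return Signal(samples, header_fs)
    if fmt == "csv":
        if fs is None:
            raise ValueError("reading EEG from CSV requires an explicit fs argument")
        raw = pd.read_csv(path, header=None, comment="#")
        col = raw.iloc[:, 0]
        if isinstance(col.iloc[0], str):  # optional single header line
            col = col.iloc[1:]
        samples = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(samples))
        if bad.size:
            raise ValueError(f"non-finite sample at row {int(bad[0])} of {path.name}")
        return Signal(samples, fs)
    raise ValueError(f"unsupported EEG format {fmt!r} (expected 'edf' or 'csv')")


def write_eeg_csv(signal: Signal, path) -> None:
    """Write samples one per row with full float precision (exact round-trip)."""
    np.savetxt(path, signal.samples, fmt="%.17g", header="eeg_uv", comments="")


def _read_edf_first_channel(path: Path) -> tuple[np.ndarray, float]:
    """Read the first channel of an EDF file via MNE, returned in the file's
    physical units (microvolts for EEG channels)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data(picks=[0])[0]
    # MNE rescales EEG channels from the EDF's microvolts to volts.
    unit = raw._orig_units.get(raw.ch_names[0], "uV") if hasattr(raw, "_orig_units") else "uV"
    if unit in ("uV", "µV"):
        data = data * 1e6
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite sample in EDF file {path.name}")
    return np.asarray(data, dtype=float), fs


def write_edf(signal: Signal, path, label: str = "EEG Fp") -> None:
    """Write a single-channel EDF file.

    EDF stores 16-bit integers, so amplitudes are quantised to
    (physical range) / 65536; callers needing exact round-trips should use
    the CSV writer instead. The record duration is one second, which requires
    an integer sampling rate.
    """
    fs = signal.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    x = signal.samples
    n_records = int(np.ceil(x.size / fs))
    padded = np.zeros(n_records * fs)
    padded[: x.size] = x

    pmax = float(np.max(np.abs(padded)))
    pmax = max(pmax, 1.0) * 1.0000001  # avoid digital overflow at the extremes
    pmin = -pmax
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.round((padded - pmin) * gain + dmin), dmin, dmax).astype("<i2")

    def f(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),  # local patient id
            f("Startdate X X X X", 80),
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 + 256), 8),  # header bytes: 256 + 256 per signal
            f("", 44),
            f(str(n_records), 8),
            f("1", 8),  # record duration, seconds
            f("1", 4),  # number of signals
            # per-signal fields
            f(label, 16),
            f("", 80),  # transducer
            f("uV", 8),
            f(f"{pmin:.6g}", 8),
            f(f"{pmax:.6g}", 8),
            f(str(dmin), 8),
            f(str(dmax), 8),
            f("", 80),  # prefiltering
            f(str(fs), 8),  # samples per record
            f("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(struct.pack(f"<{digital.size}h", *digital))


# ---------------------------------------------------------------------------
# Index-series CSV


def read_index_series(path) -> IndexSeries:
    """Read a ``time_s,value`` CSV into a validated IndexSeries.

    Out-of-range values and non-increasing times are errors — tracks are
    never silently clipped.
    """
    df = pd.read_csv(path)
    if not {"time_s", "value"}.issubset(df.columns):
        df = pd.read_csv(path, header=None, names=["time_s", "value"])
    times = pd.to_numeric(df["time_s"], errors="raise").to_numpy(dtype=float)
    values = pd.to_numeric(df["value"], errors="raise").to_numpy(dtype=float)
    return IndexSeries(times, values)


def write_index_series(series: IndexSeries, path) -> None:
    pd.DataFrame({"time_s": series.times, "value": series.values}).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# Session directories


def write_session(bundle: SessionBundle, directory, eeg_format: str = "csv") -> Path:
    """Write a SessionBundle to ``directory`` and return the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if eeg_format == "csv":
        eeg_file = "eeg.csv"
        write_eeg_csv(bundle.eeg, directory / eeg_file)
    elif eeg_format == "edf":
        eeg_file = "eeg.edf"
        write_edf(bundle.eeg, directory / eeg_file)
    else:
        raise ValueError(f"unknown eeg_format {eeg_format!r}")

    write_index_series(bundle.eacl, directory / "eacl.csv")
    if bundle.bis_ref is not None:
        write_index_series(bundle.bis_ref, directory / "bis_ref.csv")
    pd.DataFrame(bundle.events, columns=["time_s", "label"]).to_csv(
        directory / "events.csv", index=False, float_format="%.17g"
    )

    manifest = {
        "version": _FORMAT_VERSION,
        "fs_hz": bundle.eeg.fs,
        "duration_s": bundle.eeg.duration,
        "eeg_file": eeg_file,
        "seed": bundle.meta.get("seed"),
        "generator": bundle.meta.get("generator"),
        "session_id": bundle.session_id,
    }
    manifest_path = directory / MANIFEST_NAME
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def read_session(directory) -> SessionBundle:
    """Read a session directory written by :func:`write_session`."""
    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest {MANIFEST_NAME} in {directory}")
    manifest = json.loads(manifest_path.read_text())
    fs = float(manifest["fs_hz"])
    eeg_file = manifest.get("eeg_file", "eeg.csv")
    if eeg_file.endswith(".edf"):
        eeg = read_eeg(directory / eeg_file)
        if abs(eeg.fs - fs) > 1e-9:
            raise ValueError(
                f"manifest fs {fs} Hz disagrees with EDF header {eeg.fs} Hz"
            )
    else:
        eeg = read_eeg(directory / eeg_file, fs=fs)

    eacl = read_index_series(directory / "eacl.csv")
    bis_path = directory / "bis_ref.csv"
    bis_ref = read_index_series(bis_path) if bis_path.exists() else None
    events_df = pd.read_csv(directory / "events.csv")
    events = [(float(t), str(lbl)) for t, lbl in events_df.itertuples(index=False)]
    meta = {
        "seed": manifest.get("seed"),
        "generator": manifest.get("generator"),
        "session_id": manifest.get("session_id", directory.name),
    }
    return SessionBundle(eeg=eeg, eacl=eacl, bis_ref=bis_ref, events=events, meta=meta)
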