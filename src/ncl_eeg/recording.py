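"""Containers and file I/O for multichannel EEG/EOG recordings.

The canonical in-memory object is :class:`EEGRecording`: a channels x samples
matrix in microvolts, a sampling rate and a per-channel role (``"EEG"`` or
``"EOG"``).  On disk, recordings travel either as EDF (the field's standard
exchange container) or as a plain delimited matrix plus a small JSON sidecar
carrying the sampling rate, labels and roles.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "EEGRecording",
    "SegmentedEEG",
    "read_recording",
    "read_edf",
    "write_edf",
    "read_delimited",
    "write_delimited",
    "assign_roles",
]

VALID_ROLES = ("EEG", "EOG")


class DataError(ValueError):
    """Raised for unreadable or inconsistent input data."""


@dataclass
class EEGRecording:
    """A block of co-registered EEG and EOG channels.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` float array, microvolts.
    fs
        Sampling rate in Hz.
    channel_labels
        Unique channel names, one per row of ``data``.
    channel_roles
        ``"EEG"`` or ``"EOG"`` per channel.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    channel_roles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise DataError("data must be a 2-D channels x samples matrix")
        if not np.all(np.isfinite(self.data)):
            raise DataError("recording contains NaN or Inf samples")
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_roles:
            self.channel_roles = ["EEG"] * self.data.shape[0]
        if len(self.channel_labels) != self.data.shape[0]:
            raise DataError("one label required per channel")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise DataError("channel labels must be unique")
        if len(self.channel_roles) != self.data.shape[0]:
            raise DataError("one role required per channel")
        for r in self.channel_roles:
            if r not in VALID_ROLES:
                raise DataError(f"unknown channel role {r!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def eeg_indices(self) -> np.ndarray:
        return np.flatnonzero([r == "EEG" for r in self.channel_roles])

    @property
    def eog_indices(self) -> np.ndarray:
        return np.flatnonzero([r == "EOG" for r in self.channel_roles])

    @property
    def eeg(self) -> np.ndarray:
        """EEG-role rows of ``data`` (view)."""
        return self.data[self.eeg_indices]

    @property
    def eog(self) -> np.ndarray:
        """EOG-role rows of ``data`` (view)."""
        return self.data[self.eog_indices]

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "EEGRecording":
        """Copy of the recording with new samples (labels/roles preserved)."""
        return replace(self, data=np.asarray(data, dtype=np.float64),
                       fs=self.fs if fs is None else fs)

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy(),
                       channel_labels=list(self.channel_labels),
                       channel_roles=list(self.channel_roles))


@dataclass
class SegmentedEEG:
    """Non-overlapping fixed-length windows cut from an :class:`EEGRecording`."""

    segments: np.ndarray          # (n_segments, n_channels, L)
    fs: float
    segment_times: np.ndarray     # start time of each window, seconds
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=np.float64)
        if self.segments.ndim != 3:
            raise DataError("segments must be (n_segments, n_channels, L)")

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def samples_per_segment(self) -> int:
        return self.segments.shape[2]


def assign_roles(labels: list[str], eog_pattern: str = r"(?i)EOG") -> list[str]:
    """Map channel labels to roles via a regex matched against each label."""
    pat = re.compile(eog_pattern)
    return ["EOG" if pat.search(lab) else "EEG" for lab in labels]


# ---------------------------------------------------------------------------
# Delimited matrix + JSON sidecar
# ---------------------------------------------------------------------------

def write_delimited(rec: EEGRecording, path: str | Path) -> Path:
    """Write samples as a TSV matrix (channels x samples) plus ``<path>.json``."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter="\t", fmt="%.6f")
    sidecar = {
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "channel_roles": rec.channel_roles,
        "units": "uV",
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_delimited(path: str | Path) -> EEGRecording:
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise DataError(
            f"delimited recording {path} needs a sidecar {sidecar_path.name} "
            "with fields: fs, channel_labels, channel_roles"
        )
    meta = json.loads(sidecar_path.read_text())
    for key in ("fs", "channel_labels"):
        if key not in meta:
            raise DataError(f"sidecar {sidecar_path} missing required field {key!r}")
    data = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    roles = meta.get("channel_roles") or assign_roles(meta["channel_labels"])
    return EEGRecording(data=data, fs=float(meta["fs"]),
                        channel_labels=list(meta["channel_labels"]),
                        channel_roles=list(roles))


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as a 16-bit EDF file.

    One data record per second; a trailing partial second is dropped.  Each
    channel gets its own physical scaling spanning its observed range, so the
    quantization error is at most (max-min)/65535 per channel.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise DataError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = rec.n_samples // fs
    if n_records < 1:
        raise DataError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_records * fs]
    ns = rec.n_channels

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((data - phys_min[:, None]) * gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    def f(value, width: int) -> bytes:
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8), f("X X X X", 80), f("Startdate X X X X", 80),
        f("01.01.00", 8), f("00.00.00", 8),
        f(256 * (1 + ns), 8), f("", 44), f(n_records, 8), f(1, 8), f(ns, 4),
    ])
    header += b"".join(f(lab, 16) for lab in rec.channel_labels)
    header += b"".join(f("", 80) for _ in range(ns))
    header += b"".join(f("uV", 8) for _ in range(ns))
    header += b"".join(f(f"{v:.6g}"[:8], 8) for v in phys_min)
    header += b"".join(f(f"{v:.6g}"[:8], 8) for v in phys_max)
    header += b"".join(f(dig_min, 8) for _ in range(ns))
    header += b"".join(f(dig_max, 8) for _ in range(ns))
    header += b"".join(f("", 80) for _ in range(ns))
    header += b"".join(f(fs, 8) for _ in range(ns))
    header += b"".join(f("", 32) for _ in range(ns))

    # phys min/max written with %.6g may round relative to the floats used for
    # scaling; re-derive the scaling from the written strings so a conforming
    # reader recovers the samples exactly up to 16-bit quantization.
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())
    return path


def read_edf(path: str | Path, eog_pattern: str = r"(?i)EOG") -> EEGRecording:
    """Read an EDF file (via MNE) into an :class:`EEGRecording` in microvolts."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE holds Volts internally
    labels = list(raw.ch_names)
    return EEGRecording(data=data, fs=float(raw.info["sfreq"]),
                        channel_labels=labels,
                        channel_roles=assign_roles(labels, eog_pattern))


def read_recording(path: str | Path, eog_pattern: str = r"(?i)EOG") -> EEGRecording:
    """Dispatch on extension: ``.edf`` via MNE, anything else as delimited."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path, eog_pattern)
    rec = read_delimited(path)
    if not rec.channel_roles or all(r == "EEG" for r in rec.channel_roles):
        rec.channel_roles = assign_roles(rec.channel_labels, eog_pattern)
    return rec
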