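"""Synthetic multichannel EEG with a planted two-state structure.

The generator emulates resting EEG that alternates between a
"conscious-like" state A and an "unconscious-like" state B:

* **State A** — broadband, weakly autocorrelated AR(1) noise with a
  narrowband beta oscillation (default ~20 Hz) that propagates across EEG
  channels with a fixed sample lag.  The lag gives the inter-channel
  cross-spectrum a nonzero imaginary part; the broadband noise keeps the
  Poincare ratio near 1 and the Lempel-Ziv complexity high.
* **State B** — a strong slow oscillation (default ~3.5 Hz) riding on
  strongly autocorrelated AR(1) noise, independent across channels: low beta
  power, low spectral edge, low complexity, low theta connectivity.

Blink-like EOG activity is modelled as a Poisson event train of raised-cosine
deflections added to the EOG channels and, through a per-channel mixing
vector, leaked into the EEG channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal

from .recording import EEGRecording, DataError

__all__ = ["StateParams", "SynthConfig", "StateLabels", "generate_session",
           "inject_eog", "write_labels", "read_labels"]


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass
class StateParams:
    """Generative parameters for one latent state."""

    osc_center_hz: float      # oscillation band center
    osc_bandwidth_hz: float   # full bandwidth of the narrowband source
    osc_amplitude: float      # RMS amplitude of the oscillation, uV
    ar_phi: float             # AR(1) coefficient of the background noise
    noise_sd: float           # innovation SD of the AR(1) noise, uV
    shared_oscillation: bool  # one lagged source across channels vs per-channel


def _default_states() -> dict[str, StateParams]:
    return {
        # beta oscillation propagated with a lag; near-white background
        "A": StateParams(osc_center_hz=20.0, osc_bandwidth_hz=4.0,
                         osc_amplitude=8.0, ar_phi=0.3, noise_sd=10.0,
                         shared_oscillation=True),
        # strong slow wave on heavily smoothed noise, independent channels
        "B": StateParams(osc_center_hz=3.5, osc_bandwidth_hz=1.5,
                         osc_amplitude=30.0, ar_phi=0.95, noise_sd=4.0,
                         shared_oscillation=False),
    }


@dataclass
class SynthConfig:
    """Full description of one synthetic session.

    The same config (including ``seed``) always yields bit-identical output.
    """

    n_eeg_channels: int = 6
    n_eog_channels: int = 2
    fs: float = 500.0
    block_states: list[str] = field(default_factory=lambda: ["A", "B"] * 4)
    state_duration: float = 30.0      # seconds per state block
    blink_rate: float = 6.0           # events per minute
    blink_amplitude: float = 80.0     # uV peak of a blink on the EOG channels
    mixing_vector: list[float] | None = None  # EOG->EEG leakage per channel
    coupling_lag: int = 6             # propagation lag in samples (state A)
    states: dict[str, StateParams] = field(default_factory=_default_states)
    eog_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eeg_channels < 2:
            raise ConfigError("need at least 2 EEG channels")
        if self.n_eog_channels < 1:
            raise ConfigError("need at least 1 EOG channel")
        if self.fs <= 0 or self.state_duration <= 0:
            raise ConfigError("fs and state_duration must be positive")
        if self.blink_rate < 0:
            raise ConfigError("blink_rate must be non-negative")
        for name, sp in self.states.items():
            if isinstance(sp, dict):
                self.states[name] = sp = StateParams(**sp)
            if abs(sp.ar_phi) >= 1:
                raise ConfigError(f"state {name}: |ar_phi| must be < 1")
        if self.mixing_vector is None:
            self.mixing_vector = [0.3, 0.2, 0.15, 0.1, 0.08,
                                  0.05][: self.n_eeg_channels]
            while len(self.mixing_vector) < self.n_eeg_channels:
                self.mixing_vector.append(0.05)
        if len(self.mixing_vector) != self.n_eeg_channels:
            raise ConfigError("mixing_vector length must equal n_eeg_channels")
        for st in self.block_states:
            if st not in self.states:
                raise ConfigError(f"unknown state label {st!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "SynthConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml
            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls(**payload)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StateLabels:
    """Ground-truth state per emitted 3-s segment (at the analysis rate)."""

    states: list[str]
    segment_s: float = 3.0

    def __len__(self) -> int:
        return len(self.states)


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    eps = rng.normal(0.0, sd, size=n)
    out = signal.lfilter([1.0], [1.0, -phi], eps)
    return out


def _narrowband(rng: np.random.Generator, n: int, fs: float, center: float,
                bandwidth: float) -> np.ndarray:
    """Unit-RMS narrowband Gaussian noise centered at ``center`` Hz."""
    lo = max(center - bandwidth / 2.0, 0.1)
    hi = min(center + bandwidth / 2.0, fs / 2.0 * 0.95)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    pad = int(2 * fs)  # let filter transients die out
    x = signal.sosfilt(sos, rng.standard_normal(n + pad))[pad:]
    rms = np.sqrt(np.mean(x**2))
    return x / max(rms, 1e-12)


def generate_session(config: SynthConfig) -> tuple[EEGRecording, StateLabels]:
    """Generate one synthetic session with blinks already injected.

    Returns the recording (EEG + EOG channels) and the per-3-s-segment ground
    truth labels.  Segmentation downstream is contiguous from t=0, so a block
    duration that is a multiple of 3 s keeps segments state-pure.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n_eeg = config.n_eeg_channels
    block_n = int(round(config.state_duration * fs))
    lag = int(config.coupling_lag)

    blocks = []
    for st in config.block_states:
        sp = config.states[st]
        block = np.empty((n_eeg, block_n))
        for ch in range(n_eeg):
            block[ch] = _ar1(rng, block_n, sp.ar_phi, sp.noise_sd)
        if sp.osc_amplitude > 0:
            if sp.shared_oscillation:
                src = _narrowband(rng, block_n + lag * n_eeg, fs,
                                  sp.osc_center_hz, sp.osc_bandwidth_hz)
                # channel ch sees the source delayed by ch*lag samples
                for ch in range(n_eeg):
                    off = lag * (n_eeg - 1 - ch)
                    block[ch] += sp.osc_amplitude * src[off: off + block_n]
            else:
                for ch in range(n_eeg):
                    osc = _narrowband(rng, block_n, fs, sp.osc_center_hz,
                                      sp.osc_bandwidth_hz)
                    block[ch] += sp.osc_amplitude * osc
        blocks.append(block)
    eeg = np.concatenate(blocks, axis=1)

    eog = np.empty((config.n_eog_channels, eeg.shape[1]))
    for ch in range(config.n_eog_channels):
        eog[ch] = _ar1(rng, eeg.shape[1], 0.9, config.eog_noise_sd)

    labels = [f"EEG{i+1}" for i in range(n_eeg)]
    labels += [f"EOG{i+1}" for i in range(config.n_eog_channels)]
    roles = ["EEG"] * n_eeg + ["EOG"] * config.n_eog_channels
    rec = EEGRecording(data=np.vstack([eeg, eog]), fs=fs,
                       channel_labels=labels, channel_roles=roles)
    rec = inject_eog(rec, config)

    seg_s = 3.0
    n_segments = int(rec.duration // seg_s)
    seg_states = []
    for i in range(n_segments):
        mid = (i + 0.5) * seg_s
        block_idx = min(int(mid // config.state_duration),
                        len(config.block_states) - 1)
        seg_states.append(config.block_states[block_idx])
    return rec, StateLabels(states=seg_states, segment_s=seg_s)


def blink_events(config: SynthConfig, duration_s: float) -> list[tuple[float, float, float]]:
    """Deterministic blink train for a session: (onset_s, width_s, peak_uV).

    Event times follow a homogeneous Poisson process at ``blink_rate`` per
    minute; widths are uniform on 0.3-1.0 s, peaks jitter +-20% around
    ``blink_amplitude``.  Driven by a dedicated stream derived from the
    config seed so that the event train does not depend on channel counts.
    """
    rng = np.random.default_rng([config.seed, 7919])
    rate_per_s = config.blink_rate / 60.0
    n_events = rng.poisson(rate_per_s * duration_s)
    onsets = np.sort(rng.uniform(0.0, duration_s, size=n_events))
    widths = rng.uniform(0.3, 1.0, size=n_events)
    peaks = config.blink_amplitude * rng.uniform(0.8, 1.2, size=n_events)
    return list(zip(onsets.tolist(), widths.tolist(), peaks.tolist()))


def inject_eog(rec: EEGRecording, config: SynthConfig) -> EEGRecording:
    """Add blink deflections to EOG channels and leak them into the EEG.

    Each blink is a raised-cosine bump.  EOG channels receive the bump at
    full amplitude; EEG channel *i* receives ``mixing_vector[i]`` times it.
    """
    if len(config.mixing_vector) != len(rec.eeg_indices):
        raise ConfigError("mixing_vector length must equal number of EEG channels")
    if config.blink_amplitude == 0 or config.blink_rate == 0:
        return rec
    out = rec.copy()
    fs = rec.fs
    n = rec.n_samples
    trace = np.zeros(n)
    for onset, width, peak in blink_events(config, rec.duration):
        i0 = int(round(onset * fs))
        w = max(int(round(width * fs)), 3)
        i1 = min(i0 + w, n)
        if i0 >= n:
            continue
        t = np.arange(i1 - i0)
        bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / (w - 1)))
        trace[i0:i1] += peak * bump
    for idx in out.eog_indices:
        out.data[idx] += trace
    for gain, idx in zip(config.mixing_vector, out.eeg_indices):
        out.data[idx] += gain * trace
    return out


def write_labels(labels: StateLabels, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("segment_index\tstate\n")
        for i, st in enumerate(labels.states):
            fh.write(f"{i}\t{st}\n")
    return path


def read_labels(path: str | Path) -> StateLabels:
    lines = Path(path).read_text().strip().splitlines()[1:]
    states = [ln.split("\t")[1] for ln in lines]
    if not states:
        raise DataError(f"no labels found in {path}")
    return StateLabels(states=states)
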