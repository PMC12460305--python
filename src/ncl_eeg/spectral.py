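"""Spectral features: Welch PSD, relative band power and normalized SEF95.

Relative power of a band [f1, f2] is the ratio of the PSD sum over that band
to the sum over the full analysis band [fl, fh] (default 0-45 Hz, the
low-pass passband).  SEF95 is the lowest frequency below which 95% of the
0-45 Hz power lies, reported as a fraction of 45 Hz so that it shares the
[0, 1] scale of the relative powers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["PSDEstimate", "welch_psd", "relative_power", "sef95",
           "THETA_BAND", "BETA_BAND", "FULL_BAND"]

THETA_BAND = (4.0, 8.0)
BETA_BAND = (12.0, 30.0)
FULL_BAND = (0.0, 45.0)


class DegenerateSignalError(ValueError):
    pass


@dataclass
class PSDEstimate:
    freqs: np.ndarray   # Hz, strictly increasing, spanning [0, fs/2]
    power: np.ndarray   # uV^2/Hz, >= 0
    df: float           # bin width

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("PSD must be non-negative")


def welch_psd(x: np.ndarray, fs: float, win_s: float = 1.0,
              overlap: float = 0.5) -> PSDEstimate:
    """Hamming-windowed averaged periodogram of a single channel.

    The 1-s default window gives 1 Hz resolution; with 50% overlap a 3-s
    segment at 200 Hz yields five averaged sub-windows.
    """
    x = np.asarray(x, dtype=np.float64)
    nperseg = int(round(win_s * fs))
    if x.size < nperseg:
        raise ValueError(f"segment of {x.size} samples shorter than one "
                         f"{win_s} s Welch window ({nperseg} samples)")
    freqs, power = signal.welch(x, fs=fs, window="hamming", nperseg=nperseg,
                                noverlap=int(nperseg * overlap),
                                detrend="constant", scaling="density")
    return PSDEstimate(freqs=freqs, power=power, df=float(freqs[1] - freqs[0]))


def relative_power(psd: PSDEstimate, f1: float, f2: float,
                   fl: float = 0.0, fh: float = 45.0) -> float:
    """Band power as a fraction of total power, inclusive band edges."""
    if not (fl <= f1 < f2 <= fh):
        raise ValueError(f"need fl <= f1 < f2 <= fh, got {(fl, f1, f2, fh)}")
    band = (psd.freqs >= f1) & (psd.freqs <= f2)
    total = (psd.freqs >= fl) & (psd.freqs <= fh)
    if not band.any():
        raise ValueError(f"no PSD bins inside [{f1}, {f2}] Hz")
    denom = psd.power[total].sum()
    if denom <= 0:
        raise DegenerateSignalError("zero total power in the analysis band")
    return float(psd.power[band].sum() / denom)


def sef95(psd: PSDEstimate, fh: float = 45.0, quantile: float = 0.95) -> float:
    """Spectral edge frequency as a fraction of ``fh``.

    Returns the smallest grid frequency F with cumulative power over [0, F]
    >= ``quantile`` of the power over [0, fh]; no interpolation.
    """
    mask = (psd.freqs >= 0) & (psd.freqs <= fh)
    p = psd.power[mask]
    f = psd.freqs[mask]
    total = p.sum()
    if total <= 0:
        raise DegenerateSignalError("zero power in the analysis band")
    cum = np.cumsum(p)
    idx = int(np.searchsorted(cum, quantile * total))
    idx = min(idx, len(f) - 1)
    return float(f[idx] / fh)
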