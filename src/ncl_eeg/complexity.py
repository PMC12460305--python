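"""Complexity features: Poincare ellipsoid radius ratio and Lempel-Ziv
complexity of the Hilbert-binarized signal.

The Poincare plot maps a signal onto (x_n, x_{n+tau}) pairs.  SD1 is the
spread perpendicular to the identity line (short-term variability), SD2 the
spread along it (long-term variability); their ratio ERR approaches 1 for
white noise and 0 for strongly predictable signals.  For an AR(1) process
with coefficient phi the ratio has the closed form sqrt((1-phi)/(1+phi)).

LZC counts the distinct phrases in the exhaustive Lempel-Ziv (1976) parsing
of a binary sequence obtained by thresholding the analytic-signal envelope
at its mean; the count is normalized by n/log2(n), the asymptotic phrase
count of an i.i.d. fair-coin sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["PoincareFeatures", "BinarySequence", "LZCFeature",
           "poincare_err", "binarize_hilbert", "lz76_complexity"]


class DegenerateSignalError(ValueError):
    pass


@dataclass
class PoincareFeatures:
    sd1: float
    sd2: float
    err: float          # sd1 / sd2
    tau: int
    clamped: bool = False   # SD2 radicand clamped at zero


@dataclass
class BinarySequence:
    bits: np.ndarray    # uint8 over {0, 1}
    threshold: float    # mean envelope used for binarization

    @property
    def n(self) -> int:
        return int(self.bits.size)


@dataclass
class LZCFeature:
    c_raw: int          # distinct phrases in the exhaustive parsing
    lzc: float          # c_raw * log2(n) / n


def poincare_err(x: np.ndarray, tau: int = 1) -> PoincareFeatures:
    """SD1/SD2 of the lag-``tau`` Poincare plot.

    SD uses the sample (n-1 denominator) standard deviation over the
    n - tau paired points.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size <= tau + 1:
        raise ValueError(f"need more than tau+1={tau + 1} samples")
    a = x[:-tau]
    b = x[tau:]
    sd_diff = np.std(a - b, ddof=1)
    sd_x = np.std(a, ddof=1)
    sd1 = (np.sqrt(2.0) / 2.0) * sd_diff
    radicand = 2.0 * sd_x**2 - 0.5 * sd_diff**2
    clamped = radicand < 0
    sd2 = np.sqrt(max(radicand, 0.0))
    if sd2 == 0:
        raise DegenerateSignalError("SD2 = 0 (constant or degenerate signal)")
    return PoincareFeatures(sd1=float(sd1), sd2=float(sd2),
                            err=float(sd1 / sd2), tau=tau, clamped=bool(clamped))


def binarize_hilbert(x: np.ndarray) -> BinarySequence:
    """Binarize by thresholding the analytic-signal envelope at its mean."""
    x = np.asarray(x, dtype=np.float64)
    envelope = np.abs(signal.hilbert(x))
    thr = envelope.mean()
    if np.ptp(envelope) < 1e-15:
        raise DegenerateSignalError("constant envelope; cannot binarize")
    bits = (envelope > thr).astype(np.uint8)
    return BinarySequence(bits=bits, threshold=float(thr))


def lz76_complexity(s: BinarySequence | np.ndarray | str,
                    normalize: bool = True) -> LZCFeature:
    """Exhaustive-history Lempel-Ziv (1976) phrase count.

    The sequence is scanned left to right; each phrase is extended until it
    is no longer a substring of everything that precedes its final character,
    at which point a new phrase starts.  ``lzc`` is ``c_raw * log2(n) / n``.
    """
    if isinstance(s, BinarySequence):
        bits = s.bits
    elif isinstance(s, str):
        bits = np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")
    else:
        bits = np.asarray(s, dtype=np.uint8)
    n = bits.size
    if n == 0:
        raise ValueError("empty sequence")
    seq = bits.tobytes()
    if n == 1:
        return LZCFeature(c_raw=1, lzc=0.0 if normalize else 1.0)

    # Kaspar-Schuster scan: i marks the start of the current phrase, k its
    # current length, l the start of the candidate earlier occurrence.
    c = 1
    i, k, l = 0, 1, 1
    k_max = 1
    while True:
        if seq[i + k - 1] == seq[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    lzc = c * np.log2(n) / n if normalize else float(c)
    return LZCFeature(c_raw=int(c), lzc=float(lzc))
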