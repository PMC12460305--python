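"""Connectivity features: theta-band imaginary coherency and theta-band
weighted symbolic mutual information (wSMI), per channel pair.

Coherency C_xy(f) = S_xy / sqrt(S_xx * S_yy) is estimated with Welch cross-
and auto-spectra; only the magnitude of its imaginary part is kept, which is
blind to zero-lag (volume-conducted) coupling.  wSMI maps each channel onto
a stream of ordinal patterns of k=3 samples spaced tau apart, then computes
a mutual information over the joint symbol histogram in which pairs of
identical and of sign-opposed (time-reversed amplitude) patterns carry zero
weight — again discounting common-source coupling.  The temporal spacing tau
is tied to the highest frequency the patterns should resolve through
f_max = fs / (k * tau).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import signal

__all__ = ["SymbolSequence", "ConnectivityMatrix", "icoh_band", "icoh_theta",
           "symbolize", "theta_tau", "wsmi", "pair_matrix",
           "lower_triangle_mean"]

K_DEFAULT = 3
_PATTERNS = list(permutations(range(K_DEFAULT)))            # 6 ordinal patterns
_PATTERN_INDEX = {p: i for i, p in enumerate(_PATTERNS)}
# sign flip of the signal reverses all pairwise orderings: rank r -> k-1-r
_OPPOSED = np.array([_PATTERN_INDEX[tuple(K_DEFAULT - 1 - r for r in p)]
                     for p in _PATTERNS])


@dataclass
class SymbolSequence:
    """Ordinal-pattern encoding of one channel."""

    symbols: np.ndarray   # ints in [0, k!)
    k: int
    tau_samples: int
    fs: float

    def __len__(self) -> int:
        return int(self.symbols.size)


@dataclass
class ConnectivityMatrix:
    values: np.ndarray    # (n_channels, n_channels), diagonal NaN
    measure: str


def icoh_band(x: np.ndarray, y: np.ndarray, fs: float,
              band: tuple[float, float] = (4.0, 8.0), win_s: float = 1.0,
              overlap: float = 0.5) -> float:
    """Mean |Im C_xy(f)| over the band, Welch-estimated.

    Requires at least two Welch sub-windows; with a single periodogram the
    coherency magnitude is identically 1 and the estimate meaningless.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("channels must have equal length")
    nperseg = int(round(win_s * fs))
    noverlap = int(nperseg * overlap)
    if x.size < 2 * nperseg - noverlap:
        raise ValueError("need at least two Welch sub-windows for coherency")
    kw = dict(fs=fs, window="hamming", nperseg=nperseg, noverlap=noverlap,
              detrend="constant")
    f, sxy = signal.csd(x, y, **kw)
    _, sxx = signal.welch(x, **kw)
    _, syy = signal.welch(y, **kw)
    denom = np.sqrt(sxx * syy)
    mask = (f >= band[0]) & (f <= band[1])
    if np.any(denom[mask] <= 0):
        raise ValueError("zero auto-spectrum inside the analysis band")
    coherency = sxy[mask] / denom[mask]
    return float(np.mean(np.abs(coherency.imag)))


def icoh_theta(x: np.ndarray, y: np.ndarray, fs: float, **kw) -> float:
    return icoh_band(x, y, fs, band=(4.0, 8.0), **kw)


def theta_tau(fs: float, k: int = K_DEFAULT, f_upper: float = 8.0) -> int:
    """Symbol spacing (samples) resolving frequencies up to ``f_upper``.

    Inverts f_max = fs / (k * tau): tau = round(fs / (k * f_upper)).
    """
    if fs <= 0 or f_upper <= 0:
        raise ValueError("fs and f_upper must be positive")
    tau = int(round(fs / (k * f_upper)))
    if tau < 1:
        raise ValueError(f"fs={fs} too low to resolve {f_upper} Hz with k={k}")
    return tau


def symbolize(x: np.ndarray, k: int = K_DEFAULT, tau_samples: int = 1,
              fs: float = float("nan")) -> SymbolSequence:
    """Encode each (x_t, x_{t+tau}, ..., x_{t+(k-1)tau}) as its ordinal pattern.

    Ties are broken by order of occurrence (stable sort), so the earlier
    sample ranks lower.
    """
    if tau_samples <= 0:
        raise ValueError("tau must be a positive number of samples")
    x = np.asarray(x, float)
    n_sym = x.size - (k - 1) * tau_samples
    if n_sym < 1:
        raise ValueError("signal too short for one ordinal pattern")
    idx = np.arange(n_sym)[:, None] + tau_samples * np.arange(k)[None, :]
    windows = x[idx]                                  # (n_sym, k)
    ranks = np.argsort(np.argsort(windows, axis=1, kind="stable"), axis=1)
    weights = np.array([math.factorial(k - 1 - j) for j in range(k)])
    # Lehmer-style code: count of smaller ranks to the right, base factorial
    codes = np.zeros(n_sym, dtype=np.int64)
    for j in range(k):
        smaller_after = np.sum(ranks[:, j + 1:] < ranks[:, j:j + 1], axis=1)
        codes += smaller_after * weights[j]
    return SymbolSequence(symbols=codes, k=k, tau_samples=tau_samples, fs=fs)


def wsmi(sx: SymbolSequence, sy: SymbolSequence, k: int = K_DEFAULT) -> float:
    """Weighted symbolic mutual information between two symbol streams.

    Natural-log mutual information over the empirical joint symbol
    distribution, normalized by ln(k!).  Weight 0 is assigned to identical
    and to sign-opposed pattern pairs, 1 otherwise; the result can be
    slightly negative on finite samples.
    """
    if len(sx) != len(sy):
        raise ValueError("symbol sequences must have equal length")
    if sx.k != k or sy.k != k:
        raise ValueError("symbol sequences must use the requested k")
    if k != K_DEFAULT:
        raise NotImplementedError("weight table implemented for k = 3")
    n = len(sx)
    if n < 30:
        warnings.warn(f"only {n} aligned symbols; wSMI estimate is unstable")
    n_sym = math.factorial(k)
    joint = np.zeros((n_sym, n_sym))
    np.add.at(joint, (sx.symbols, sy.symbols), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)

    w = np.ones((n_sym, n_sym))
    w[np.arange(n_sym), np.arange(n_sym)] = 0.0
    w[np.arange(n_sym), _OPPOSED] = 0.0

    mask = joint > 0
    outer = px[:, None] * py[None, :]
    terms = np.zeros_like(joint)
    terms[mask] = joint[mask] * np.log(joint[mask] / outer[mask])
    return float(np.sum(w * terms) / math.log(n_sym))


def pair_matrix(segment: np.ndarray, fs: float, measure: str = "icoh_theta",
                tau_samples: int | None = None, k: int = K_DEFAULT,
                band: tuple[float, float] = (4.0, 8.0)) -> ConnectivityMatrix:
    """Fill the connectivity matrix for all unordered channel pairs.

    ``segment`` is (n_channels, L).  The strict lower triangle is computed
    and mirrored; the diagonal is left NaN.
    """
    segment = np.asarray(segment, float)
    n_ch = segment.shape[0]
    if n_ch < 2:
        raise ValueError("need at least 2 channels for connectivity")
    values = np.full((n_ch, n_ch), np.nan)
    if measure == "wsmi_theta":
        if tau_samples is None:
            tau_samples = theta_tau(fs, k=k, f_upper=band[1])
        seqs = [symbolize(segment[c], k=k, tau_samples=tau_samples, fs=fs)
                for c in range(n_ch)]
    for i in range(1, n_ch):
        for j in range(i):
            if measure == "icoh_theta":
                v = icoh_band(segment[i], segment[j], fs, band=band)
            elif measure == "wsmi_theta":
                v = wsmi(seqs[i], seqs[j], k=k)
            else:
                raise ValueError(f"unknown measure {measure!r}")
            values[i, j] = values[j, i] = v
    return ConnectivityMatrix(values=values, measure=measure)


def lower_triangle_mean(m: ConnectivityMatrix | np.ndarray) -> float:
    """Mean of the strict lower triangle of a connectivity matrix."""
    values = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("matrix has no off-diagonal entries")
    idx = np.tril_indices(n, k=-1)
    return float(values[idx].mean())
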