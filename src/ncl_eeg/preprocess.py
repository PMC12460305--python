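"""Preprocessing: CCA-based EOG artifact reduction, resampling to the
analysis rate, low-pass filtering and fixed-length segmentation.

The pipeline order is fixed: artifact removal on the raw recording, then
polyphase resampling to 200 Hz (with its own anti-alias filter), then a
zero-phase third-order Butterworth low-pass at 45 Hz, then contiguous
non-overlapping 3-s windows.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from scipy import linalg, signal

from .recording import EEGRecording, SegmentedEEG, DataError

__all__ = ["remove_eog_cca", "resample_to", "lowpass_filter", "segment",
           "preprocess_session"]


class ArtifactRemovalError(ValueError):
    pass


class SegmentationError(ValueError):
    pass


def _canonical_basis(x: np.ndarray, y: np.ndarray, ridge: float = 1e-10):
    """Canonical correlation of two centered sample blocks.

    Parameters are ``(n_samples, d)`` arrays.  Returns ``(corrs, a, a_inv)``
    where the columns of ``a`` (d_x x d_x) map the centered x block onto
    unit-variance canonical variates ``z = xc @ a``, ordered by decreasing
    canonical correlation (only the first ``min(d_x, d_y)`` entries of
    ``corrs`` can be nonzero), and ``a_inv`` maps back: ``xc = z @ a_inv``.
    """
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    cxx = xc.T @ xc / (n - 1)
    cyy = yc.T @ yc / (n - 1)
    cxy = xc.T @ yc / (n - 1)
    # absolute floor keeps the whitening defined even for an all-zero block
    eps_x = ridge * np.trace(cxx) / cxx.shape[0] + 1e-15
    eps_y = ridge * np.trace(cyy) / cyy.shape[0] + 1e-15
    cxx += eps_x * np.eye(cxx.shape[0])
    cyy += eps_y * np.eye(cyy.shape[0])

    cxx_isqrt = linalg.inv(linalg.sqrtm(cxx).real)
    cyy_isqrt = linalg.inv(linalg.sqrtm(cyy).real)
    m = cxx_isqrt @ cxy @ cyy_isqrt
    u, s, _ = linalg.svd(m, full_matrices=True)
    corrs = np.zeros(cxx.shape[0])
    corrs[: len(s)] = np.clip(s, 0.0, 1.0)
    a = cxx_isqrt @ u
    a_inv = u.T @ linalg.sqrtm(cxx).real
    return corrs, a, a_inv


def remove_eog_cca(rec: EEGRecording, corr_threshold: float = 0.5) -> EEGRecording:
    """Project EOG-correlated canonical components out of the EEG block.

    Canonical variate pairs are computed between the multichannel EEG block
    and the multichannel EOG block of the whole recording.  EEG-side
    components whose canonical correlation is >= ``corr_threshold`` are
    zeroed and the EEG reconstructed from the rest; at most as many
    components as there are EOG channels can be removed.  EOG channels pass
    through unchanged.
    """
    if not 0.0 <= corr_threshold <= 1.0:
        raise ArtifactRemovalError("corr_threshold must lie in [0, 1]")
    eog_idx = rec.eog_indices
    if len(eog_idx) == 0:
        raise ArtifactRemovalError("recording has no EOG channels")
    eeg_idx = rec.eeg_indices
    x = rec.data[eeg_idx].T   # (n_samples, n_eeg)
    y = rec.data[eog_idx].T
    if x.shape[0] <= x.shape[1] + y.shape[1]:
        raise ArtifactRemovalError("fewer samples than channels")

    cond = np.linalg.cond(np.cov(x, rowvar=False))
    if cond > 1e10:
        warnings.warn("rank-deficient EEG covariance; ridge regularization applied")
    corrs, a, a_inv = _canonical_basis(x, y)

    keep = np.ones(len(corrs), dtype=bool)
    # the >= boundary is inclusive; tolerance absorbs the ridge perturbation
    removable = np.flatnonzero(corrs >= corr_threshold - 1e-9)
    # cap at the number of EOG channels, dropping the most correlated first
    removable = removable[np.argsort(corrs[removable])[::-1][: len(eog_idx)]]
    keep[removable] = False

    mean = x.mean(axis=0)
    z = (x - mean) @ a
    z[:, ~keep] = 0.0
    x_clean = z @ a_inv + mean

    out = rec.copy()
    out.data[eeg_idx] = x_clean.T
    return out


def resample_to(rec: EEGRecording, target_fs: float = 200.0) -> EEGRecording:
    """Rational-factor polyphase resampling with anti-alias filtering."""
    if rec.fs < target_fs:
        raise DataError(f"refusing to upsample ({rec.fs} Hz -> {target_fs} Hz)")
    if rec.fs == target_fs:
        return rec.copy()
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.with_data(data, fs=target_fs)


def lowpass_filter(rec: EEGRecording, f_hi: float = 45.0, order: int = 3) -> EEGRecording:
    """Zero-phase (forward-backward) Butterworth low-pass."""
    if f_hi >= rec.fs / 2:
        raise DataError(f"cutoff {f_hi} Hz must be below Nyquist ({rec.fs / 2} Hz)")
    sos = signal.butter(order, f_hi, btype="lowpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.with_data(data)


def segment(rec: EEGRecording, window_s: float = 3.0) -> SegmentedEEG:
    """Cut the EEG channels into contiguous non-overlapping windows.

    A trailing partial window is discarded.  Only EEG-role channels are kept;
    the artifact channels have served their purpose by this stage.
    """
    L = int(round(window_s * rec.fs))
    eeg = rec.eeg
    n_seg = eeg.shape[1] // L
    if n_seg < 1:
        raise SegmentationError(
            f"recording ({rec.duration:.2f} s) shorter than one {window_s} s window")
    segs = eeg[:, : n_seg * L].reshape(eeg.shape[0], n_seg, L).transpose(1, 0, 2)
    times = np.arange(n_seg) * window_s
    labels = [rec.channel_labels[i] for i in rec.eeg_indices]
    return SegmentedEEG(segments=segs.copy(), fs=rec.fs, segment_times=times,
                        channel_labels=labels)


def preprocess_session(rec: EEGRecording, corr_threshold: float = 0.5,
                       target_fs: float = 200.0, f_hi: float = 45.0,
                       filter_order: int = 3, window_s: float = 3.0,
                       remove_artifacts: bool = True) -> SegmentedEEG:
    """Full preprocessing chain: CCA removal -> resample -> low-pass -> segment."""
    if remove_artifacts:
        rec = remove_eog_cca(rec, corr_threshold)
    rec = resample_to(rec, target_fs)
    rec = lowpass_filter(rec, f_hi, filter_order)
    return segment(rec, window_s)
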