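"""Per-segment feature extraction: the five univariate features for every
channel plus the two pair-averaged theta-band connectivity features."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import complexity, connectivity, spectral
from .recording import SegmentedEEG

__all__ = ["UNIVARIATE_FEATURES", "CONNECTIVITY_FEATURES", "FEATURE_ORDER",
           "channel_features", "connectivity_means", "extract_features"]

log = logging.getLogger(__name__)

UNIVARIATE_FEATURES = ["rp_theta", "rp_beta", "sef95", "err", "lzc"]
CONNECTIVITY_FEATURES = ["icoh_theta", "wsmi_theta"]
FEATURE_ORDER = UNIVARIATE_FEATURES + CONNECTIVITY_FEATURES


def channel_features(seg: SegmentedEEG, welch_win_s: float = 1.0,
                     welch_overlap: float = 0.5, poincare_tau: int = 1,
                     fh: float = 45.0) -> pd.DataFrame:
    """One row per (segment, channel) with the five univariate features.

    Failed (degenerate) feature computations leave NaN in that cell; row
    filtering happens at assembly time.
    """
    rows = []
    for s in range(seg.n_segments):
        for c, label in enumerate(seg.channel_labels):
            x = seg.segments[s, c]
            row = {"segment": s, "channel": label}
            try:
                psd = spectral.welch_psd(x, seg.fs, win_s=welch_win_s,
                                         overlap=welch_overlap)
                row["rp_theta"] = spectral.relative_power(psd, *spectral.THETA_BAND,
                                                          fh=fh)
                row["rp_beta"] = spectral.relative_power(psd, *spectral.BETA_BAND,
                                                         fh=fh)
                row["sef95"] = spectral.sef95(psd, fh=fh)
            except ValueError:
                log.warning("segment %d channel %s: degenerate spectrum", s, label)
                row.update(rp_theta=np.nan, rp_beta=np.nan, sef95=np.nan)
            try:
                row["err"] = complexity.poincare_err(x, tau=poincare_tau).err
            except ValueError:
                row["err"] = np.nan
            try:
                bits = complexity.binarize_hilbert(x)
                row["lzc"] = complexity.lz76_complexity(bits).lzc
            except ValueError:
                row["lzc"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def connectivity_means(seg: SegmentedEEG, band: tuple[float, float] = (4.0, 8.0),
                       tau_samples: int | None = None) -> pd.DataFrame:
    """One row per segment: lower-triangle means of theta iCOH and wSMI."""
    if tau_samples is None:
        tau_samples = connectivity.theta_tau(seg.fs, f_upper=band[1])
    rows = []
    for s in range(seg.n_segments):
        seg_data = seg.segments[s]
        row = {"segment": s}
        for measure, col in (("icoh_theta", "icoh_theta"),
                             ("wsmi_theta", "wsmi_theta")):
            try:
                m = connectivity.pair_matrix(seg_data, seg.fs, measure=measure,
                                             tau_samples=tau_samples, band=band)
                row[col] = connectivity.lower_triangle_mean(m)
            except ValueError:
                log.warning("segment %d: degenerate %s", s, measure)
                row[col] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def extract_features(seg: SegmentedEEG, **kw) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper returning (per-channel table, connectivity table)."""
    conn_kw = {k: kw.pop(k) for k in ("band", "tau_samples") if k in kw}
    return channel_features(seg, **kw), connectivity_means(seg, **conn_kw)
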