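"""Evaluation: fuzzy-partition validity indices, threshold-based proxy
consciousness scores, and Spearman rank correlations.

With no behavioural ground truth available for consciousness, the clustering
is judged on two axes: internal validity of the fuzzy partition (partition
coefficient and partition entropy) and agreement of the NCL with a proxy
score built from literature thresholds on five of the seven features.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ncl_core import FeatureMatrix, MembershipMatrix, NCLSeries

__all__ = ["ProxyThresholds", "ProxyScores", "ValidityReport",
           "partition_coefficient", "partition_entropy", "proxy_scores",
           "spearman", "session_report"]


@dataclass
class ProxyThresholds:
    """Literature lower bounds for feature values indicative of consciousness.

    The spectral edge threshold is stated in Hz (8 Hz) but the sef95 feature
    is normalized by 45 Hz, so the comparison uses 8/45.  Relative beta power
    and the Poincare ratio have no published reference values and do not
    participate.
    """

    rp_theta_min: float = 0.07
    sef95_min_hz: float = 8.0
    sef95_norm_hz: float = 45.0
    lzc_min: float = 0.4
    icoh_min: float = 0.14
    wsmi_min: float = 0.088

    def as_dict(self) -> dict[str, float]:
        return {
            "rp_theta": self.rp_theta_min,
            "sef95": self.sef95_min_hz / self.sef95_norm_hz,
            "lzc": self.lzc_min,
            "icoh_theta": self.icoh_min,
            "wsmi_theta": self.wsmi_min,
        }


@dataclass
class ProxyScores:
    binary_matrix: np.ndarray   # (n, 5) of {0, 1}
    score: np.ndarray           # row means in [0, 1]
    features: list[str] = field(default_factory=list)


@dataclass
class ValidityReport:
    pc: dict[str, float]
    pe: dict[str, float]
    correlations: pd.DataFrame
    n: int


def partition_coefficient(U: MembershipMatrix | np.ndarray) -> float:
    """PC(U) = (1/n) sum_k sum_i u_ik^2; in [1/c, 1], 1 means crisp."""
    u = U.U if isinstance(U, MembershipMatrix) else np.asarray(U, float)
    if u.size == 0:
        raise ValueError("empty membership matrix")
    return float((u ** 2).sum() / u.shape[0])


def partition_entropy(U: MembershipMatrix | np.ndarray,
                      log_base: float | None = None) -> float:
    """PE(U) = -(1/n) sum_k sum_i u_ik log(u_ik), with 0 log 0 = 0.

    The default base is the cluster count c, which pins the range to [0, 1];
    pass ``log_base=math.e`` for the natural-log variant.
    """
    u = U.U if isinstance(U, MembershipMatrix) else np.asarray(U, float)
    if u.size == 0:
        raise ValueError("empty membership matrix")
    base = log_base if log_base is not None else u.shape[1]
    pos = u > 0
    terms = np.zeros_like(u)
    terms[pos] = u[pos] * np.log(u[pos]) / math.log(base)
    val = -terms.sum() / u.shape[0]
    return float(val) if val != 0 else 0.0


def proxy_scores(fm: FeatureMatrix | pd.DataFrame,
                 thr: ProxyThresholds | None = None) -> ProxyScores:
    """Binary indicator per (segment, thresholded feature), strict >.

    The score is the row mean over the five indicators.
    """
    thr = thr or ProxyThresholds()
    if isinstance(fm, FeatureMatrix):
        df = pd.DataFrame(fm.values, columns=fm.columns)
    else:
        df = fm
    thresholds = thr.as_dict()
    missing = [c for c in thresholds if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing thresholded columns {missing}")
    cols = list(thresholds)
    binary = np.column_stack([(df[c].to_numpy() > thresholds[c]).astype(int)
                              for c in cols])
    return ProxyScores(binary_matrix=binary, score=binary.mean(axis=1),
                       features=cols)


def _exact_spearman_p(rho: float, rx: np.ndarray, ry: np.ndarray) -> float:
    """Two-sided exact permutation p-value via full enumeration (n <= 10)."""
    n = len(rx)
    perms = np.array(list(_iter_permutations(range(n))))
    ry_perm = ry[perms]                        # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum(axis=1))
    rhos = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation.

    The p-value uses the t approximation for n > 10 and exact permutation
    enumeration for n <= 10.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length series of at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    rho, p = stats.spearmanr(x, y)
    if x.size <= 10:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        p = _exact_spearman_p(rho, rx, ry)
    return float(rho), float(p)


def session_report(fm: FeatureMatrix, ncl: NCLSeries,
                   u_fcm: MembershipMatrix, u_gmm: MembershipMatrix,
                   proxy: ProxyScores | None = None,
                   external_accuracy: np.ndarray | None = None) -> ValidityReport:
    """Validity indices plus the correlation table for one session.

    Correlations: NCL vs proxy score, each feature vs NCL, and (when a
    performance-accuracy series aligned to the segments is supplied) NCL vs
    accuracy.
    """
    if proxy is None:
        proxy = proxy_scores(fm)
    n = fm.n
    if len(ncl.ncl) != n or u_fcm.U.shape[0] != n or u_gmm.U.shape[0] != n:
        raise ValueError("feature matrix, NCL and memberships must align")
    if external_accuracy is not None and len(external_accuracy) != n:
        raise ValueError("external accuracy series does not align with segments")

    rows = []

    def _corr(name: str, a: np.ndarray, b: np.ndarray) -> None:
        try:
            rho, p = spearman(a, b)
        except ValueError:
            rho, p = float("nan"), float("nan")
        rows.append({"pair": name, "rho": rho, "p": p})

    _corr("ncl_vs_proxy", ncl.ncl, proxy.score)
    for j, col in enumerate(fm.columns):
        _corr(f"{col}_vs_ncl", fm.original_units(fm.values)[:, j], ncl.ncl)
    if external_accuracy is not None:
        _corr("ncl_vs_accuracy", ncl.ncl, np.asarray(external_accuracy, float))

    report = ValidityReport(
        pc={"fcm": partition_coefficient(u_fcm),
            "gmm": partition_coefficient(u_gmm)},
        pe={"fcm": partition_entropy(u_fcm),
            "gmm": partition_entropy(u_gmm)},
        correlations=pd.DataFrame(rows),
        n=n,
    )
    return report


def write_report(report: ValidityReport, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.correlations.to_csv(out_dir / "correlations.tsv", sep="\t", index=False)
    payload = {"n": report.n, "pc": report.pc, "pe": report.pe,
               "correlations": report.correlations.to_dict(orient="records")}
    (out_dir / "report.json").write_text(json.dumps(payload, indent=1))
    return out_dir
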