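"""Soft clustering and the normalized consciousness level (NCL).

The per-session feature matrix (n segments x 7 features) is clustered twice:
by fuzzy c-means (FCM) and by a Gaussian mixture model (GMM), each with two
clusters.  Both produce an n x 2 membership matrix whose rows sum to 1.  In
each partition the "conscious" cluster is identified by a majority vote over
the seven features — all of them are expected to be larger in conscious-like
segments — and the NCL of segment i is the product of its two conscious-
cluster memberships, a value in [0, 1] that is high only when both methods
agree.

FCM minimizes J_m = sum_i sum_j u_ij^m ||x_i - c_j||^2 by alternating the
center update c_j = sum_i u_ij^m x_i / sum_i u_ij^m with the membership
update u_ij = 1 / sum_k (d_ij/d_ik)^(2/(m-1)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import calinski_harabasz_score
from sklearn.mixture import GaussianMixture

from .features import FEATURE_ORDER, UNIVARIATE_FEATURES, CONNECTIVITY_FEATURES

__all__ = ["FCMParams", "GMMParams", "FeatureMatrix", "MembershipMatrix",
           "NCLSeries", "assemble_features", "standardize", "fcm_fit",
           "fcm_memberships", "gmm_fit", "label_conscious", "product_ensemble",
           "choose_k_chi"]

log = logging.getLogger(__name__)


class DegenerateClusteringError(ValueError):
    pass


@dataclass
class FCMParams:
    n_clusters: int = 2
    m: float = 2.0            # fuzzifier; m -> 1 recovers hard k-means
    max_iter: int = 1000
    epsilon: float = 1e-5     # minimum objective improvement
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")


@dataclass
class GMMParams:
    n_components: int = 2
    max_iter: int = 1000
    tol: float = 1e-5
    reg_covar: float = 1e-6
    n_init: int = 5
    seed: int = 0


@dataclass
class FeatureMatrix:
    """n segments x 7 named features, plus scaling metadata."""

    values: np.ndarray
    columns: list[str] = field(default_factory=lambda: list(FEATURE_ORDER))
    segment_index: np.ndarray | None = None
    scale_mean: np.ndarray | None = None   # set by standardize()
    scale_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.segment_index is None:
            self.segment_index = np.arange(self.values.shape[0])

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "segment", self.segment_index)
        return df

    def original_units(self, points: np.ndarray) -> np.ndarray:
        """Map standardized coordinates back to feature units."""
        if self.scale_mean is None:
            return np.asarray(points)
        return np.asarray(points) * self.scale_sd + self.scale_mean


@dataclass
class MembershipMatrix:
    U: np.ndarray             # (n, n_clusters), entries in [0, 1]
    source: str               # "fcm" | "gmm" | "ensemble-product"

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=np.float64)
        if np.any(self.U < -1e-12) or np.any(self.U > 1 + 1e-12):
            raise ValueError("memberships must lie in [0, 1]")
        if self.source in ("fcm", "gmm"):
            sums = self.U.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"{self.source} membership rows must sum to 1")


@dataclass
class NCLSeries:
    ncl: np.ndarray
    conscious_index: dict[str, int]     # per method
    segment_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ncl = np.asarray(self.ncl, dtype=np.float64)
        if np.any(self.ncl < -1e-12) or np.any(self.ncl > 1 + 1e-12):
            raise ValueError("NCL must lie in [0, 1]")


def assemble_features(per_channel: pd.DataFrame,
                      conn_means: pd.DataFrame) -> FeatureMatrix:
    """Average the univariate features over channels and join the
    connectivity means; drop (and log) segments with any failed feature."""
    for col in UNIVARIATE_FEATURES:
        if col not in per_channel.columns:
            raise ValueError(f"per-channel table missing feature {col!r}")
    for col in CONNECTIVITY_FEATURES:
        if col not in conn_means.columns:
            raise ValueError(f"connectivity table missing feature {col!r}")
    # NaN must propagate: a failed channel invalidates the segment mean
    uni = per_channel.groupby("segment")[UNIVARIATE_FEATURES].agg(
        lambda s: s.to_numpy().mean())
    conn = conn_means.set_index("segment")[CONNECTIVITY_FEATURES]
    merged = uni.join(conn, how="inner")[FEATURE_ORDER]
    bad = merged.index[merged.isna().any(axis=1)]
    if len(bad):
        log.warning("dropping %d segment(s) with failed features: %s",
                    len(bad), list(bad))
        merged = merged.drop(index=bad)
    return FeatureMatrix(values=merged.to_numpy(),
                         segment_index=merged.index.to_numpy())


def standardize(fm: FeatureMatrix) -> FeatureMatrix:
    """Z-score each feature column, keeping the inverse transform.

    Constant columns cannot be scaled and are dropped with a warning.
    """
    if fm.n < 2:
        raise ValueError("need at least 2 rows to standardize")
    mean = fm.values.mean(axis=0)
    sd = fm.values.std(axis=0, ddof=1)
    keep = sd > 1e-10 * (np.abs(mean) + 1.0)   # constant up to rounding
    if not keep.all():
        dropped = [c for c, k in zip(fm.columns, keep) if not k]
        warnings.warn(f"dropping constant feature column(s): {dropped}")
    values = (fm.values[:, keep] - mean[keep]) / sd[keep]
    return FeatureMatrix(values=values,
                         columns=[c for c, k in zip(fm.columns, keep) if k],
                         segment_index=fm.segment_index.copy(),
                         scale_mean=mean[keep], scale_sd=sd[keep])


def fcm_memberships(x: np.ndarray, centers: np.ndarray, m: float = 2.0) -> np.ndarray:
    """Membership update: u_ij = 1 / sum_k (d_ij/d_ik)^(2/(m-1)).

    A point at zero distance from a center gets membership 1 there and 0
    elsewhere.
    """
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    zero = d2 < 1e-300
    u = np.empty_like(d2)
    power = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** -power
        u = inv / inv.sum(axis=1, keepdims=True)
    # a point sitting on a center belongs there crisply
    rows = zero.any(axis=1)
    if rows.any():
        u[rows] = 0.0
        u[rows, np.argmax(zero[rows], axis=1)] = 1.0
    return u


def fcm_fit(fm: FeatureMatrix | np.ndarray, params: FCMParams | None = None
            ) -> tuple[np.ndarray, MembershipMatrix, list[float]]:
    """Fuzzy c-means from a seeded random membership initialization.

    Returns (centers, memberships, objective trace).  Iteration stops when
    the objective improves by less than ``epsilon`` or after ``max_iter``
    rounds.
    """
    params = params or FCMParams()
    x = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, float)
    n = x.shape[0]
    if n <= params.n_clusters:
        raise DegenerateClusteringError("need more points than clusters")
    if np.allclose(x, x[0]):
        raise DegenerateClusteringError("all data points identical")
    rng = np.random.default_rng(params.seed)
    u = rng.random((n, params.n_clusters))
    u /= u.sum(axis=1, keepdims=True)

    trace: list[float] = []
    for _ in range(params.max_iter):
        um = u ** params.m
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        obj = float((um * d2).sum())
        u = fcm_memberships(x, centers, params.m)
        trace.append(obj)
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) < params.epsilon:
            break
    # make the returned centers an exact Eq.-9 fixed point of the returned U
    um = u ** params.m
    centers = (um.T @ x) / um.sum(axis=0)[:, None]
    return centers, MembershipMatrix(U=u, source="fcm"), trace


def gmm_fit(fm: FeatureMatrix | np.ndarray, params: GMMParams | None = None
            ) -> tuple[GaussianMixture, MembershipMatrix, list[float]]:
    """Full-covariance Gaussian mixture via EM (sklearn backend).

    Returns (model, posterior memberships, per-iteration mean log-likelihood
    trace of the best initialization rerun to convergence).
    """
    params = params or GMMParams()
    x = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, float)
    model = GaussianMixture(n_components=params.n_components,
                            covariance_type="full", tol=params.tol,
                            max_iter=params.max_iter, reg_covar=params.reg_covar,
                            n_init=params.n_init, random_state=params.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x)
    if not model.converged_:
        warnings.warn("GMM EM did not converge within max_iter")

    # rerun EM from the fitted solution one step at a time to expose the
    # monotone log-likelihood trace
    trace_model = GaussianMixture(n_components=params.n_components,
                                  covariance_type="full", tol=params.tol,
                                  max_iter=1, reg_covar=params.reg_covar,
                                  warm_start=True, random_state=params.seed)
    trace_model.weights_init = model.weights_
    trace_model.means_init = model.means_
    trace_model.precisions_init = model.precisions_
    trace: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(25):
            trace_model.fit(x)
            trace.append(float(trace_model.lower_bound_))
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < params.tol:
                break
        u = model.predict_proba(x)
    return model, MembershipMatrix(U=u, source="gmm"), trace


def label_conscious(centers_original_units: np.ndarray,
                    columns: list[str] | None = None) -> int:
    """Pick the conscious cluster by majority vote over the seven features.

    Every feature is expected to be larger in the conscious-like state, so
    each feature votes for the cluster with the larger centroid coordinate.
    With an odd number of voting features a tie requires exact centroid
    equality; it is broken in favour of the cluster with the larger spectral
    edge (sef95).
    """
    centers = np.asarray(centers_original_units, dtype=np.float64)
    if centers.shape[0] != 2:
        raise ValueError("conscious labeling is defined for exactly 2 clusters")
    columns = list(columns) if columns is not None else list(FEATURE_ORDER)
    if np.allclose(centers[0], centers[1]):
        raise DegenerateClusteringError("identical centroids; clusters indistinct")
    votes = np.array([0, 0])
    for j in range(centers.shape[1]):
        if centers[0, j] > centers[1, j]:
            votes[0] += 1
        elif centers[1, j] > centers[0, j]:
            votes[1] += 1
    if votes[0] == votes[1]:
        j = columns.index("sef95") if "sef95" in columns else 0
        return int(np.argmax(centers[:, j]))
    return int(np.argmax(votes))


def product_ensemble(u_fcm: MembershipMatrix, u_gmm: MembershipMatrix,
                     idx_fcm: int, idx_gmm: int,
                     segment_times: np.ndarray | None = None) -> NCLSeries:
    """NCL_i = U_fcm[i, conscious] * U_gmm[i, conscious] (no renormalization)."""
    if u_fcm.U.shape[0] != u_gmm.U.shape[0]:
        raise ValueError("membership matrices have different lengths")
    ncl = u_fcm.U[:, idx_fcm] * u_gmm.U[:, idx_gmm]
    return NCLSeries(ncl=ncl, conscious_index={"fcm": idx_fcm, "gmm": idx_gmm},
                     segment_times=segment_times)


def choose_k_chi(fm: FeatureMatrix | np.ndarray, k_range=range(2, 7),
                 fcm_params: FCMParams | None = None,
                 gmm_params: GMMParams | None = None
                 ) -> tuple[dict[str, int], pd.DataFrame]:
    """Calinski-Harabasz scan over cluster counts for both methods.

    Memberships are hardened by arg-max before computing the index; the
    returned dict gives the CHI-maximizing k per method.
    """
    x = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, float)
    fcm_params = fcm_params or FCMParams()
    gmm_params = gmm_params or GMMParams()
    rows = []
    for k in k_range:
        if x.shape[0] <= k:
            break
        entry = {"k": k, "chi_fcm": np.nan, "chi_gmm": np.nan}
        fp = FCMParams(n_clusters=k, m=fcm_params.m, max_iter=fcm_params.max_iter,
                       epsilon=fcm_params.epsilon, seed=fcm_params.seed)
        _, u, _ = fcm_fit(x, fp)
        hard = u.U.argmax(axis=1)
        if len(np.unique(hard)) == k:
            entry["chi_fcm"] = calinski_harabasz_score(x, hard)
        else:
            log.warning("FCM k=%d produced an empty hardened cluster", k)
        gp = GMMParams(n_components=k, max_iter=gmm_params.max_iter,
                       tol=gmm_params.tol, reg_covar=gmm_params.reg_covar,
                       n_init=gmm_params.n_init, seed=gmm_params.seed)
        _, u, _ = gmm_fit(x, gp)
        hard = u.U.argmax(axis=1)
        if len(np.unique(hard)) == k:
            entry["chi_gmm"] = calinski_harabasz_score(x, hard)
        else:
            log.warning("GMM k=%d produced an empty hardened cluster", k)
        rows.append(entry)
    table = pd.DataFrame(rows)
    best = {}
    for method in ("fcm", "gmm"):
        col = table[f"chi_{method}"]
        if col.notna().any():
            best[method] = int(table.loc[col.idxmax(), "k"])
    return best, table
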