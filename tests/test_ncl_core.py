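"""Feature assembly, FCM/GMM soft clustering, conscious labeling and the
product ensemble."""

import numpy as np
import pandas as pd
import pytest

from ncl_eeg.ncl_core import (DegenerateClusteringError, FCMParams,
                              FeatureMatrix, GMMParams, MembershipMatrix,
                              assemble_features, choose_k_chi, fcm_fit,
                              fcm_memberships, gmm_fit, label_conscious,
                              product_ensemble, standardize)
from ncl_eeg.features import FEATURE_ORDER, UNIVARIATE_FEATURES


def _blobs(rng, n_per=100, sep=10.0, dim=2):
    a = rng.standard_normal((n_per, dim))
    b = rng.standard_normal((n_per, dim)) + sep
    x = np.vstack([a, b])
    labels = np.array([0] * n_per + [1] * n_per)
    return x, labels


def _toy_tables(n_segments=4, channels=("C1", "C2", "C3")):
    rng = np.random.default_rng(3)
    rows = []
    for s in range(n_segments):
        for c in channels:
            row = {"segment": s, "channel": c}
            row.update({f: rng.random() for f in UNIVARIATE_FEATURES})
            rows.append(row)
    per_channel = pd.DataFrame(rows)
    conn = pd.DataFrame({"segment": range(n_segments),
                         "icoh_theta": rng.random(n_segments),
                         "wsmi_theta": rng.random(n_segments)})
    return per_channel, conn


class TestAssemble:
    def test_two_channel_mean(self):
        per_channel, conn = _toy_tables(n_segments=1, channels=("C1", "C2"))
        per_channel.loc[0, "rp_beta"] = 0.1
        per_channel.loc[1, "rp_beta"] = 0.3
        fm = assemble_features(per_channel, conn)
        assert fm.values[0, fm.columns.index("rp_beta")] == pytest.approx(0.2)

    def test_single_channel_passthrough(self):
        per_channel, conn = _toy_tables(n_segments=2, channels=("C1",))
        fm = assemble_features(per_channel, conn)
        for f in UNIVARIATE_FEATURES:
            np.testing.assert_allclose(
                fm.values[:, fm.columns.index(f)],
                per_channel.sort_values("segment")[f].to_numpy())

    def test_matches_loop_oracle(self):
        per_channel, conn = _toy_tables()
        fm = assemble_features(per_channel, conn)
        assert fm.columns == FEATURE_ORDER
        for s in range(4):
            expected = []
            for f in UNIVARIATE_FEATURES:
                vals = [per_channel.loc[(per_channel.segment == s)
                                        & (per_channel.channel == c), f].item()
                        for c in ("C1", "C2", "C3")]
                expected.append(np.mean(vals))
            expected.append(conn.loc[conn.segment == s, "icoh_theta"].item())
            expected.append(conn.loc[conn.segment == s, "wsmi_theta"].item())
            np.testing.assert_allclose(fm.values[s], expected)

    def test_nan_row_dropped(self):
        per_channel, conn = _toy_tables()
        per_channel.loc[0, "lzc"] = np.nan
        fm = assemble_features(per_channel, conn)
        assert fm.n == 3
        assert 0 not in fm.segment_index


class TestStandardize:
    def test_zscores_columns(self, rng):
        fm = FeatureMatrix(values=rng.random((50, 7)) * [1, 10, 100, 1, 1, 1, 1])
        out = standardize(fm)
        np.testing.assert_allclose(out.values.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_idempotent_on_standardized(self, rng):
        x = rng.standard_normal((40, 3))
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        out = standardize(FeatureMatrix(values=x, columns=["a", "b", "c"]))
        np.testing.assert_allclose(out.values, x, atol=1e-12)

    def test_constant_column_dropped(self, rng):
        x = rng.standard_normal((30, 3))
        x[:, 1] = 4.2
        with pytest.warns(UserWarning):
            out = standardize(FeatureMatrix(values=x, columns=["a", "b", "c"]))
        assert out.columns == ["a", "c"]

    def test_inverse_transform_recovers_units(self, rng):
        x = rng.random((20, 2)) * 100
        out = standardize(FeatureMatrix(values=x, columns=["a", "b"]))
        np.testing.assert_allclose(out.original_units(out.values), x)


class TestFCM:
    def test_separated_blobs_recovered(self, rng):
        x, labels = _blobs(rng)
        centers, u, trace = fcm_fit(x, FCMParams(seed=0))
        hard = u.U.argmax(axis=1)
        # map clusters to blobs by majority
        maps = hard[labels == 0].mean() < 0.5
        acc = np.mean((hard == (0 if maps else 1)) == (labels == 0))
        confident = (u.U.max(axis=1) > 0.9).mean()
        assert acc >= 0.99 or acc <= 0.01  # label permutation allowed
        assert confident >= 0.99
        assert trace[-1] <= trace[0]

    def test_centers_are_fixed_point(self, rng):
        x, _ = _blobs(rng, n_per=50)
        centers, u, _ = fcm_fit(x, FCMParams(seed=1))
        um = u.U ** 2
        expected = (um.T @ x) / um.sum(axis=0)[:, None]
        assert np.abs(centers - expected).max() < 1e-6

    def test_midpoint_membership_half(self):
        centers = np.array([[0.0, 0.0], [4.0, 0.0]])
        u = fcm_memberships(np.array([[2.0, 0.0]]), centers, m=2.0)
        np.testing.assert_allclose(u[0], [0.5, 0.5])

    def test_point_on_center_is_crisp(self):
        centers = np.array([[0.0, 0.0], [4.0, 0.0]])
        u = fcm_memberships(np.array([[4.0, 0.0]]), centers, m=2.0)
        np.testing.assert_array_equal(u[0], [0.0, 1.0])

    def test_rows_sum_to_one(self, rng):
        x = rng.standard_normal((60, 4))
        _, u, _ = fcm_fit(x, FCMParams(seed=2))
        np.testing.assert_allclose(u.U.sum(axis=1), 1.0, atol=1e-9)

    def test_identical_points_rejected(self):
        with pytest.raises(DegenerateClusteringError):
            fcm_fit(np.ones((10, 3)), FCMParams())

    def test_seeded_determinism(self, rng):
        x = rng.standard_normal((60, 4))
        _, u1, _ = fcm_fit(x, FCMParams(seed=5))
        _, u2, _ = fcm_fit(x, FCMParams(seed=5))
        np.testing.assert_array_equal(u1.U, u2.U)


class TestGMM:
    def test_means_recovered_on_blobs(self, rng):
        x, _ = _blobs(rng, n_per=150, sep=8.0)
        model, u, _ = gmm_fit(x, GMMParams(seed=0))
        means = model.means_[np.argsort(model.means_[:, 0])]
        np.testing.assert_allclose(means[0], [0, 0], atol=0.2)
        np.testing.assert_allclose(means[1], [8, 8], atol=0.2)
        np.testing.assert_allclose(u.U.sum(axis=1), 1.0, atol=1e-9)

    def test_single_component_memberships_one(self, rng):
        x = rng.standard_normal((50, 3))
        _, u, _ = gmm_fit(x, GMMParams(n_components=1, seed=0))
        np.testing.assert_allclose(u.U, 1.0)

    def test_loglik_trace_monotone(self, rng):
        x, _ = _blobs(rng, n_per=80, sep=3.0)
        _, _, trace = gmm_fit(x, GMMParams(seed=3))
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-8)


class TestLabelConscious:
    def test_unanimous(self):
        centers = np.array([[1.0] * 7, [0.0] * 7])
        assert label_conscious(centers) == 0

    def test_majority_four_to_three(self):
        # cluster 0 higher on rp_beta, sef95, lzc, icoh; cluster 1 on the rest
        c0 = np.array([0.1, 0.9, 0.9, 0.2, 0.9, 0.9, 0.1])
        c1 = np.array([0.5, 0.1, 0.3, 0.8, 0.2, 0.3, 0.6])
        assert label_conscious(np.vstack([c0, c1])) == 0

    def test_matches_bruteforce_vote(self, rng):
        for _ in range(50):
            centers = rng.random((2, 7))
            votes0 = sum(centers[0, j] > centers[1, j] for j in range(7))
            votes1 = sum(centers[1, j] > centers[0, j] for j in range(7))
            expected = 0 if votes0 > votes1 else 1
            assert label_conscious(centers) == expected

    def test_identical_centroids_rejected(self):
        with pytest.raises(DegenerateClusteringError):
            label_conscious(np.ones((2, 7)))


class TestProductEnsemble:
    @pytest.mark.parametrize("uf,ug,expected", [
        (0.9, 0.8, 0.72),
        (0.0, 0.7, 0.0),
        (1.0, 1.0, 1.0),
    ])
    def test_products(self, uf, ug, expected):
        u_fcm = MembershipMatrix(U=np.array([[uf, 1 - uf]]), source="fcm")
        u_gmm = MembershipMatrix(U=np.array([[ug, 1 - ug]]), source="gmm")
        ncl = product_ensemble(u_fcm, u_gmm, 0, 0)
        assert ncl.ncl[0] == pytest.approx(expected)

    def test_ncl_bounded_by_min_membership(self, rng):
        uf = rng.random((30, 1))
        u_fcm = MembershipMatrix(U=np.hstack([uf, 1 - uf]), source="fcm")
        ug = rng.random((30, 1))
        u_gmm = MembershipMatrix(U=np.hstack([ug, 1 - ug]), source="gmm")
        ncl = product_ensemble(u_fcm, u_gmm, 0, 0)
        assert np.all(ncl.ncl <= np.minimum(uf[:, 0], ug[:, 0]) + 1e-12)

    def test_cluster_permutation_invariance(self, rng):
        uf = rng.random((20, 1))
        U1 = np.hstack([uf, 1 - uf])
        u_gmm = MembershipMatrix(U=rng.dirichlet([1, 1], 20), source="gmm")
        a = product_ensemble(MembershipMatrix(U1, "fcm"), u_gmm, 0, 1)
        b = product_ensemble(MembershipMatrix(U1[:, ::-1], "fcm"), u_gmm, 1, 1)
        np.testing.assert_allclose(a.ncl, b.ncl)

    def test_length_mismatch_rejected(self, rng):
        u1 = MembershipMatrix(U=rng.dirichlet([1, 1], 5), source="fcm")
        u2 = MembershipMatrix(U=rng.dirichlet([1, 1], 6), source="gmm")
        with pytest.raises(ValueError):
            product_ensemble(u1, u2, 0, 0)


class TestChooseK:
    def test_two_blobs_select_k2(self, rng):
        x, _ = _blobs(rng, n_per=60, sep=10.0)
        best, table = choose_k_chi(x, k_range=range(2, 6))
        assert best["fcm"] == 2
        assert best["gmm"] == 2

    def test_chi_matches_hand_computation(self):
        """6 points in two tight 1-D blobs: BGSS/WGSS worked by hand."""
        x = np.array([[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]])
        best, table = choose_k_chi(x, k_range=[2])
        # blob means 0.1 and 10.1, grand mean 5.1: BGSS = 150, WGSS = 0.04
        expected = (150.0 / 1) / (0.04 / 4)
        assert table.loc[0, "chi_fcm"] == pytest.approx(expected, rel=1e-6)
        assert table.loc[0, "chi_gmm"] == pytest.approx(expected, rel=1e-6)

    def test_single_blob_does_not_crash(self, rng):
        x = rng.standard_normal((60, 2))
        best, table = choose_k_chi(x, k_range=range(2, 5))
        assert len(table) == 3
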