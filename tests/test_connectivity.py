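"""Imaginary coherency, ordinal symbolization and wSMI."""

import math
from itertools import permutations

import numpy as np
import pytest

from ncl_eeg.connectivity import (ConnectivityMatrix, icoh_theta, icoh_band,
                                  lower_triangle_mean, pair_matrix, symbolize,
                                  theta_tau, wsmi, SymbolSequence)
from ncl_eeg.synthdata import StateParams, SynthConfig, generate_session
from ncl_eeg.preprocess import preprocess_session
from ncl_eeg.features import connectivity_means


def _sym(values, k=3, tau=1):
    return SymbolSequence(symbols=np.asarray(values), k=k, tau_samples=tau,
                          fs=200.0)


class TestICoh:
    def test_identical_channels_zero(self, rng):
        x = rng.standard_normal(600)
        assert icoh_theta(x, x, fs=200.0) < 1e-10

    def test_quarter_period_lag_maximal(self, rng):
        """6 Hz tone delayed by a quarter period: Im C = sin(90 deg) = 1."""
        fs = 200.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 6 * t) + 0.01 * rng.standard_normal(t.size)
        lag = int(round(fs / 6 / 4))
        y = np.roll(x, lag)
        assert icoh_theta(x[lag:], y[lag:], fs) >= 0.9

    def test_independent_noise_near_zero(self, rng):
        x = rng.standard_normal(20000)
        y = rng.standard_normal(20000)
        assert icoh_theta(x, y, fs=200.0) < 0.1

    def test_symmetry(self, rng):
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        assert icoh_theta(x, y, 200.0) == pytest.approx(icoh_theta(y, x, 200.0))

    def test_single_window_rejected(self, rng):
        with pytest.raises(ValueError):
            icoh_theta(rng.standard_normal(200), rng.standard_normal(200), 200.0)


class TestSymbolize:
    def test_monotone_ramps_give_constant_symbols(self):
        up = symbolize(np.arange(50, dtype=float), tau_samples=1)
        down = symbolize(-np.arange(50, dtype=float), tau_samples=1)
        assert len(set(up.symbols.tolist())) == 1
        assert len(set(down.symbols.tolist())) == 1
        assert up.symbols[0] != down.symbols[0]

    def test_matches_bruteforce_rank_enumeration(self):
        """Each triple maps to the lexicographic index of its rank pattern."""
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 7.0])
        got = symbolize(x, tau_samples=1).symbols
        patterns = sorted(permutations(range(3)))
        expected = []
        for t in range(4):
            triple = x[t: t + 3]
            order = sorted(range(3), key=lambda i: (triple[i], i))
            ranks = [0] * 3
            for r, i in enumerate(order):
                ranks[i] = r
            expected.append(patterns.index(tuple(ranks)))
        np.testing.assert_array_equal(got, expected)

    def test_tau_spacing_and_length(self):
        x = np.arange(20, dtype=float)
        s = symbolize(x, tau_samples=4)
        assert len(s) == 20 - 2 * 4

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            symbolize(np.arange(10.0), tau_samples=0)


class TestThetaTau:
    @pytest.mark.parametrize("fs,f_upper,expected", [
        (200.0, 8.0, 8),        # theta upper edge at the analysis rate
        (1000.0, 1000.0 / 96.0, 32),  # 32 ms spacing example
        (24.0, 8.0, 1),
    ])
    def test_values(self, fs, f_upper, expected):
        assert theta_tau(fs, f_upper=f_upper) == expected

    def test_too_low_fs_rejected(self):
        with pytest.raises(ValueError):
            theta_tau(10.0, f_upper=8.0)


class TestWsmi:
    def test_identical_streams_exactly_zero(self, rng):
        s = _sym(rng.integers(0, 6, 500))
        assert wsmi(s, s) == 0.0

    def test_independent_streams_near_zero(self, rng):
        sx = _sym(rng.integers(0, 6, 10_000))
        sy = _sym(rng.integers(0, 6, 10_000))
        assert abs(wsmi(sx, sy)) < 0.01

    def test_hand_computed_two_cell_joint(self):
        """Two perfectly coupled non-identical, non-opposed symbol pairs."""
        sx = _sym([0] * 5 + [1] * 5)
        sy = _sym([2] * 5 + [3] * 5)
        # p(0,2)=p(1,3)=0.5, marginals 0.5 -> MI = ln 2, weights 1
        expected = math.log(2) / math.log(6)
        with pytest.warns(UserWarning):  # short stream warning
            assert wsmi(sx, sy) == pytest.approx(expected)

    def test_opposed_patterns_carry_no_weight(self):
        # 0 <-> 5 are time-reversed patterns (ascending vs descending)
        sx = _sym([0] * 50)
        sy = _sym([5] * 50)
        assert wsmi(sx, sy) == 0.0

    def test_symmetry(self, rng):
        sx = _sym(rng.integers(0, 6, 2000))
        sy = _sym((sx.symbols + rng.integers(0, 3, 2000)) % 6)
        assert wsmi(sx, sy) == pytest.approx(wsmi(sy, sx))

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            wsmi(_sym([0, 1, 2]), _sym([0, 1]))


class TestPairMatrix:
    @pytest.mark.parametrize("n_ch,n_pairs", [(2, 1), (5, 10)])
    def test_pair_count(self, rng, n_ch, n_pairs):
        seg = rng.standard_normal((n_ch, 600))
        m = pair_matrix(seg, fs=200.0, measure="icoh_theta")
        idx = np.tril_indices(n_ch, k=-1)
        assert np.isfinite(m.values[idx]).sum() == n_pairs
        np.testing.assert_allclose(m.values, m.values.T, equal_nan=True)

    def test_duplicated_channels_give_zero_icoh(self, rng):
        x = rng.standard_normal(600)
        seg = np.tile(x, (3, 1))
        m = pair_matrix(seg, fs=200.0, measure="icoh_theta")
        assert np.nanmax(np.abs(m.values)) < 1e-10

    def test_single_channel_rejected(self, rng):
        with pytest.raises(ValueError):
            pair_matrix(rng.standard_normal((1, 600)), fs=200.0)


class TestLowerTriangleMean:
    def test_constant_matrix(self):
        m = ConnectivityMatrix(values=np.full((4, 4), 0.3), measure="icoh_theta")
        assert lower_triangle_mean(m) == pytest.approx(0.3)

    def test_three_by_three(self):
        v = np.full((3, 3), np.nan)
        v[1, 0], v[2, 0], v[2, 1] = 0.1, 0.2, 0.3
        assert lower_triangle_mean(ConnectivityMatrix(v, "x")) == pytest.approx(0.2)

    def test_matches_loop_oracle(self, rng):
        v = rng.random((5, 5))
        v = (v + v.T) / 2
        got = lower_triangle_mean(ConnectivityMatrix(v, "x"))
        expected = np.mean([v[i, j] for i in range(5) for j in range(i)])
        assert got == pytest.approx(expected)


def test_theta_propagation_raises_theta_connectivity():
    """Moving the lagged shared oscillation into the theta band makes both
    theta-connectivity features higher in state A than in state B."""
    states = {
        "A": StateParams(osc_center_hz=6.0, osc_bandwidth_hz=2.0,
                         osc_amplitude=12.0, ar_phi=0.3, noise_sd=8.0,
                         shared_oscillation=True),
        "B": StateParams(osc_center_hz=6.0, osc_bandwidth_hz=2.0,
                         osc_amplitude=12.0, ar_phi=0.3, noise_sd=8.0,
                         shared_oscillation=False),
    }
    cfg = SynthConfig(seed=29, block_states=["A", "B"], states=states,
                      blink_rate=0.0, coupling_lag=10)
    rec, labels = generate_session(cfg)
    seg = preprocess_session(rec, remove_artifacts=False)
    conn = connectivity_means(seg)
    st = np.array(labels.states[: len(conn)])
    for col in ("icoh_theta", "wsmi_theta"):
        vals = conn[col].to_numpy()
        assert vals[st == "A"].mean() > vals[st == "B"].mean()
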