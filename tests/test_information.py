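"""Information estimators: discretization, MI, lagged MI, surrogates, PID."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from volnet import (LagGrid, SurrogateConfig, discretize, entropy, lagged_mi,
                    mutual_information, mutual_information_continuous,
                    pid_decompose, pid_from_symbols, surrogate_test)


class TestDiscretize:
    def test_equal_occupancy_bins_from_cube_root_rule(self):
        rng = np.random.default_rng(0)
        sym = discretize(rng.normal(size=1000))
        counts = np.bincount(sym)
        assert len(counts) == 10  # floor(1000 ** (1/3))
        assert counts.min() >= 90 and counts.max() <= 110

    def test_constant_series_single_symbol_entropy_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            sym = discretize(np.full(100, 3.7))
        assert entropy(sym) == 0.0

    def test_monotone_transform_leaves_symbols_unchanged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        np.testing.assert_array_equal(discretize(x), discretize(np.exp(x)))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=10, max_size=200))
    def test_rank_invariance_property(self, values):
        # values rounded to 1e-3 so the affine map cannot create or break
        # ties through float rounding; invariance is about exact monotone maps
        x = np.round(np.asarray(values), 3)
        a = discretize(x)
        b = discretize(3.0 * x + 7.0)
        np.testing.assert_array_equal(a, b)


class TestMutualInformation:
    def test_identical_four_symbol_sequences_give_two_bits(self):
        x = np.tile([0, 1, 2, 3], 100)
        assert mutual_information(x, x) == pytest.approx(2.0)

    def test_exact_symmetry(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 7, 500)
        y = rng.integers(0, 3, 500)
        assert mutual_information(x, y) == mutual_information(y, x)

    def test_matches_reference_implementation(self):
        # independent plug-in oracle: sklearn's contingency-based estimator
        from sklearn.metrics import mutual_info_score
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, 800)
        y = (x + rng.integers(0, 3, 800)) % 5
        assert mutual_information(x, y) == pytest.approx(
            mutual_info_score(x, y) / np.log(2), abs=1e-12)

    def test_gaussian_closed_form_agreement_improves_with_n(self):
        rho = 0.6
        analytic = -0.5 * np.log2(1 - rho ** 2)
        errs = []
        for n in (1000, 10000, 50000):
            z = np.random.default_rng(123).multivariate_normal(
                [0, 0], [[1, rho], [rho, 1]], size=n)
            errs.append(abs(mutual_information_continuous(z[:, 0], z[:, 1])
                            - analytic))
        assert errs[2] < errs[1] < errs[0]

    def test_independent_sequences_consistent_with_permutation_null(self):
        # the plug-in estimate carries O(B^2 / n) bias, so compare against
        # the permutation-null scale instead of absolute zero
        rng = np.random.default_rng(4)
        x = discretize(rng.normal(size=10000))
        y = discretize(rng.normal(size=10000))
        est = mutual_information(x, y)
        null = np.mean([mutual_information(rng.permutation(x), y)
                        for _ in range(100)])
        assert abs(est - null) < 0.01
        assert est < 2 * null + 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mutual_information(np.zeros(5, int), np.zeros(6, int))


class TestLaggedMI:
    def test_default_grid_evaluates_twenty_lags(self, coupled_panel):
        res = lagged_mi(coupled_panel, coupled_panel.channels[0],
                        coupled_panel.channels[1], LagGrid(5, 100, 5))
        assert len(res.lags) == 20
        assert res.lags[0] == 5.0 and res.lags[-1] == 100.0

    def test_injected_lag_recovered(self, coupled_panel):
        res = lagged_mi(coupled_panel, coupled_panel.channels[1],
                        coupled_panel.channels[3], LagGrid(5, 100, 5))
        assert res.best_lag == 10.0  # 2 steps at 5 min

    def test_independent_channels_not_significant(self, flat_panel):
        res = lagged_mi(flat_panel, 31.018, 33.033, LagGrid(5, 50, 5),
                        surr=SurrogateConfig(n_shuffles=200, seed=5))
        assert res.p_value > 0.05

    def test_insufficient_overlap_names_the_lag(self, flat_panel):
        short = flat_panel.data.iloc[:35]
        from volnet import FluxPanel
        panel = FluxPanel(short.copy())
        with pytest.raises(ValueError, match="lag 30"):
            lagged_mi(panel, 31.018, 33.033, LagGrid(5, 50, 5))


class TestSurrogates:
    def test_observed_above_all_surrogates_gives_floor_p(self):
        x = np.arange(200.0)
        y = np.arange(200.0)

        def stat(a, b):  # maximized by the identity alignment
            return float(np.corrcoef(a, b)[0, 1])

        p = surrogate_test(stat, x, y, SurrogateConfig(n_shuffles=100, seed=0))
        assert p == pytest.approx(1 / 101)

    def test_default_shuffle_count(self):
        assert SurrogateConfig().n_shuffles == 2500

    def test_pvalues_uniform_under_independence(self):
        # Kolmogorov distance of the null p-value distribution
        from volnet.information import _mi_surrogate_pvalue
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(400):
            x = discretize(rng.normal(size=200))
            y = discretize(rng.normal(size=200))
            ps.append(_mi_surrogate_pvalue(x, y, 200, rng))
        ps = np.sort(ps)
        ks = np.max(np.abs(ps - np.arange(1, len(ps) + 1) / len(ps)))
        assert ks < 0.07


class TestPID:
    def test_xor_is_pure_synergy(self):
        x1 = np.tile([0, 0, 1, 1], 64)
        x2 = np.tile([0, 1, 0, 1], 64)
        parts = pid_from_symbols(x1, x2, x1 ^ x2)
        assert parts["unique1"] == parts["unique2"] == parts["redundant"] == 0.0
        assert parts["synergistic"] == pytest.approx(1.0)

    def test_duplicate_sources_are_pure_redundancy(self):
        y = np.tile([0, 1], 128)
        parts = pid_from_symbols(y, y, y)
        assert parts["redundant"] == pytest.approx(1.0)
        assert parts["unique1"] == parts["unique2"] == 0.0
        assert parts["synergistic"] == pytest.approx(0.0, abs=1e-12)

    def test_copy_with_independent_distractor_is_pure_uniqueness(self):
        # exhaustive product table: y = x1, x2 independent
        x1 = np.tile([0, 0, 1, 1], 64)
        x2 = np.tile([0, 1, 0, 1], 64)
        parts = pid_from_symbols(x1, x2, x1)
        assert parts["unique1"] == pytest.approx(1.0)  # = H(Y)
        assert parts["unique2"] == parts["redundant"] == 0.0
        assert parts["synergistic"] == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_identity_and_nonnegativity_on_random_triads(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(40, 200))
        b = int(rng.integers(2, 6))
        x1 = rng.integers(0, b, n)
        x2 = rng.integers(0, b, n)
        y = (x1 + x2 + rng.integers(0, b, n)) % b
        parts = pid_from_symbols(x1, x2, y)
        total = (parts["unique1"] + parts["unique2"] + parts["redundant"]
                 + parts["synergistic"])
        assert total == pytest.approx(parts["i_total"], abs=1e-9)
        assert min(parts["unique1"], parts["unique2"], parts["redundant"],
                   parts["synergistic"]) >= 0.0

    def test_redundancy_modes_bracket_the_rescaled_value(self):
        rng = np.random.default_rng(6)
        x1 = rng.integers(0, 3, 300)
        x2 = (x1 + rng.integers(0, 2, 300)) % 3
        y = (x1 + x2) % 3
        r_min = pid_from_symbols(x1, x2, y, redundancy="minimum")["redundant"]
        r_mmi = pid_from_symbols(x1, x2, y, redundancy="mmi")["redundant"]
        r = pid_from_symbols(x1, x2, y)["redundant"]
        assert r_min <= r <= r_mmi

    def test_zero_entropy_source_warns_and_zeroes_unique(self):
        y = np.tile([0, 1], 64)
        with pytest.warns(UserWarning, match="zero-entropy"):
            parts = pid_from_symbols(np.zeros(128, int), y, y)
        assert parts["unique1"] == 0.0

    def test_panel_level_decomposition_aligns_lags(self, coupled_panel):
        chans = coupled_panel.channels
        res = pid_decompose(coupled_panel, (chans[1], 10.0), (chans[0], 5.0),
                            chans[3])
        total = res.unique1 + res.unique2 + res.redundant + res.synergistic
        assert total == pytest.approx(res.i_total, abs=1e-9)
        assert res.unique1 > res.unique2  # channel 1 is the true driver
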