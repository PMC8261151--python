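"""Preprocessing chain: normalization, gap filling, background, smoothing."""

import numpy as np
import pandas as pd
import pytest

from volnet import (IonCountMatrix, PanelFormatError, PreprocessConfig,
                    PreprocessLog, average_replicates, fill_gaps,
                    normalize_primary_ion, ordination_overview,
                    smooth_and_aggregate, subtract_background)
from volnet.panel import FluxPanel


def _mat(values, channels, t=None, chamber="jar"):
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values)) * 60.0 if t is None else np.asarray(t, float)
    return IonCountMatrix(pd.DataFrame(values, index=t, columns=channels),
                          chamber_id=chamber)


class TestNormalize:
    def test_count_equal_to_reference_gives_the_constant(self):
        mat = _mat([[1000.0, 1000.0]], [33.033, 21.0])
        out = normalize_primary_ion(mat)
        assert out.data.iloc[0, 0] == 500.0
        assert 21.0 not in out.channels  # reference dropped

    def test_zero_count_normalizes_to_zero(self):
        out = normalize_primary_ion(_mat([[0.0, 800.0]], [33.033, 21.0]))
        assert out.data.iloc[0, 0] == 0.0

    def test_linearity_in_the_raw_count(self):
        a = normalize_primary_ion(_mat([[250.0, 1000.0]], [33.033, 21.0]))
        b = normalize_primary_ion(_mat([[500.0, 1000.0]], [33.033, 21.0]))
        assert b.data.iloc[0, 0] == 2 * a.data.iloc[0, 0]

    def test_missing_reference_channel_is_an_error(self):
        with pytest.raises(PanelFormatError, match="reference"):
            normalize_primary_ion(_mat([[1.0]], [33.033]))

    def test_zero_reference_at_observed_time_reports_timestamp(self):
        mat = _mat([[1.0, 1000.0], [1.0, 0.0]], [33.033, 21.0])
        with pytest.raises(PanelFormatError, match="t=60"):
            normalize_primary_ion(mat)


class TestFillGaps:
    def test_linear_midpoint(self):
        mat = _mat([[2.0], [np.nan], [4.0]], [33.033])
        out = fill_gaps(mat)
        assert out.data.iloc[1, 0] == 3.0

    def test_50min_gap_at_5min_resolution_fills_as_even_ramp(self):
        # 10 missing points between values a and b, per the rotation gaps
        t = np.arange(12) * 300.0  # 5-min steps, seconds
        v = np.full(12, np.nan)
        v[0], v[11] = 10.0, 32.0
        out = fill_gaps(_mat(v[:, None], [33.033], t=t),
                        PreprocessConfig(max_gap_minutes=50.0))
        np.testing.assert_allclose(out.data.iloc[:, 0].to_numpy(),
                                   np.linspace(10.0, 32.0, 12))

    def test_runs_longer_than_max_gap_stay_missing(self):
        t = np.arange(13) * 300.0
        v = np.full(13, np.nan)
        v[0], v[12] = 10.0, 32.0  # 11 missing > 10-step limit
        out = fill_gaps(_mat(v[:, None], [33.033], t=t),
                        PreprocessConfig(max_gap_minutes=50.0))
        assert np.isnan(out.data.iloc[1:12, 0]).all()

    def test_leading_block_stays_missing_and_is_logged(self):
        log = PreprocessLog()
        out = fill_gaps(_mat([[np.nan], [np.nan], [5.0]], [33.033]), log=log)
        assert np.isnan(out.data.iloc[0, 0]) and np.isnan(out.data.iloc[1, 0])
        assert log.cells_unfilled == 2


class TestSubtract:
    def test_entrywise_difference(self):
        out = subtract_background(_mat([[10.0]], [33.033]),
                                  _mat([[4.0]], [33.033], chamber="blank"))
        assert out.data.iloc[0, 0] == 6.0

    def test_negative_clipped_to_zero_and_counted(self):
        log = PreprocessLog()
        out = subtract_background(_mat([[3.0]], [33.033]),
                                  _mat([[5.0]], [33.033]), log=log)
        assert out.data.iloc[0, 0] == 0.0
        assert log.cells_clipped == 1

    def test_zero_blank_is_identity(self):
        out = subtract_background(_mat([[7.0, 9.0]], [33.033, 45.033]),
                                  _mat([[0.0, 0.0]], [33.033, 45.033]))
        np.testing.assert_array_equal(out.data.to_numpy(), [[7.0, 9.0]])

    def test_channel_mismatch_lists_channels(self):
        with pytest.raises(PanelFormatError, match="45.033"):
            subtract_background(_mat([[1.0]], [33.033]),
                                _mat([[1.0]], [45.033]))


class TestAverage:
    def test_pointwise_mean(self):
        out = average_replicates([_mat([[2.0]], [33.033]),
                                  _mat([[4.0]], [33.033])])
        assert out.data.iloc[0, 0] == 3.0

    def test_missing_cells_ignored_not_propagated(self):
        out = average_replicates([_mat([[np.nan]], [33.033]),
                                  _mat([[4.0]], [33.033]),
                                  _mat([[6.0]], [33.033])])
        assert out.data.iloc[0, 0] == 5.0

    def test_all_missing_stays_missing(self):
        out = average_replicates([_mat([[np.nan]], [33.033]),
                                  _mat([[np.nan]], [33.033])])
        assert np.isnan(out.data.iloc[0, 0])

    def test_single_replicate_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = average_replicates([_mat([[2.0]], [33.033])])
        assert out.data.iloc[0, 0] == 2.0


class TestSmoothAggregate:
    def test_constant_channel_unchanged(self):
        t = np.arange(60) * 60.0
        out = smooth_and_aggregate(_mat(np.full((60, 1), 7.0), [33.033], t=t))
        np.testing.assert_allclose(out.data.to_numpy(), 7.0)

    def test_white_noise_variance_strictly_reduced(self):
        rng = np.random.default_rng(11)
        t = np.arange(240) * 60.0
        v = rng.normal(10.0, 2.0, size=(240, 1))
        out = smooth_and_aggregate(_mat(v, [33.033], t=t))
        assert out.data.iloc[:, 0].var() < v.var()

    def test_60_one_minute_points_aggregate_to_12_windows(self):
        t = np.arange(60) * 60.0
        v = np.linspace(1.0, 5.0, 60)[:, None]
        out = smooth_and_aggregate(_mat(v, [33.033], t=t))
        assert out.n_times == 12
        assert out.step == 5.0

    def test_sparse_channel_dropped_with_warning(self):
        t = np.arange(60) * 60.0
        v = np.column_stack([np.linspace(1, 2, 60),
                             np.r_[np.ones(5), np.full(55, np.nan)]])
        log = PreprocessLog()
        with pytest.warns(UserWarning, match="dropped"):
            out = smooth_and_aggregate(_mat(v, [33.033, 45.033], t=t), log=log)
        assert out.channels == [33.033]
        assert log.channels_dropped == [45.033]


class TestOrdination:
    def test_two_correlated_channels_put_everything_on_pc1(self):
        t = np.arange(50) * 5.0
        base = np.sin(np.arange(50) / 5.0)
        df = pd.DataFrame({31.018: base, 33.033: 2 * base + 1}, index=t)
        res = ordination_overview(FluxPanel(df))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, flat_panel):
        res = ordination_overview(flat_panel)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_scores_carry_phase_labels(self, flat_panel):
        flat_panel.wetup_time = 750.0
        res = ordination_overview(flat_panel)
        assert set(res.scores["phase"]) == {"dry", "wet"}

    def test_constant_panel_is_an_error(self):
        df = pd.DataFrame(np.ones((30, 2)), index=np.arange(30) * 5.0,
                          columns=[31.018, 33.033])
        with pytest.raises(ValueError, match="variance"):
            ordination_overview(FluxPanel(df))
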