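"""Label binning, imputation, normalization, splits and truncation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ttdml import (Cohort, LongitudinalSeries, NormalizationStats,
                   PatientRecord, PreprocessConfig, StaticProfile,
                   categorize_ttd, default_vocabulary, impute_series,
                   prepare_cohort, temporal_split, truncate_history)
from ttdml.preprocessing import (DEFAULT_BIN_EDGES, EXTENDED_BIN_EDGES,
                                 prepare_patient)


@pytest.mark.parametrize("ttd,expected", [
    (7.15, 0),       # the typical (median-like) TTD falls in the first bin
    (29.999, 0),
    (30.0, 1),       # half-open bins: the boundary belongs to the upper bin
    (59.9, 1),
    (60.0, 2),
    (120.0, 3),
    (121.0, 3),
    (5000.0, 3),
])
def test_categorize_default_edges(ttd, expected):
    assert categorize_ttd(ttd, DEFAULT_BIN_EDGES) == expected


@pytest.mark.parametrize("ttd,expected", [(150.0, 3), (180.0, 4), (240.0, 5)])
def test_categorize_extended_edges(ttd, expected):
    assert categorize_ttd(ttd, EXTENDED_BIN_EDGES) == expected


def test_categorize_rejects_nonpositive():
    with pytest.raises(ValueError):
        categorize_ttd(0.0)
    with pytest.raises(ValueError):
        categorize_ttd(-5.0)


@given(st.floats(min_value=0.01, max_value=1e5))
@settings(max_examples=200, deadline=None)
def test_label_conservation(ttd):
    """Every positive TTD maps to exactly one valid category."""
    cat = categorize_ttd(ttd, DEFAULT_BIN_EDGES)
    assert 0 <= cat <= len(DEFAULT_BIN_EDGES)


def _single_channel_series(col, mask_col):
    vocab = default_vocabulary()
    k = vocab.n_longitudinal
    n = len(col)
    values = np.full((n, k), np.nan)
    mask = np.zeros((n, k))
    values[:, 0] = col
    mask[:, 0] = mask_col
    # give every row at least one observation so the series is valid raw input
    values[:, 1] = 1.0
    mask[:, 1] = 1.0
    return LongitudinalSeries(-np.arange(n, 0, -1, dtype=float), values, mask)


@pytest.fixture()
def stats_with_mean(small_split):
    return small_split["stats"]


def test_impute_forward_then_backward_fill(stats_with_mean):
    series = _single_channel_series([np.nan, 4.0, np.nan, 6.0], [0, 1, 0, 1])
    out = impute_series(series, stats_with_mean)
    np.testing.assert_allclose(out.values[:, 0], [4.0, 4.0, 4.0, 6.0])
    np.testing.assert_array_equal(out.mask, series.mask)


def test_impute_never_observed_uses_training_mean(stats_with_mean):
    series = _single_channel_series([np.nan, np.nan], [0, 0])
    out = impute_series(series, stats_with_mean)
    expected = stats_with_mean.channel_mean[0]
    np.testing.assert_allclose(out.values[:, 0], [expected, expected])


def test_impute_fully_observed_unchanged(stats_with_mean):
    series = _single_channel_series([2.0, 3.0, 4.0], [1, 1, 1])
    out = impute_series(series, stats_with_mean)
    np.testing.assert_allclose(out.values[:, 0], [2.0, 3.0, 4.0])


def test_impute_idempotent(stats_with_mean, small_cohort):
    cohort, _ = small_cohort
    series = cohort.records[0].series
    once = impute_series(series, stats_with_mean)
    twice = impute_series(once, stats_with_mean)
    # masks unchanged, so the second pass only re-fills the same entries
    obs = once.mask > 0
    np.testing.assert_allclose(twice.values[obs], once.values[obs])


def test_normalization_round_trip(small_split):
    stats = small_split["stats"]
    rng = np.random.default_rng(0)
    values = rng.normal(50, 10, size=(4, stats.vocabulary.n_longitudinal))
    back = stats.denormalize_values(stats.normalize_values(values))
    np.testing.assert_allclose(back, values)


def test_normalization_zscores_continuous_channels(small_split):
    stats = small_split["stats"]
    j = stats.vocabulary.longitudinal_index("pulse")
    values = np.zeros((2, stats.vocabulary.n_longitudinal))
    values[0, j] = stats.channel_mean[j]
    values[1, j] = stats.channel_mean[j] + stats.channel_sd[j]
    out = stats.normalize_values(values)
    assert out[0, j] == pytest.approx(0.0)
    assert out[1, j] == pytest.approx(1.0)


def test_binary_channels_untouched(small_split):
    stats = small_split["stats"]
    j = stats.vocabulary.longitudinal_index("corneal_reflex")
    values = np.zeros((1, stats.vocabulary.n_longitudinal))
    values[0, j] = 1.0
    assert stats.normalize_values(values)[0, j] == 1.0


def _cohort_with_years(years):
    vocab = default_vocabulary()
    k = vocab.n_longitudinal
    recs = []
    for i, year in enumerate(years):
        values = np.full((1, k), np.nan)
        mask = np.zeros((1, k))
        values[0, 0] = 1.0
        mask[0, 0] = 1.0
        recs.append(PatientRecord(
            f"p{i}", StaticProfile(np.array([70, 25, 0, 1, 80.0])),
            LongitudinalSeries(np.array([-10.0]), values, mask), 15.0, year))
    return Cohort(recs, vocab)


def test_temporal_split_threshold():
    train, test = temporal_split(_cohort_with_years([2018, 2020, 2022]), 2021)
    assert len(train) == 2 and len(test) == 1


def test_temporal_split_cutoff_year_goes_to_test():
    train, test = temporal_split(_cohort_with_years([2019, 2021]), 2021)
    assert [r.era_year for r in test] == [2021]


def test_temporal_split_empty_side_errors():
    with pytest.raises(ValueError, match="test"):
        temporal_split(_cohort_with_years([2018, 2019]), 2021)
    with pytest.raises(ValueError, match="train"):
        temporal_split(_cohort_with_years([2022, 2023]), 2021)


def test_truncate_history_threshold_filter():
    series = _single_channel_series([1.0, 2.0, 3.0], [1, 1, 1])
    series.times = np.array([-800.0, -700.0, -100.0])
    out, empty = truncate_history(series, 720.0)
    assert not empty
    # only observations at or before 12 h pre-extubation survive
    np.testing.assert_allclose(out.times, [-800.0])


def test_truncate_history_degenerate_flags_empty():
    series = _single_channel_series([1.0], [1])
    out, empty = truncate_history(series, 1e9)
    assert empty and out.n_observations == 0


def test_truncate_history_identity_when_horizon_outside_window():
    series = _single_channel_series([1.0, 2.0], [1, 1])
    series.times = np.array([-5000.0, -4000.0])
    out, empty = truncate_history(series, 720.0)
    assert not empty
    np.testing.assert_allclose(out.times, series.times)


def test_stats_do_not_leak_test_split(small_cohort):
    """Normalization and mean-fill statistics depend on the train side only."""
    cohort, _ = small_cohort
    train_c, test_c = temporal_split(cohort)
    stats = NormalizationStats.fit(train_c)
    # recompute from a cohort whose *test* side is grossly corrupted
    corrupted = []
    for rec in cohort:
        if rec.era_year >= 2021:
            series = LongitudinalSeries(rec.series.times,
                                        rec.series.values * 1e3,
                                        rec.series.mask)
            rec = PatientRecord(rec.patient_id, rec.static, series,
                                rec.ttd_minutes, rec.era_year)
        corrupted.append(rec)
    corrupted_train, _ = temporal_split(
        Cohort(corrupted, cohort.vocabulary))
    stats2 = NormalizationStats.fit(corrupted_train)
    np.testing.assert_allclose(stats2.channel_mean, stats.channel_mean)
    np.testing.assert_allclose(stats2.channel_sd, stats.channel_sd)


def test_prepare_patient_has_no_nans(small_split, small_cohort):
    cohort, _ = small_cohort
    prep = prepare_patient(cohort.records[0], small_split["stats"])
    assert np.all(np.isfinite(prep.values))
    assert np.all(np.isfinite(prep.statics))
    assert prep.delta_t[0] == 0.0
    assert np.all(prep.delta_t[1:] > 0)


def test_prepare_cohort_horizon_drops_flagged_patients(small_cohort):
    cohort, _ = small_cohort
    stats = NormalizationStats.fit(cohort)
    full = prepare_cohort(cohort, stats, PreprocessConfig())
    early = prepare_cohort(cohort, stats, PreprocessConfig(horizon_min=720.0))
    assert 0 < len(early) < len(full)
    for p in early:
        assert np.all(p.times <= -720.0)
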