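"""VI preprocessing chain: masking, filling, smoothing, derived operators."""

import numpy as np
import pandas as pd
import pytest

from phenoml.meteo_features import CutoffRule
from phenoml.satellite_features import (
    FLAG_SETS,
    SMOOTHING_LAM,
    VICellCache,
    assemble_modis_features,
    fill_gaps,
    mask_snow,
    modis_feature_names,
    normalize_location,
    rate_of_change,
    reliability_mean,
    rolling_week,
    smooth_to_daily,
    snow_feature_names,
    snow_metrics,
)


def _daily_series(start, n, values):
    idx = pd.date_range(start, periods=n, freq="D")
    return pd.Series(np.asarray(values, dtype=float), index=idx)


# ---------------------------------------------------------------------------
# names


def test_feature_name_counts():
    assert len(modis_feature_names()) == 64
    assert len(snow_feature_names()) == 5
    assert len(set(modis_feature_names())) == 64


# ---------------------------------------------------------------------------
# snow masking


def _toy_vi(values, dates=None):
    dates = dates if dates is not None else pd.date_range("2007-01-01", periods=len(values))
    return pd.DataFrame(
        {
            "cell_id": "c0",
            "pixel_id": 0,
            "date": dates,
            "variable": "NDVI",
            "value": np.asarray(values, dtype=float),
            "reliability": 0,
        }
    )


def _toy_snow(flags, dates=None):
    dates = dates if dates is not None else pd.date_range("2007-01-01", periods=len(flags))
    return pd.DataFrame({"cell_id": "c0", "date": dates, "value": list(flags)})


def test_mask_snow_all_snow_zeroes_everything():
    out = mask_snow(_toy_vi([0.5] * 4), _toy_snow([1, 1, 1, 1]))
    assert (out["value"] == 0.0).all()


def test_mask_snow_no_snow_is_identity():
    vi = _toy_vi([0.1, 0.2, 0.3, 0.4])
    out = mask_snow(vi, _toy_snow([0, 0, 0, 0]))
    pd.testing.assert_frame_equal(out, vi)


def test_mask_snow_elementwise_oracle():
    vi = _toy_vi([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
    out = mask_snow(vi, _toy_snow([0, 1, 1, 0, 0, 0]))
    assert list(out["value"]) == [0.1, 0.0, 0.0, 0.4, 0.5, 0.6]


def test_mask_snow_uncovered_date_raises():
    vi = _toy_vi([0.1, 0.2, 0.3])
    with pytest.raises(ValueError, match="cover"):
        mask_snow(vi, _toy_snow([0, 0]))


# ---------------------------------------------------------------------------
# gap filling


def _series_frame(values, dates):
    return pd.DataFrame(
        {"value": np.asarray(values, dtype=float), "reliability": 0},
        index=pd.DatetimeIndex(dates),
    )


def test_fill_gaps_midpoint():
    dates = pd.date_range("2007-01-01", periods=3, freq="8D")
    out = fill_gaps(_series_frame([0.2, np.nan, 0.4], dates))
    assert out["value"].iloc[1] == pytest.approx(0.3)
    assert out["reliability"].iloc[1] == 3  # filled points marked worst


def test_fill_gaps_no_gaps_identity():
    dates = pd.date_range("2007-01-01", periods=5, freq="8D")
    frame = _series_frame([0.1, 0.2, 0.3, 0.4, 0.5], dates)
    pd.testing.assert_frame_equal(fill_gaps(frame), frame)


def test_fill_gaps_matches_two_pointer_oracle():
    rng = np.random.default_rng(0)
    dates = pd.date_range("2007-01-01", periods=50, freq="8D")
    values = rng.normal(0.5, 0.1, 50)
    values[rng.random(50) < 0.3] = np.nan
    values[[0, -1]] = np.nan  # exercise edge fill
    values[5] = 0.7  # guarantee some valid points
    out = fill_gaps(_series_frame(values, dates))

    # independent two-pointer linear interpolation on the time axis
    t = dates.asi8.astype(float)
    valid = np.flatnonzero(~np.isnan(values))
    expect = values.copy()
    for i in range(50):
        if not np.isnan(values[i]):
            continue
        left = valid[valid < i]
        right = valid[valid > i]
        if len(left) and len(right):
            i0, i1 = left[-1], right[0]
            frac = (t[i] - t[i0]) / (t[i1] - t[i0])
            expect[i] = values[i0] + frac * (values[i1] - values[i0])
        elif len(right):
            expect[i] = values[right[0]]
        else:
            expect[i] = values[left[-1]]
    assert np.allclose(out["value"].to_numpy(), expect, atol=1e-9)


def test_fill_gaps_all_missing_raises():
    dates = pd.date_range("2007-01-01", periods=4, freq="8D")
    with pytest.raises(ValueError, match="all-missing"):
        fill_gaps(_series_frame([np.nan] * 4, dates))


def test_masking_before_filling_preserves_snow_zeros():
    """A snow-day zero anchors interpolation: no bridging across the snow period."""
    dates = pd.date_range("2007-01-01", periods=5, freq="8D")
    observed = [0, 2, 4]  # middle observation falls on a snow day
    vi = _toy_vi([0.5, 0.5, 0.5], dates[observed])
    snow = _toy_snow([0, 0, 1, 0, 0], dates)
    masked = mask_snow(vi, snow)
    means = reliability_mean(masked, None)
    filled = fill_gaps(pd.DataFrame({"value": means, "reliability": 0}))
    # masking precedes filling, so the snow day is an exact zero, not 0.5
    assert filled["value"].loc[dates[2]] == 0.0


# ---------------------------------------------------------------------------
# smoothing


def test_smooth_constant_series():
    dates = pd.date_range("2007-01-01", periods=6, freq="8D")
    out = smooth_to_daily(pd.Series(0.5, index=dates))
    assert (out == 0.5).all()
    assert len(out) == 41


def test_smooth_reproduces_straight_line():
    dates = pd.date_range("2007-01-01", periods=8, freq="8D")
    x = (dates - dates[0]).days.to_numpy(dtype=float)
    series = pd.Series(0.1 + 0.01 * x, index=dates)
    out = smooth_to_daily(series, lam=0.0)
    days = (out.index - dates[0]).days.to_numpy(dtype=float)
    assert np.allclose(out.to_numpy(), 0.1 + 0.01 * days, atol=1e-6)


def test_smooth_noisy_sinusoid_beats_noise_floor():
    rng = np.random.default_rng(1)
    dates = pd.date_range("2007-01-01", periods=20, freq="8D")
    x = (dates - dates[0]).days.to_numpy(dtype=float)
    truth = 0.5 + 0.3 * np.sin(2 * np.pi * x / 160.0)
    noise_sd = 0.05
    series = pd.Series(truth + rng.normal(0, noise_sd, len(x)), index=dates)
    for lam in (None, SMOOTHING_LAM):  # GCV and the pipeline's fixed penalty
        out = smooth_to_daily(series, lam=lam)
        daily_x = (out.index - dates[0]).days.to_numpy(dtype=float)
        daily_truth = 0.5 + 0.3 * np.sin(2 * np.pi * daily_x / 160.0)
        rmse = np.sqrt(np.mean((out.to_numpy() - daily_truth) ** 2))
        assert rmse < noise_sd


def test_smooth_extends_to_end_date():
    dates = pd.date_range("2007-01-01", periods=5, freq="8D")
    series = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5], index=dates)
    out = smooth_to_daily(series, end=pd.Timestamp("2007-02-07"))
    assert out.index[-1] == pd.Timestamp("2007-02-07")
    assert np.isfinite(out.to_numpy()).all()


def test_smooth_needs_four_points():
    dates = pd.date_range("2007-01-01", periods=3, freq="8D")
    with pytest.raises(ValueError, match="4 support points"):
        smooth_to_daily(pd.Series([0.1, 0.2, 0.3], index=dates))


# ---------------------------------------------------------------------------
# reliability-stratified aggregation


def test_reliability_mean_single_good_pixel_identity():
    vi = _toy_vi([0.1, 0.2, 0.3])
    out = reliability_mean(vi, (0,))
    assert np.allclose(out.to_numpy(), [0.1, 0.2, 0.3])


def test_reliability_mean_hand_oracle():
    flags = [0, 0, 1, 2, 3, 3, 1, 0, 2]
    values = np.arange(9, dtype=float) / 10.0
    vi = pd.DataFrame(
        {
            "cell_id": "c0",
            "pixel_id": range(9),
            "date": pd.Timestamp("2007-06-01"),
            "variable": "NDVI",
            "value": values,
            "reliability": flags,
        }
    )
    got = reliability_mean(vi, (0, 1))
    qualify = [v for v, f in zip(values, flags) if f in (0, 1)]
    assert got.iloc[0] == pytest.approx(np.mean(qualify))


def test_reliability_mean_empty_flag_set_raises():
    with pytest.raises(ValueError, match="flag_set"):
        reliability_mean(_toy_vi([0.1]), ())


def test_reliability_strata_valid_date_monotonicity(tiny):
    """Strictest stratum {0} can never have more valid dates than {0,1,2}."""
    for cell in tiny.stations["cell_id"].unique()[:3]:
        pixels = tiny.vi[(tiny.vi["cell_id"] == cell) & (tiny.vi["variable"] == "NDVI")]
        strict = reliability_mean(pixels, FLAG_SETS["r0"])
        loose = reliability_mean(pixels, FLAG_SETS["r012"])
        assert strict.notna().sum() <= loose.notna().sum()
        assert len(strict) == len(loose)


# ---------------------------------------------------------------------------
# derived operators


def test_constant_series_operator_identities():
    s = _daily_series("2007-01-01", 40, np.full(40, 0.7))
    roll = rolling_week(s)
    assert np.allclose(roll.dropna().to_numpy(), 0.7)
    at = s.index[-1]
    assert rate_of_change(s, 30, 10, at) == pytest.approx(0.0)
    assert rate_of_change(s, 10, 7, at) == pytest.approx(0.0)
    history = _daily_series("2006-01-01", 365, np.full(365, 0.7))
    z = normalize_location(s, history)
    assert np.allclose(z.to_numpy(), 0.0)


def test_ramp_has_positive_rate():
    s = _daily_series("2007-01-01", 40, np.linspace(0.0, 1.0, 40))
    assert rate_of_change(s, 30, 10, s.index[-1]) > 0


def test_operators_match_window_oracles():
    rng = np.random.default_rng(2)
    s = _daily_series("2008-03-01", 60, rng.normal(0.5, 0.2, 60))
    history = _daily_series("2007-01-01", 365, rng.normal(0.5, 0.2, 365))
    vals = s.to_numpy()

    roll = rolling_week(s)
    for i in range(6, 60):
        assert abs(roll.iloc[i] - vals[i - 6 : i + 1].mean()) < 1e-9

    at = s.index[45]
    assert abs(rate_of_change(s, 30, 10, at) - (vals[36:46].mean() - vals[16:46].mean())) < 1e-9
    assert abs(rate_of_change(s, 10, 7, at) - (vals[39:46].mean() - vals[36:46].mean())) < 1e-9

    z = normalize_location(s, history, window_days=7)
    hist_doys = history.index.dayofyear.to_numpy()
    hist_vals = history.to_numpy()
    for i, (date, value) in enumerate(s.items()):
        doy = pd.Timestamp(date).dayofyear
        pool = hist_vals[np.mod(doy - hist_doys, 365) <= 7]
        expect = (value - pool.mean()) / pool.std()
        assert abs(z.iloc[i] - expect) < 1e-9


def test_rate_of_change_insufficient_history_raises():
    s = _daily_series("2007-01-01", 20, np.ones(20))
    with pytest.raises(ValueError, match="insufficient history"):
        rate_of_change(s, 30, 10, s.index[-1])


# ---------------------------------------------------------------------------
# snow metrics


def test_snow_metrics_never_snow():
    s = _daily_series("2007-01-01", 181, np.zeros(181))
    out = snow_metrics(s, pd.Timestamp("2007-06-30"))
    assert out == {
        "mod_snow_present": 0.0,
        "mod_snow_run_days": 0.0,
        "mod_snowfree_run_days": 181.0,
        "mod_snow_days_month": 0.0,
        "mod_last_snow_doy": 0.0,
    }


def test_snow_metrics_run_length_oracle():
    cutoff = pd.Timestamp("2007-03-31")  # DOY 90
    vals = np.zeros(90)
    vals[:80] = 1.0  # snow through DOY 80, bare for the last 10 days
    s = _daily_series("2007-01-01", 90, vals)
    out = snow_metrics(s, cutoff)
    assert out["mod_snowfree_run_days"] == 10.0
    assert out["mod_last_snow_doy"] == 80.0
    assert out["mod_snow_present"] == 0.0
    assert out["mod_snow_days_month"] == 21.0  # DOYs 60..80 fall in March


def test_snow_presence_run_consistency():
    rng = np.random.default_rng(3)
    for _ in range(10):
        vals = (rng.random(60) < 0.4).astype(float)
        s = _daily_series("2007-01-01", 60, vals)
        out = snow_metrics(s, s.index[-1])
        assert (out["mod_snow_present"] == 1.0) == (out["mod_snow_run_days"] >= 1.0)


# ---------------------------------------------------------------------------
# cell-level assembly


def test_assembled_modis_row_complete_and_finite(tiny_builder, tiny):
    cell = tiny.stations["cell_id"].iloc[0]
    rule = CutoffRule("p", 5)
    row = assemble_modis_features(tiny_builder.vicache, cell, 2008, rule, (2007, 2008))
    assert list(row) == modis_feature_names() + snow_feature_names()
    assert all(np.isfinite(v) for v in row.values())


def test_doubling_one_index_scales_only_its_linear_features(tiny):
    """LAI x2: LAI mean/roll/rate features double, LAI norm features are
    scale-invariant, all other indices and snow metrics are untouched."""
    cell = tiny.stations["cell_id"].iloc[0]
    vi2 = tiny.vi.copy()
    lai = vi2["variable"] == "LAI"
    vi2.loc[lai, "value"] = vi2.loc[lai, "value"] * 2.0

    rule = CutoffRule("p", 5)
    base = assemble_modis_features(VICellCache(tiny.vi, tiny.snow), cell, 2008, rule, (2007, 2008))
    doubled = assemble_modis_features(VICellCache(vi2, tiny.snow), cell, 2008, rule, (2007, 2008))

    for name in base:
        if "_lai_" in name and ("_mean_" in name or "_roll7_" in name or "_rate_" in name):
            assert doubled[name] == pytest.approx(2.0 * base[name], rel=1e-8, abs=1e-10), name
        else:
            assert doubled[name] == pytest.approx(base[name], rel=1e-8, abs=1e-10), name
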