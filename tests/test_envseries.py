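"""Environmental preprocessing: offset, pO2, window summaries, gaps, trends."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fjordbeta as fb
from fjordbeta.envseries import (
    P_ATM_KPA, X_O2, oxygen_solubility, water_vapor_pressure_kpa,
)

from conftest import make_env


# ---------------------------------------------------------------------------
# offset correction
# ---------------------------------------------------------------------------

class TestOffset:
    def test_zero_offset_is_identity(self):
        env = make_env({"o2_conc": [1.0, 2.0, 0.5]})
        out = fb.correct_offset(env, 0.0)
        pd.testing.assert_frame_equal(out.values, env.values)

    def test_constant_offset_zeroes_matching_signal(self):
        env = make_env({"o2_conc": [0.048] * 5})
        out = fb.correct_offset(env, 0.048)
        assert np.allclose(out.values["o2_conc"], 0.0)

    def test_clamp_at_zero(self):
        env = make_env({"o2_conc": [0.02, 0.10]})
        out = fb.correct_offset(env, 0.048)
        assert np.allclose(out.values["o2_conc"], [0.0, 0.052])

    def test_other_channels_untouched_and_negative_rejected(self):
        env = make_env({"o2_conc": [1.0], "temperature": [8.0]})
        out = fb.correct_offset(env, 0.5)
        assert out.values["temperature"].iloc[0] == 8.0
        with pytest.raises(ValueError, match="offset"):
            fb.correct_offset(env, -0.1)


# ---------------------------------------------------------------------------
# oxygen partial pressure
# ---------------------------------------------------------------------------

class TestPO2:
    def test_zero_concentration_gives_zero(self):
        assert fb.compute_po2(0.0, 10.0, 31.0) == 0.0

    def test_saturation_identity(self):
        # a 100%-air-saturated sample: pO2 must equal xO2 * (Patm - pH2O)
        t, s = 10.0, 31.0
        csat = oxygen_solubility(t, s)
        po2 = fb.compute_po2(csat, t, s)
        expected = X_O2 * (P_ATM_KPA - water_vapor_pressure_kpa(t, s))
        assert abs(po2 - expected) < 0.1

    def test_linear_in_concentration(self):
        a = fb.compute_po2(1.0, 9.0, 31.0)
        b = fb.compute_po2(2.0, 9.0, 31.0)
        assert b == pytest.approx(2 * a, rel=1e-12)

    @given(st.floats(0.1, 8.0), st.floats(2.0, 20.0), st.floats(20.0, 35.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_concentration(self, c, t, s):
        assert fb.compute_po2(c + 0.1, t, s) > fb.compute_po2(c, t, s)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            fb.compute_po2(np.array([-0.1]), 10.0, 31.0)

    def test_missing_channel_rejected(self):
        env = make_env({"o2_conc": [1.0, 2.0]})
        with pytest.raises(ValueError, match="temperature"):
            fb.add_po2(env)

    def test_commutes_with_time_subsetting(self):
        env = make_env({"o2_conc": np.linspace(0.1, 2, 10),
                        "temperature": np.full(10, 9.0),
                        "salinity": np.full(10, 31.0)})
        full = fb.add_po2(env).values["po2"]
        sub = fb.add_po2(env.subset(env.timestamps[3], env.timestamps[7]))
        assert np.allclose(sub.values["po2"], full.iloc[3:8])


# ---------------------------------------------------------------------------
# window summaries
# ---------------------------------------------------------------------------

class TestWindowSummary:
    def test_constant_series(self):
        env = make_env({"x": np.full(120, 3.5)})
        tgt = [env.timestamps[60]]
        ws = fb.summarize_window(env, tgt, "1h")
        assert ws.stats["mean"]["x"].iloc[0] == 3.5
        assert ws.stats["max"]["x"].iloc[0] == 3.5
        assert ws.stats["min"]["x"].iloc[0] == 3.5
        assert ws.stats["sd"]["x"].iloc[0] == 0.0

    def test_hand_computed_five_values(self):
        env = make_env({"x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        tgt = [env.timestamps[-1]]
        ws = fb.summarize_window(env, tgt, "5min")
        assert ws.stats["mean"]["x"].iloc[0] == pytest.approx(3.0)
        assert ws.stats["min"]["x"].iloc[0] == 1.0
        assert ws.stats["max"]["x"].iloc[0] == 5.0
        assert ws.stats["sd"]["x"].iloc[0] == pytest.approx(1.5811, abs=1e-4)

    def test_half_open_window_excludes_left_edge(self):
        env = make_env({"x": [10.0, 1.0, 1.0]})
        tgt = [env.timestamps[2]]
        ws = fb.summarize_window(env, tgt, "2min")  # (t-2min, t] -> rows 1, 2
        assert ws.stats["max"]["x"].iloc[0] == 1.0

    def test_order_invariance_within_window(self, rng):
        vals = rng.normal(size=30)
        env1 = make_env({"x": vals})
        env2 = make_env({"x": vals[::-1]})
        t = [env1.timestamps[-1] + pd.Timedelta("1min")]
        w1 = fb.summarize_window(env1, t, "40min")
        w2 = fb.summarize_window(env2, t, "40min")
        for s in ("mean", "sd", "max", "min"):
            assert w1.stats[s]["x"].iloc[0] == pytest.approx(w2.stats[s]["x"].iloc[0])

    def test_zero_coverage_yields_missing(self):
        env = make_env({"x": [1.0, 2.0]})
        early = [env.timestamps[0] - pd.Timedelta("1h")]
        ws = fb.summarize_window(env, early, "12min")
        assert np.isnan(ws.stats["mean"]["x"].iloc[0])
        assert ws.coverage["x"].iloc[0] == 0.0

    def test_masked_samples_ignored(self):
        env = make_env({"x": [1.0, 100.0, 3.0]})
        env.mask.iloc[1, 0] = True
        ws = fb.summarize_window(env, [env.timestamps[-1]], "3min")
        assert ws.stats["max"]["x"].iloc[0] == 3.0
        assert ws.stats["mean"]["x"].iloc[0] == 2.0


# ---------------------------------------------------------------------------
# interpolation and running mean
# ---------------------------------------------------------------------------

class TestInterpolate:
    def test_no_gaps_identity(self):
        env = make_env({"x": [1.0, 2.0, 3.0]})
        out = fb.interpolate_gaps(env)
        pd.testing.assert_frame_equal(out.values, env.values)

    def test_midpoint(self):
        env = make_env({"x": [1.0, np.nan, 3.0]})
        out = fb.interpolate_gaps(env)
        assert out.values["x"].iloc[1] == 2.0
        assert not out.mask["x"].iloc[1]

    def test_leading_gap_never_extrapolated(self):
        env = make_env({"x": [np.nan, 2.0, 3.0]})
        out = fb.interpolate_gaps(env)
        assert out.mask["x"].iloc[0]

    def test_max_gap_limits_fill(self):
        env = make_env({"x": [1.0, np.nan, np.nan, np.nan, 5.0, np.nan, 7.0]})
        out = fb.interpolate_gaps(env, max_gap="2min")
        assert out.mask["x"].iloc[1:4].all()  # 4-min anchor span, too long
        assert out.values["x"].iloc[5] == 6.0  # 2-min span, filled

    def test_all_missing_rejected(self):
        env = make_env({"x": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="no observed"):
            fb.interpolate_gaps(env)

    def test_roundtrip_with_window_summary_on_linear_signal(self):
        t = np.arange(200, dtype=float)
        env_full = make_env({"x": 2.0 + 0.5 * t})
        vals = env_full.values.copy()
        vals.iloc[50:55] = np.nan
        env_gap = fb.EnvSeries(vals)
        filled = fb.interpolate_gaps(env_gap)
        tgt = [env_full.timestamps[60]]
        w1 = fb.summarize_window(env_full, tgt, "30min")
        w2 = fb.summarize_window(filled, tgt, "30min")
        assert w1.stats["mean"]["x"].iloc[0] == pytest.approx(
            w2.stats["mean"]["x"].iloc[0])


class TestRunningMean:
    def test_constant_shortened_by_trim(self):
        env = make_env({"x": np.full(100 * 24, 2.0)}, freq="1h")
        out = fb.running_mean(env, "10D", "5D")
        assert np.allclose(out.values["x"], 2.0)
        assert out.timestamps[0] >= env.timestamps[0] + pd.Timedelta("5D")

    def test_linear_signal_unchanged_in_interior(self):
        n = 200 * 24
        t = np.arange(n) / 24.0
        env = make_env({"x": 1.0 + 0.3 * t}, freq="1h")
        out = fb.running_mean(env, "20D", "15D")
        expect = 1.0 + 0.3 * (out.timestamps - env.timestamps[0]).total_seconds().to_numpy() / 86400
        assert np.allclose(out.values["x"], expect, atol=1e-6)

    def test_window_longer_than_span_rejected(self):
        env = make_env({"x": np.arange(10.0)}, freq="1h")
        with pytest.raises(ValueError, match="span"):
            fb.running_mean(env, "400D", "0D")


# ---------------------------------------------------------------------------
# long-term trend and threshold durations
# ---------------------------------------------------------------------------

class TestDecadalTrend:
    def test_flat_series_zero_slope(self):
        env = make_env({"o2_conc": np.full(4 * 365 * 24, 1.5)}, freq="1h")
        slope, _, _ = fb.decadal_trend(env, truncate_at_maxima=False)
        assert abs(slope) < 1e-10

    def test_whole_cycle_sinusoid_near_zero_slope(self):
        n = 5 * 8766
        yr = np.arange(n) / 8766.0
        env = make_env({"o2_conc": 1.5 + 0.8 * np.cos(2 * np.pi * yr)}, freq="1h")
        slope, _, _ = fb.decadal_trend(env)
        assert abs(slope) < 5e-3

    def test_programmed_slope_recovered_within_10pct(self):
        cyc = fb.generate_trend_cycle(slope=-0.067, seed=3)
        slope, p, _ = fb.decadal_trend(cyc)
        assert abs(slope - (-0.067)) < 0.1 * 0.067
        assert p < 1e-6


class TestThresholdDurations:
    def test_always_above_gives_zero_and_flat_trend(self):
        env = make_env({"o2_conc": np.full(4 * 8766, 2.0)}, freq="1h",
                       start="2006-03-16")
        rep = fb.threshold_durations(env, thresholds=(0.5,))
        assert (rep.durations[0.5].dropna() == 0).all()
        assert abs(rep.trends[0.5]["slope_days_per_year"]) < 1e-9

    def test_square_wave_exact_to_sampling_step(self):
        expo = fb.generate_exposure_series(years=4, base_duration_days=100.0,
                                           duration_slope=0.0, seed=1)
        rep = fb.threshold_durations(expo, thresholds=(0.5,))
        got = rep.durations[0.5].dropna()
        assert np.all(np.abs(got - 100.0) <= 1.0 / 24 + 1e-9)

    def test_programmed_duration_trend_recovered(self):
        expo = fb.generate_exposure_series(duration_slope=12.4, seed=2)
        rep = fb.threshold_durations(expo, thresholds=(0.5,))
        tr = rep.trends[0.5]
        assert tr["slope_days_per_year"] == pytest.approx(12.4, abs=0.5)
        assert tr["p_value"] < 0.01

    def test_monotone_in_threshold(self):
        expo = fb.generate_exposure_series(years=3, seed=5)
        rep = fb.threshold_durations(expo, thresholds=(0.3, 0.5, 1.0))
        d = rep.durations.dropna()
        assert (d[0.3] <= d[0.5] + 1e-9).all()
        assert (d[0.5] <= d[1.0] + 1e-9).all()

    def test_empty_year_reported_missing(self):
        # two years of data, then a year-long hole before a final stub
        idx1 = pd.date_range("2006-03-16", "2008-03-10", freq="1h")
        idx2 = pd.date_range("2009-06-01", "2009-08-01", freq="1h")
        idx = idx1.append(idx2)
        df = pd.DataFrame({"o2_conc": np.full(len(idx), 0.2)}, index=idx)
        rep = fb.threshold_durations(fb.EnvSeries(df), thresholds=(0.5,))
        assert rep.durations[0.5].isna().any()
        assert not rep.durations[0.5].dropna().empty
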