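"""Synthetic scenario generator: oxygen cycle, guild dynamics, drivers, gaps."""

import numpy as np
import pandas as pd
import pytest

import fjordbeta as fb
from fjordbeta.simulate import GapModel, expected_densities, seasonal_template

from conftest import make_env


def _constant_env(o2, days=160, freq="1h", start="2012-01-01"):
    n = int(days * 24)
    return make_env({"o2_conc": np.full(n, float(o2))}, start=start, freq=freq)


def _step_env(high, low, days_before, days_low, days_after, freq="1h"):
    vals = np.concatenate([
        np.full(int(days_before * 24), high),
        np.full(int(days_low * 24), low),
        np.full(int(days_after * 24), high),
    ])
    return make_env({"o2_conc": vals}, start="2012-01-01", freq=freq)


class TestOxygenCycle:
    def test_zero_variability_equals_template(self):
        sc = fb.default_scenario(noise_sd_frac=0.0, sensor_offset=0.0,
                                 sampling_interval_env=30.0)
        env = fb.generate_oxygen_cycle(sc)
        tpl = seasonal_template(sc, env.timestamps)
        assert np.allclose(env.values["o2_conc"], tpl, atol=1e-12)

    def test_fixed_seed_bit_identical(self):
        sc = fb.default_scenario(sampling_interval_env=30.0, seed=3)
        a = fb.generate_oxygen_cycle(sc)
        b = fb.generate_oxygen_cycle(sc)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_severe_hypoxia_duration_matches_configuration(self):
        sc = fb.default_scenario()
        assert sc.severe_hypoxia_days == 174.0  # the observed cycle's duration
        env = fb.generate_oxygen_cycle(sc)
        o2 = env.values["o2_conc"] - sc.sensor_offset
        daily = o2.groupby(o2.index.normalize()).mean()
        days_below = int((daily < sc.severe_threshold).sum())
        assert abs(days_below - sc.severe_hypoxia_days) <= 2

    def test_window_variability_tracks_the_mean(self):
        sc = fb.default_scenario(sampling_interval_env=5.0, seed=1)
        env = fb.generate_oxygen_cycle(sc)
        o2 = env.values["o2_conc"]
        m = o2.rolling("12h").mean().to_numpy()[::144]
        s = o2.rolling("12h").std().to_numpy()[::144]
        ok = np.isfinite(m) & np.isfinite(s)
        assert np.corrcoef(m[ok], s[ok])[0, 1] > 0.5

    def test_floor_respected_and_backscatter_suppressed(self):
        sc = fb.default_scenario(sampling_interval_env=30.0)
        env = fb.generate_oxygen_cycle(sc)
        o2 = env.values["o2_conc"] - sc.sensor_offset
        assert (o2 >= sc.o2_floor - 1e-9).all()
        bs = env.values["backscatter"]
        assert bs[o2 < 0.1].mean() < bs[o2 > 1.5].mean() - 20

    @pytest.mark.parametrize("field, value", [
        ("o2_baseline", np.nan), ("gap_fraction", 1.2), ("o2_floor", -0.5),
        ("noise_sd_frac", -1.0),
    ])
    def test_invalid_scenario_fields_named(self, field, value):
        with pytest.raises(ValueError, match=field):
            fb.default_scenario(**{field: value})


class TestGuildDynamics:
    def test_constant_high_oxygen_no_stress_response(self):
        env = _constant_env(1.8)
        arch = [a for a in fb.default_archetypes() if a.guild in ("sessile", "emergent")]
        mu = expected_densities(env, arch)
        for sp in arch:
            if sp.guild == "sessile":
                assert np.allclose(mu[sp.name], sp.carrying_density)
            else:
                assert np.allclose(mu[sp.name], 0.0)

    def test_sessile_step_response_shows_hysteresis(self):
        sp = next(a for a in fb.default_archetypes() if a.name == "ball_sponge")
        lag = sp.mortality_lag_days
        env = _step_env(1.8, 0.1, days_before=10, days_low=lag + 30, days_after=45)
        mu = expected_densities(env, [sp])[sp.name]
        step_end = pd.Timestamp("2012-01-01") + pd.Timedelta(days=10 + lag + 30)
        # declined by the end of the exposure
        assert mu.loc[:step_end].iloc[-1] < sp.carrying_density
        # still declining 30 days after oxygen recovery
        t30 = step_end + pd.Timedelta(days=30)
        window = mu.loc[t30 - pd.Timedelta("2D"): t30]
        assert window.iloc[-1] < window.iloc[0] - 1e-9

    def test_mobile_tracks_oxygen_with_days_scale_response(self):
        sp = next(a for a in fb.default_archetypes() if a.name == "slender_sole")
        env = _step_env(1.8, 0.05, days_before=30, days_low=60, days_after=0)
        mu = expected_densities(env, [sp])[sp.name]
        daily = mu.groupby(mu.index.normalize()).mean()
        assert daily.iloc[5] > 0.9 * sp.carrying_density
        # logistic occupancy at O2 = 0.05 with threshold 0.36 retains a tail
        assert daily.iloc[-1] < 0.15 * sp.carrying_density
        drop_days = (daily < 0.5 * sp.carrying_density).idxmax() - pd.Timestamp("2012-01-31")
        assert pd.Timedelta("0D") < drop_days < pd.Timedelta("40D")

    def test_emergent_only_below_threshold(self):
        sp = next(a for a in fb.default_archetypes() if a.guild == "emergent")
        env = _step_env(1.5, 0.02, days_before=20, days_low=40, days_after=30)
        mu = expected_densities(env, [sp])[sp.name]
        assert mu.loc[:"2012-01-15"].max() == 0.0
        assert mu.loc["2012-02-10":"2012-02-25"].min() > 0.5 * sp.carrying_density
        assert mu.iloc[-1] == 0.0

    def test_diel_species_higher_at_midnight(self):
        arch = [a for a in fb.default_archetypes() if a.name == "slender_sole"]
        env = _constant_env(1.8, days=40)
        targets = pd.date_range("2012-01-02", periods=70, freq="12h")
        comm = fb.generate_community(env, arch, seed=11, targets=targets)
        dens = comm.densities["slender_sole"]
        midnight = dens[dens.index.hour == 0]
        noon = dens[dens.index.hour == 12]
        assert midnight.mean() > noon.mean()

    def test_counts_nonnegative_and_reproducible(self):
        env = _constant_env(1.0, days=30)
        targets = pd.date_range("2012-01-02", periods=50, freq="12h")
        c1 = fb.generate_community(env, fb.default_archetypes(), seed=4, targets=targets)
        c2 = fb.generate_community(env, fb.default_archetypes(), seed=4, targets=targets)
        assert (c1.densities.to_numpy() >= 0).all()
        pd.testing.assert_frame_equal(c1.densities, c2.densities)

    def test_empty_archetypes_rejected(self):
        env = _constant_env(1.0, days=5)
        with pytest.raises(ValueError, match="empty"):
            fb.generate_community(env, [], seed=0)


class TestPresenceDrivers:
    def test_seven_binary_columns(self):
        env = _constant_env(1.0, days=30)
        d = fb.generate_presence_drivers(env, seed=0)
        assert d.shape[1] == 7
        assert set(np.unique(d.to_numpy())) <= {0, 1}

    def test_zero_slope_gives_constant_rate_bernoulli(self):
        lo = _constant_env(0.05, days=60)
        hi = _constant_env(1.8, days=60)
        d_lo = fb.generate_presence_drivers(lo, seed=1, slope=0.0)
        d_hi = fb.generate_presence_drivers(hi, seed=1, slope=0.0)
        # same constant on-rate regardless of oxygen
        assert abs(d_lo["bacterial_mat"].mean() - d_hi["bacterial_mat"].mean()) < 0.05

    def test_bacterial_mat_more_likely_in_anoxia(self):
        lo = _constant_env(0.05, days=90)
        hi = _constant_env(1.8, days=90)
        r_lo = fb.generate_presence_drivers(lo, seed=2)["bacterial_mat"].mean()
        r_hi = fb.generate_presence_drivers(hi, seed=2)["bacterial_mat"].mean()
        assert r_lo > r_hi + 0.3

    def test_zooplankton_swarms_at_high_oxygen(self):
        lo = _constant_env(0.05, days=90)
        hi = _constant_env(1.8, days=90)
        r_lo = fb.generate_presence_drivers(lo, seed=3)["euphausiid_swarm"].mean()
        r_hi = fb.generate_presence_drivers(hi, seed=3)["euphausiid_swarm"].mean()
        assert r_hi > r_lo + 0.3


class TestGapModel:
    def test_identity_when_disabled(self):
        env = _constant_env(1.0, days=10)
        out = fb.apply_gap_model(env, GapModel(fraction=0.0, long_gap_days=0.0), seed=0)
        assert not out.mask.to_numpy().any()

    def test_masked_fraction_within_one_percent(self):
        env = _constant_env(1.0, days=200)
        out = fb.apply_gap_model(env, GapModel(fraction=0.28, long_gap_days=15.0,
                                               long_gap_start="2012-03-01"), seed=1)
        frac = out.mask["o2_conc"].mean()
        assert abs(frac - 0.28) <= 0.01

    def test_values_untouched_by_masking(self):
        env = _constant_env(1.0, days=50)
        before = env.values.copy()
        out = fb.apply_gap_model(env, GapModel(fraction=0.2, long_gap_days=5.0,
                                               long_gap_start="2012-01-10"), seed=2)
        pd.testing.assert_frame_equal(out.values, before)

    def test_long_block_spans_fifteen_days(self):
        targets = pd.date_range("2012-01-01", periods=200, freq="12h")
        dens = pd.DataFrame({"sp": np.ones(200)}, index=targets)
        comm = fb.CommunityMatrix(dens)
        gm = GapModel(fraction=30 / 200, long_gap_days=15.0, long_gap_start="2012-02-01")
        out = fb.apply_gap_model(comm, gm, seed=0)
        miss = out.row_mask.to_numpy()
        runs, cur, best = [], None, (0, 0)
        for i, v in enumerate(miss):
            if v and cur is None:
                cur = i
            if not v and cur is not None:
                runs.append((cur, i - 1)); cur = None
        if cur is not None:
            runs.append((cur, len(miss) - 1))
        longest = max(runs, key=lambda r: r[1] - r[0])
        span = targets[longest[1]] - targets[longest[0]]
        assert pd.Timedelta("14D") <= span <= pd.Timedelta("15D")

    def test_block_longer_than_record_rejected(self):
        env = _constant_env(1.0, days=5)
        with pytest.raises(ValueError, match="span"):
            fb.apply_gap_model(env, GapModel(fraction=0.1, long_gap_days=20.0), seed=0)


class TestDataset:
    def test_dataset_deterministic_and_consistent(self, fast_scenario):
        d1 = fb.simulate_dataset(fast_scenario)
        d2 = fb.simulate_dataset(fast_scenario)
        pd.testing.assert_frame_equal(d1["env"].values, d2["env"].values)
        pd.testing.assert_frame_equal(d1["community"].densities,
                                      d2["community"].densities)
        pd.testing.assert_series_equal(d1["community"].row_mask,
                                       d2["community"].row_mask)
        assert d1["truth"]["sessile_hysteresis_ratio"] == pytest.approx(1 / 0.3)

    def test_scenario_roundtrip_via_dict(self):
        sc = fb.default_scenario(seed=9)
        sc2 = fb.FjordScenario.from_dict(sc.to_dict())
        assert sc2 == sc
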