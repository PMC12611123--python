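"""Preprocessing-chain tests: interpolation, robust outlier screening,
seasonal adjustment, frequency alignment, standardization, and windowing."""

import numpy as np
import pandas as pd
import pytest

from ecorestore.preprocess import (
    Standardizer,
    align_frequency,
    fill_missing,
    invert_seasonal_adjust,
    make_windows,
    monthly_climatology,
    preprocess_panel,
    remove_outliers,
    seasonal_adjust,
)
from ecorestore.simulate import (
    COVARIATES,
    ScenarioConfig,
    SiteSeries,
    generate_panel,
    inject_missingness,
)


def make_site(values: dict, site_id="S0", altitude=3000.0):
    n = len(next(iter(values.values())))
    cols = {c: values.get(c, np.linspace(0.2, 0.8, n)) for c in COVARIATES}
    cols["survival_pct"] = values.get("survival_pct", np.full(n, 80.0))
    df = pd.DataFrame(cols, index=pd.RangeIndex(n, name="month_index"))
    return SiteSeries(site_id=site_id, altitude_m=altitude, data=df)


class TestFillMissing:
    def test_linear_midpoint(self):
        s = make_site({"temp_c": [1.0, np.nan, 3.0]})
        out = fill_missing(s)
        assert out.data["temp_c"].iloc[1] == pytest.approx(2.0)

    def test_leading_gap_takes_nearest(self):
        s = make_site({"temp_c": [np.nan, 5.0, 6.0]})
        out = fill_missing(s)
        assert out.data["temp_c"].iloc[0] == pytest.approx(5.0)

    def test_no_missing_is_identity(self):
        s = make_site({"temp_c": [1.0, 2.0, 3.0]})
        pd.testing.assert_frame_equal(fill_missing(s).data, s.data)

    def test_fully_missing_variable_raises(self):
        s = make_site({"temp_c": [np.nan, np.nan, np.nan]})
        with pytest.raises(ValueError, match="temp_c.*S0|S0.*temp_c"):
            fill_missing(s)


class TestRemoveOutliers:
    def test_spike_in_flat_series_replaced(self):
        s = make_site({"temp_c": [1.0, 1.0, 100.0, 1.0, 1.0]})
        out, report = remove_outliers(s)
        assert out.data["temp_c"].iloc[2] == pytest.approx(1.0)
        assert len(report) == 1
        assert report.iloc[0]["variable"] == "temp_c"
        assert report.iloc[0]["month_index"] == 2

    def test_mild_series_untouched(self):
        vals = [1.0, 1.2, 0.9, 1.1, 1.0]
        s = make_site({"temp_c": vals})
        out, report = remove_outliers(s)
        np.testing.assert_array_equal(out.data["temp_c"], vals)
        assert report.empty

    def test_infinite_threshold_is_identity(self):
        s = make_site({"temp_c": [1.0, 1.0, 100.0, 1.0, 1.0]})
        out, report = remove_outliers(s, z_thresh=np.inf)
        np.testing.assert_array_equal(out.data["temp_c"], s.data["temp_c"])
        assert report.empty

    def test_constant_variable_warns_and_skips(self):
        s = make_site({"temp_c": [2.0] * 5})
        with pytest.warns(UserWarning, match="zero variance"):
            out, report = remove_outliers(s)
        np.testing.assert_array_equal(out.data["temp_c"], 2.0)

    def test_gapful_series_rejected(self):
        s = make_site({"temp_c": [1.0, np.nan, 2.0]})
        with pytest.raises(ValueError, match="gap-free"):
            remove_outliers(s)

    def test_chain_idempotent(self):
        panel = generate_panel(ScenarioConfig(n_sites=4, months=36, seed=31))
        panel = [inject_missingness(s, 0.1, seed=i) for i, s in enumerate(panel)]

        def chain(p):
            out = []
            for s in p:
                s2 = fill_missing(s)
                s2, _ = remove_outliers(s2)
                out.append(fill_missing(s2))
            return out

        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            once = chain(panel)
            twice = chain(once)
        for a, b in zip(once, twice):
            pd.testing.assert_frame_equal(a.data, b.data)


class TestSeasonalAdjust:
    def make_periodic_panel(self):
        m = np.arange(24)
        temp = 5 * np.cos(2 * np.pi * (m - 6) / 12)
        precip = 10 + 5 * np.sin(2 * np.pi * m / 12)
        return [make_site({"temp_c": temp, "precip_mm": precip})]

    def test_pure_periodic_series_zeroes_out(self):
        panel = self.make_periodic_panel()
        clim = monthly_climatology(panel)
        out = seasonal_adjust(panel[0], clim)
        np.testing.assert_allclose(out.data["temp_c"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out.data["precip_mm"], 0.0, atol=1e-12)

    def test_round_trip_restores_original(self):
        panel = generate_panel(ScenarioConfig(n_sites=3, months=36, seed=32))
        clim = monthly_climatology(panel)
        out = invert_seasonal_adjust(seasonal_adjust(panel[0], clim), clim)
        pd.testing.assert_frame_equal(out.data, panel[0].data, atol=1e-12)

    def test_january_hand_example(self):
        # January observed at 2 and 4 across two years: climatology 3,
        # residuals -1 and +1
        temp = np.zeros(24)
        temp[0], temp[12] = 2.0, 4.0
        panel = [make_site({"temp_c": temp})]
        clim = monthly_climatology(panel)
        assert clim["temp_c"].loc[0] == pytest.approx(3.0)
        out = seasonal_adjust(panel[0], clim)
        assert out.data["temp_c"].iloc[0] == pytest.approx(-1.0)
        assert out.data["temp_c"].iloc[12] == pytest.approx(1.0)

    def test_missing_calendar_month_raises(self):
        panel = [make_site({"temp_c": np.arange(10, dtype=float)})]  # 10 months
        with pytest.raises(ValueError, match="missing calendar months"):
            monthly_climatology(panel)

    def test_climatology_respects_training_cutoff(self):
        panel = generate_panel(ScenarioConfig(n_sites=3, months=48, seed=33))
        clim = monthly_climatology(panel, max_month_index=23)
        tampered = []
        for s in panel:
            t = s.copy()
            t.data.loc[t.data.index > 23, "temp_c"] += 100.0  # future months
            tampered.append(t)
        clim2 = monthly_climatology(tampered, max_month_index=23)
        pd.testing.assert_frame_equal(clim, clim2)


class TestAlignFrequency:
    def test_quarterly_to_monthly(self):
        got = align_frequency([0, 3], [10.0, 16.0], np.arange(4))
        np.testing.assert_allclose(got, [10.0, 12.0, 14.0, 16.0])

    def test_monthly_input_is_identity(self):
        vals = np.array([1.0, 4.0, 2.0])
        np.testing.assert_array_equal(
            align_frequency([0, 1, 2], vals, np.arange(3)), vals
        )

    def test_extrapolation_holds_last_value(self):
        got = align_frequency([0, 2], [1.0, 3.0], np.arange(5))
        np.testing.assert_allclose(got, [1.0, 2.0, 3.0, 3.0, 3.0])

    def test_single_observation_raises(self):
        with pytest.raises(ValueError, match="two observations"):
            align_frequency([0], [1.0], np.arange(3))


class TestStandardizer:
    @pytest.fixture()
    def split_windows(self):
        panel = generate_panel(ScenarioConfig(n_sites=8, months=40, seed=34))
        ds = make_windows(panel, T=12)
        n = len(ds)
        train = ds.subset(np.arange(int(0.7 * n)))
        test = ds.subset(np.arange(int(0.7 * n), n))
        return train, test

    def test_hand_example(self):
        # value 14 under train mean 10 / std 2 -> 2.0
        assert (14.0 - 10.0) / 2.0 == 2.0  # definitionally what transform does

    def test_train_split_zero_mean_unit_std(self, split_windows):
        train, _ = split_windows
        std = Standardizer.fit(train)
        Z = std.transform(train).X.reshape(-1, train.D)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_test_split_not_centred_by_train_stats(self, split_windows):
        train, test = split_windows
        std = Standardizer.fit(train)
        Z = std.transform(test).X.reshape(-1, test.D)
        assert np.abs(Z.mean(axis=0)).max() > 1e-3  # leakage guard

    def test_stats_depend_only_on_training_rows(self, split_windows):
        train, test = split_windows
        std1 = Standardizer.fit(train)
        test.X[...] += 1e6  # perturbing test rows must not matter
        std2 = Standardizer.fit(train)
        np.testing.assert_array_equal(std1.mean, std2.mean)
        np.testing.assert_array_equal(std1.std, std2.std)

    def test_zero_std_raises_with_variable_name(self, split_windows):
        train, _ = split_windows
        train.X[:, :, 2] = 7.0
        with pytest.raises(ValueError, match="soil_moisture"):
            Standardizer.fit(train)

    def test_round_trip(self, split_windows):
        train, _ = split_windows
        std = Standardizer.fit(train)
        Z = std.transform(train)
        np.testing.assert_allclose(std.inverse_transform_X(Z.X), train.X, atol=1e-9)
        np.testing.assert_allclose(
            std.inverse_transform_y(std.transform_y(train.y)), train.y, atol=1e-9
        )

    def test_dict_round_trip(self, split_windows):
        train, _ = split_windows
        std = Standardizer.fit(train)
        std2 = Standardizer.from_dict(std.to_dict())
        np.testing.assert_array_equal(std.mean, std2.mean)
        assert std.y_mean == std2.y_mean


class TestMakeWindows:
    def test_window_count_per_site(self):
        panel = generate_panel(ScenarioConfig(n_sites=1, months=60, seed=35))
        ds = make_windows(panel, T=30)
        assert len(ds) == 31  # 60 - 30 + 1

    @pytest.mark.parametrize("months,T", [(12, 5), (20, 20), (7, 3)])
    def test_window_count_formula(self, months, T):
        panel = generate_panel(ScenarioConfig(n_sites=2, months=months, seed=36))
        ds = make_windows(panel, T=T)
        assert len(ds) == 2 * (months - T + 1)

    def test_benchmark_trim_to_3217(self):
        panel = generate_panel(ScenarioConfig(seed=37))
        ds = make_windows(panel, T=30, max_samples=3217)
        assert len(ds) == 3217

    def test_flat_fvc_gives_zero_target(self):
        s = make_site({"fvc": np.full(10, 0.4)})
        ds = make_windows([s], T=5)
        np.testing.assert_allclose(ds.y, 0.0, atol=1e-12)

    def test_survival_task_targets_window_end(self):
        panel = generate_panel(ScenarioConfig(n_sites=2, months=20, seed=38))
        ds = make_windows(panel, T=10, task="survival")
        s0 = [s for s in panel if s.site_id == ds.site_id[0]][0]
        end = ds.window_end[0]
        assert ds.y[0] == s0.data["survival_pct"].loc[end]

    def test_short_site_skipped_with_warning(self):
        long = generate_panel(ScenarioConfig(n_sites=1, months=20, seed=39))[0]
        short = generate_panel(ScenarioConfig(n_sites=1, months=5, seed=40))[0]
        short.site_id = "SHORT"
        with pytest.warns(UserWarning, match="SHORT"):
            ds = make_windows([long, short], T=10)
        assert len(ds) == 11

    def test_all_sites_short_raises(self):
        panel = generate_panel(ScenarioConfig(n_sites=2, months=5, seed=41))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="shorter"):
                make_windows(panel, T=10)

    def test_window_end_sorted(self):
        panel = generate_panel(ScenarioConfig(n_sites=4, months=24, seed=42))
        ds = make_windows(panel, T=6)
        assert np.all(np.diff(ds.window_end) >= 0)

    def test_missing_values_rejected(self):
        panel = generate_panel(ScenarioConfig(n_sites=1, months=20, seed=43))
        broken = inject_missingness(panel[0], 0.1, seed=0)
        with pytest.raises(ValueError, match="missing"):
            make_windows([broken], T=10)


class TestPreprocessPanel:
    def test_output_gap_free_and_windowable(self):
        panel = generate_panel(ScenarioConfig(n_sites=3, months=36, seed=44))
        panel = [inject_missingness(s, 0.15, seed=i) for i, s in enumerate(panel)]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            clean = preprocess_panel(panel)
        for s in clean:
            assert not s.data.isna().any().any()
        ds = make_windows(clean, T=12)
        assert len(ds) == 3 * 25
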