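import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fieldwater import TrialConfig, cover_fraction, interpolate_daily, standardise_ndvi
from fieldwater.errors import CalibrationError


def _obs(rows, plot="P01", instrument="greenseeker"):
    return pd.DataFrame(
        [{"plot_id": plot, "date": pd.Timestamp(d), "instrument": instrument, "ndvi_raw": v} for d, v in rows]
    )


def _calendar(plot="P01", sowing="2021-09-15", emergence="2021-10-01", harvest="2022-03-01"):
    return pd.DataFrame(
        [{"plot_id": plot, "crop": "wheat", "sowing": pd.Timestamp(sowing),
          "emergence": pd.Timestamp(emergence), "harvest": pd.Timestamp(harvest)}]
    )


class TestStandardise:
    def test_identity_calibration_returns_input(self):
        obs = _obs([("2021-10-01", 0.3), ("2021-10-15", 0.6)])
        out = standardise_ndvi(obs, {"greenseeker": (1.0, 0.0)})
        assert np.allclose(out["ndvi"], obs["ndvi_raw"])
        assert len(out) == len(obs)

    def test_linear_calibration_applied_per_instrument(self):
        obs = _obs([("2021-10-01", 0.5)])
        out = standardise_ndvi(obs, {"greenseeker": (1.1, -0.05)})
        assert out["ndvi"].iloc[0] == pytest.approx(0.50)  # 1.1*0.5 - 0.05

    def test_unknown_instrument_error_names_it(self):
        obs = _obs([("2021-10-01", 0.5)], instrument="drone")
        with pytest.raises(CalibrationError, match="drone"):
            standardise_ndvi(obs, {"greenseeker": (1.0, 0.0)})


class TestCoverFraction:
    def test_closure_threshold_maps_to_full_cover(self, config):
        assert cover_fraction(0.75, config) == 1.0

    def test_bare_baseline_maps_to_zero(self, config):
        assert cover_fraction(0.15, config) == 0.0

    def test_linear_midpoint(self, config):
        assert cover_fraction(0.45, config) == pytest.approx(0.5)  # (0.45-0.15)/0.6

    @given(st.floats(-1, 1), st.floats(-1, 1))
    @settings(deadline=None)
    def test_monotone_and_bounded(self, a, b):
        config = TrialConfig()
        fa, fb = cover_fraction(a, config), cover_fraction(b, config)
        assert 0.0 <= fa <= 1.0
        if a <= b:
            assert fa <= fb


class TestInterpolateDaily:
    dates = pd.date_range("2021-06-01", "2022-05-31", freq="D")

    def _run(self, obs, config, calendar=None):
        calendar = calendar if calendar is not None else _calendar()
        obs = standardise_ndvi(obs, None)
        return interpolate_daily(obs, calendar, config, self.dates, plot_id="P01")

    def test_linear_rise_between_emergence_and_closure(self, config):
        # cover 0 at emergence, 1 thirty days later -> 0.5 at the midpoint
        obs = _obs([("2021-10-01", 0.15), ("2021-10-31", 0.75)])
        daily = self._run(obs, config).set_index("date")["cover"]
        assert daily.loc["2021-10-16"] == pytest.approx(0.5)
        assert daily.loc["2021-10-01"] == 0.0
        assert daily.loc["2021-10-31"] == 1.0

    def test_no_observations_gives_all_zero_series(self, config):
        daily = self._run(_obs([]).reindex(columns=["plot_id", "date", "instrument", "ndvi_raw"]), config)
        assert (daily["cover"] == 0).all()
        assert len(daily) == len(self.dates)

    def test_fortnightly_segment_midpoint(self, config):
        # obs at day 10 (cover 0.4) and day 24 (cover 0.6): day 17 is 0.5
        obs = _obs([("2021-10-11", 0.15 + 0.4 * 0.6), ("2021-10-25", 0.15 + 0.6 * 0.6)])
        daily = self._run(obs, config).set_index("date")["cover"]
        assert daily.loc["2021-10-18"] == pytest.approx(0.5)

    def test_cover_zero_outside_crop_and_after_harvest(self, config):
        obs = _obs([("2021-10-15", 0.6), ("2022-01-10", 0.8)])
        daily = self._run(obs, config).set_index("date")["cover"]
        assert (daily.loc[:"2021-09-30"] == 0).all()  # fallow + pre-emergence
        assert (daily.loc["2022-03-02":] == 0).all()  # after harvest

    def test_fallow_observation_dropped_with_warning(self, config):
        obs = _obs([("2021-07-15", 0.5), ("2021-10-15", 0.6)])
        with pytest.warns(UserWarning, match="2021-07-15"):
            daily = self._run(obs, config).set_index("date")["cover"]
        assert daily.loc["2021-07-15"] == 0.0

    def test_closure_is_held_at_one_until_next_observation(self, config):
        # closure observed, then a lower (senescent) observation: hold 1
        # in between, honour the later observation exactly
        obs = _obs([("2021-10-01", 0.15), ("2021-11-01", 0.80), ("2022-01-01", 0.45)])
        daily = self._run(obs, config).set_index("date")["cover"]
        assert (daily.loc["2021-11-01":"2021-12-31"] == 1.0).all()
        assert daily.loc["2022-01-01"] == pytest.approx(0.5)

    def test_passes_through_every_retained_observation(self, config):
        obs = _obs([("2021-10-05", 0.3), ("2021-11-02", 0.5), ("2021-12-14", 0.7), ("2022-02-01", 0.6)])
        std = standardise_ndvi(obs, None)
        daily = self._run(obs, config).set_index("date")["cover"]
        for _, row in std.iterrows():
            assert daily.loc[row["date"]] == pytest.approx(cover_fraction(row["ndvi"], config))

    def test_monotone_rise_for_monotone_observations(self, config):
        obs = _obs([("2021-10-01", 0.2), ("2021-10-15", 0.4), ("2021-10-29", 0.6), ("2021-11-12", 0.75)])
        daily = self._run(obs, config).set_index("date")["cover"]
        rise = daily.loc["2021-10-01":"2021-11-12"]
        assert (rise.diff().dropna() >= -1e-12).all()
        assert (daily >= 0).all() and (daily <= 1).all()
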