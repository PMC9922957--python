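import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import naive_balance, random_forcings
from fieldwater import DailyForcing, FieldCapacity, TrialConfig, apply_reset, run_balance, step
from fieldwater.balance import FROM_FIRST_OBSERVATION
from fieldwater.errors import InitializationError

FC = FieldCapacity(plot_id="P01", fc_mm=180.0, n_obs=3)


def _forcing(date="2021-01-01", rain=0.0, pet=0.0, irrigation=0.0, cover=1.0, observed=None):
    return DailyForcing(
        date=pd.Timestamp(date), rain_mm=rain, pet_mm=pet,
        irrigation_mm=irrigation, cover=cover, observed_storage_mm=observed,
    )


class TestStep:
    def test_drying_day_accumulates_deficit(self, config):
        smd, aet, drainage = step(10.0, _forcing(pet=5.0), config)
        assert (smd, aet, drainage) == (15.0, 5.0, 0.0)

    def test_saturated_bucket_passes_all_surplus_as_drainage(self, config):
        smd, aet, drainage = step(0.0, _forcing(rain=20.0), config)
        assert (smd, aet, drainage) == (0.0, 0.0, 20.0)

    def test_mixed_inputs_partition_into_deficit_and_drainage(self, config):
        # 5 + 1 - 3 - 4 = -1: deficit erased, 1 mm drains
        smd, aet, drainage = step(5.0, _forcing(rain=3.0, irrigation=4.0, pet=2.0, cover=0.5), config)
        assert aet == pytest.approx(1.0)
        assert smd == 0.0
        assert drainage == pytest.approx(1.0)

    def test_zero_cover_means_zero_aet(self, config):
        _, aet, _ = step(10.0, _forcing(pet=6.0, cover=0.0), config)
        assert aet == 0.0

    def test_linear_stress_reduces_aet_when_dry(self):
        config = TrialConfig(stress_model="linear", taw_mm=100.0, raw_mm=50.0)
        _, aet_wet, _ = step(30.0, _forcing(pet=4.0), config)   # below RAW: unrestricted
        _, aet_mid, _ = step(75.0, _forcing(pet=4.0), config)   # halfway RAW->TAW
        _, aet_dry, _ = step(120.0, _forcing(pet=4.0), config)  # beyond TAW: none
        assert aet_wet == pytest.approx(4.0)
        assert aet_mid == pytest.approx(2.0)
        assert aet_dry == 0.0


class TestApplyReset:
    def test_reset_to_observed_deficit(self):
        smd, residual = apply_reset(35.0, 160.0, FC)
        assert smd == pytest.approx(20.0)  # 180 - 160
        assert residual == pytest.approx(15.0)

    def test_observation_at_field_capacity_resets_to_zero(self):
        smd, _ = apply_reset(12.0, 180.0, FC)
        assert smd == 0.0

    def test_supersaturated_observation_clamps_to_zero(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="fieldwater.balance"):
            smd, residual = apply_reset(5.0, 190.0, FC)
        assert smd == 0.0
        assert residual == 5.0
        assert "supersaturation" in caplog.text


class TestRunBalance:
    def test_constant_drying_accumulates_cumulatively(self, config):
        forcings = [_forcing(date=d, pet=4.0) for d in pd.date_range("2021-01-01", periods=5)]
        traj = run_balance(forcings, FC, config, smd_init=0.0)
        assert np.allclose(traj["smd_mm"], [4, 8, 12, 16, 20])
        assert not traj["reset"].any()

    def test_observation_day_resets_regardless_of_model_state(self, config):
        forcings = [_forcing(date=d, pet=4.0) for d in pd.date_range("2021-01-01", periods=5)]
        forcings[2] = _forcing(date="2021-01-03", pet=4.0, observed=FC.fc_mm - 7.0)
        traj = run_balance(forcings, FC, config, smd_init=0.0)
        assert traj["smd_mm"].iloc[2] == pytest.approx(7.0)
        assert traj["reset"].iloc[2]
        assert traj["reset_residual_mm"].iloc[2] == pytest.approx(12.0 - 7.0)
        # subsequent days continue from the corrected state
        assert traj["smd_mm"].iloc[3] == pytest.approx(11.0)

    def test_init_from_first_observation_requires_one(self, config):
        forcings = [_forcing(date="2021-01-01", pet=2.0)]
        with pytest.raises(InitializationError, match="observation"):
            run_balance(forcings, FC, config, smd_init=FROM_FIRST_OBSERVATION)

    def test_non_contiguous_forcings_are_refused(self, config):
        forcings = [_forcing(date="2021-01-01"), _forcing(date="2021-01-03")]
        with pytest.raises(InitializationError, match="contiguous"):
            run_balance(forcings, FC, config, smd_init=0.0)

    def test_zero_cover_and_no_water_leaves_smd_constant(self, config):
        forcings = [_forcing(date=d, pet=5.0, cover=0.0) for d in pd.date_range("2021-01-01", periods=30)]
        traj = run_balance(forcings, FC, config, smd_init=25.0)
        assert (traj["smd_mm"] == 25.0).all()
        assert (traj["drainage_mm"] == 0.0).all()
        assert (traj["aet_mm"] == 0.0).all()

    def test_matches_naive_reference_on_random_fixtures(self, config):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            forcings = random_forcings(rng, 365)
            traj = run_balance(forcings, FC, config, smd_init=10.0)
            ref = naive_balance(forcings, FC.fc_mm, config, smd_init=10.0)
            assert np.array_equal(traj["smd_mm"].to_numpy(), ref["smd_mm"].to_numpy())
            assert np.array_equal(traj["drainage_mm"].to_numpy(), ref["drainage_mm"].to_numpy())
            assert np.array_equal(traj["aet_mm"].to_numpy(), ref["aet_mm"].to_numpy())


class TestProperties:
    @given(
        st.floats(0, 50), st.floats(0, 40), st.floats(0, 8),
        st.floats(0, 30), st.floats(0, 1),
    )
    @settings(deadline=None)
    def test_step_mass_balance_and_bounds(self, smd_prev, rain, pet, irrigation, cover):
        config = TrialConfig()
        forcing = _forcing(rain=rain, pet=pet, irrigation=irrigation, cover=cover)
        smd, aet, drainage = step(smd_prev, forcing, config)
        assert smd >= 0 and drainage >= 0
        assert aet <= pet + 1e-12
        assert (smd - smd_prev) == pytest.approx(aet - rain - irrigation + drainage, abs=1e-9)
        if drainage > 0:
            assert smd == 0.0

    @given(
        st.floats(0, 50), st.floats(0, 40), st.floats(0.1, 30),
        st.floats(0, 8), st.floats(0, 1),
    )
    @settings(deadline=None)
    def test_more_rain_never_dries_the_soil(self, smd_prev, rain, extra, pet, cover):
        config = TrialConfig()
        base = step(smd_prev, _forcing(rain=rain, pet=pet, cover=cover), config)
        wetter = step(smd_prev, _forcing(rain=rain + extra, pet=pet, cover=cover), config)
        assert wetter[0] <= base[0] + 1e-12   # smd_next never increases
        assert wetter[2] >= base[2] - 1e-12   # drainage never decreases
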