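import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fieldwater import TrialConfig, generate_trial, run_pipeline

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def config():
    return TrialConfig()


@pytest.fixture(scope="session")
def zero_noise_trial(config):
    """Two-plot, two-year trial with noise-free observations, plus its
    pipeline reconstruction — the closure fixture."""
    bundle, truth = generate_trial(n_plots=2, seed=11, config=config, ndvi_sd=0.0, theta_sd=0.0)
    result = run_pipeline(bundle, config)
    return bundle, truth, result


@pytest.fixture(scope="session")
def noisy_trial(config):
    """Three-plot trial at the default observation-noise levels."""
    bundle, truth = generate_trial(n_plots=3, seed=7, config=config)
    result = run_pipeline(bundle, config)
    return bundle, truth, result


def assert_mass_balance(trajectory: pd.DataFrame, forcings: pd.DataFrame, tol=1e-9):
    """Check dSMD = AET - Rain - Irrigation + Drainage on every non-reset step."""
    merged = trajectory.merge(
        forcings[["date", "rain_mm", "irrigation_mm"]], on="date", how="left"
    )
    smd = merged["smd_mm"].to_numpy()
    prev = np.concatenate([[np.nan], smd[:-1]])
    lhs = smd - prev
    rhs = (
        merged["aet_mm"].to_numpy()
        - merged["rain_mm"].to_numpy()
        - merged["irrigation_mm"].to_numpy()
        + merged["drainage_mm"].to_numpy()
    )
    nonreset = ~merged["reset"].to_numpy(dtype=bool)
    nonreset[0] = False  # no previous state on the first day
    assert np.all(np.abs(lhs[nonreset] - rhs[nonreset]) <= tol)
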