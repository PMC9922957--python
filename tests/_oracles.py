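"""Independent reference implementations used only to cross-check the package.

These are deliberately naive: step-by-step water accounting written from the
model definition with explicit branches, and drainage segmentation by
clustering the positions of draining days.  They share no code with the
implementations they check.
"""

import numpy as np
import pandas as pd

from fieldwater import DailyForcing, TrialConfig


def naive_balance(forcings, fc_mm, config: TrialConfig, smd_init: float):
    """One-day-at-a-time deficit accounting, branch by branch."""
    smd = smd_init
    rows = []
    for f in forcings:
        demand = f.pet_mm * f.cover
        if config.stress_model == "linear":
            if smd <= config.raw_mm:
                factor = 1.0
            elif smd >= config.taw_mm:
                factor = 0.0
            else:
                factor = (config.taw_mm - smd) / (config.taw_mm - config.raw_mm)
            demand = demand * factor
        water_in = f.rain_mm + f.irrigation_mm
        smd = smd + demand
        if water_in >= smd:
            drainage = water_in - smd
            smd = 0.0
        else:
            smd = smd - water_in
            drainage = 0.0
        reset = False
        residual = np.nan
        if f.observed_storage_mm is not None:
            target = fc_mm - f.observed_storage_mm
            if target < 0.0:
                target = 0.0
            residual = smd - target
            smd = target
            reset = True
        rows.append((f.date, smd, demand, drainage, reset, residual))
    return pd.DataFrame(
        rows, columns=["date", "smd_mm", "aet_mm", "drainage_mm", "reset", "reset_residual_mm"]
    )


def brute_segment(values, min_total, merge_gap):
    """Event segmentation by clustering positive-day positions."""
    positions = [i for i, v in enumerate(values) if v > 0]
    clusters = []
    for pos in positions:
        if clusters and pos - clusters[-1][-1] - 1 <= merge_gap:
            clusters[-1].append(pos)
        else:
            clusters.append([pos])
    out = []
    for cluster in clusters:
        total = sum(values[i] for i in cluster)
        if total >= min_total:
            peak = max(values[i] for i in cluster)
            out.append((cluster[0], cluster[-1], total, peak))
    return out


def random_forcings(rng, n_days, with_observations=True, start="2021-01-01"):
    """A random but valid forcing sequence for oracle-equivalence checks."""
    dates = pd.date_range(start, periods=n_days, freq="D")
    rain = np.where(rng.random(n_days) < 0.35, rng.gamma(0.7, 8.0, n_days), 0.0)
    pet = rng.uniform(0.0, 7.0, n_days)
    irrigation = np.where(rng.random(n_days) < 0.05, rng.uniform(5.0, 30.0, n_days), 0.0)
    cover = np.clip(rng.random(n_days), 0.0, 1.0)
    observed = np.full(n_days, np.nan)
    if with_observations:
        for i in np.flatnonzero(rng.random(n_days) < 0.1):
            observed[i] = rng.uniform(100.0, 200.0)
    return [
        DailyForcing(
            date=dates[i],
            rain_mm=float(rain[i]),
            pet_mm=float(pet[i]),
            irrigation_mm=float(irrigation[i]),
            cover=float(cover[i]),
            observed_storage_mm=None if np.isnan(observed[i]) else float(observed[i]),
        )
        for i in range(n_days)
    ]
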