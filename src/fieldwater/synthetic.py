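"""Synthetic field trials with known ground truth.

The study data this pipeline was designed around cannot be redistributed, so
this module manufactures complete trials — weather, crop calendar, true
canopy and soil-water trajectories — and then degrades them into the sparse,
noisy observation tables a field team would actually produce.  Because the
truth is built by running the same forward bucket model the pipeline later
inverts, a zero-noise trial is a closure test: the full pipeline must
recover the true field capacity exactly and the deficit/drainage
trajectories to numerical precision.

What it emulates: a southern-hemisphere irrigated annual-crop trial.  PET
follows a seasonal sinusoid with its minimum in June-August; rain is a
Bernoulli-occurrence x gamma-amount process; one crop per year is sown in
September, reaches canopy closure 8 weeks after emergence, and is harvested
in early March; irrigation is triggered in the cropped season when the
deficit exceeds a trigger depth; NDVI is observed fortnightly during the
season and the neutron probe fortnightly year-round, starting on the trial
start date (1 June, when the profile is at field capacity).

The observation grid is aligned with the true cover curve's knots
(emergence and closure fall on probe/NDVI dates) so that the canopy
module's piecewise-linear interpolation is an exact inverse at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import balance as wb
from .config import TrialConfig
from .io import InputBundle, write_bundle

#: Days from emergence to full canopy closure (8 fortnights-aligned weeks).
CLOSURE_DAYS = 56

#: Irrigation policy: apply this depth when the deficit exceeds the trigger.
IRRIGATION_TRIGGER_MM = 30.0
IRRIGATION_DEPTH_MM = 25.0


@dataclass(frozen=True)
class ClimateParams:
    """Stochastic climate: daily rain occurrence x gamma amounts, seasonal PET.

    Defaults approximate an east-coast New Zealand cropping site: ~660 mm/yr
    rain, PET ~0.5 mm/d midwinter to ~4.5 mm/d midsummer.
    """

    rain_prob: float = 0.3
    rain_mean_mm: float = 6.0
    rain_shape: float = 0.7
    pet_mean_mm: float = 2.5
    pet_amplitude_mm: float = 2.0
    pet_peak_doy: int = 15  # mid-January: southern-hemisphere summer


@dataclass
class SyntheticTruth:
    """Ground truth of a generated trial, for assertions only."""

    cover: pd.DataFrame  # plot_id, date, cover
    balance: pd.DataFrame  # plot_id, date, smd_mm, aet_mm, drainage_mm
    fc_mm: Dict[str, float]
    ndvi_sd: float
    theta_sd: float


def generate_weather(
    start,
    end,
    seed: int,
    climate: ClimateParams = ClimateParams(),
) -> pd.DataFrame:
    """Contiguous daily weather between start and end (inclusive).

    PET is a deterministic sinusoid of day-of-year peaking in midsummer
    (so June-August PET is minimal); rain on each day is an independent
    Bernoulli(rain_prob) draw of a Gamma(rain_shape) amount with the given
    mean.  Identical (seed, parameters) give identical series.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start >= end:
        raise ValueError("start must be before end")
    dates = pd.date_range(start, end, freq="D")
    rng = np.random.default_rng(seed)
    doy = dates.dayofyear.to_numpy()
    pet = climate.pet_mean_mm + climate.pet_amplitude_mm * np.cos(
        2 * np.pi * (doy - climate.pet_peak_doy) / 365.25
    )
    pet = np.clip(pet, 0.0, None)
    wet = rng.random(len(dates)) < climate.rain_prob
    scale = climate.rain_mean_mm / climate.rain_shape
    amounts = rng.gamma(climate.rain_shape, scale, size=len(dates))
    rain = np.where(wet, amounts, 0.0)
    return pd.DataFrame({"date": dates, "rain_mm": rain, "pet_mm": pet})


def _crop_seasons(start: pd.Timestamp, end: pd.Timestamp) -> list:
    """September-sown seasons fully contained in [start, end].

    Emergence is a fortnight after sowing and closure CLOSURE_DAYS after
    emergence, so both land on the fortnightly observation grid anchored at
    emergence.
    """
    seasons = []
    for year in range(start.year - 1, end.year + 1):
        sowing = pd.Timestamp(year=year, month=9, day=15)
        emergence = sowing + pd.Timedelta(days=14)
        harvest = pd.Timestamp(year=year + 1, month=3, day=1)
        if sowing >= start and harvest <= end:
            seasons.append({"sowing": sowing, "emergence": emergence, "harvest": harvest})
    return seasons


def _true_cover(dates: pd.DatetimeIndex, seasons: list) -> np.ndarray:
    cover = np.zeros(len(dates))
    for season in seasons:
        emergence, harvest = season["emergence"], season["harvest"]
        closure = emergence + pd.Timedelta(days=CLOSURE_DAYS)
        days_since = (dates - emergence).days.to_numpy()
        in_season = (dates >= emergence) & (dates <= harvest)
        ramp = np.clip(days_since / CLOSURE_DAYS, 0.0, 1.0)
        cover = np.where(in_season, ramp, cover)
    return cover


def generate_trial(
    n_plots: int,
    seed: int,
    config: TrialConfig = TrialConfig(),
    climate: ClimateParams = ClimateParams(),
    start="2020-06-01",
    end="2022-05-31",
    ndvi_sd: float = 0.03,
    theta_sd: float = 0.01,
    n_layers: int = 3,
    fc_fraction_range=(0.28, 0.32),
):
    """Generate a complete synthetic trial and its ground truth.

    Returns ``(bundle, truth)``: the five observation tables as an
    :class:`~fieldwater.io.InputBundle` and the :class:`SyntheticTruth`
    they were sampled from.  ``ndvi_sd`` and ``theta_sd`` are the Gaussian
    observation-noise scales (0 gives exact closure); probe noise is drawn
    per layer so profile aggregation genuinely averages.
    """
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    rng = np.random.default_rng(seed)

    weather = generate_weather(start, end, seed=int(rng.integers(0, 2**31 - 1)), climate=climate)
    dates = pd.DatetimeIndex(weather["date"])
    rain = weather["rain_mm"].to_numpy()
    pet = weather["pet_mm"].to_numpy()

    seasons = _crop_seasons(start, end)
    depth_mm = config.profile_depth_cm * 10.0
    crops = ["ryegrass", "wheat", "barley", "peas", "potato", "onion"]

    calendar_rows = []
    cover_frames = []
    balance_frames = []
    irrigation_rows = []
    ndvi_rows = []
    probe_rows = []
    fc_true: Dict[str, float] = {}

    ndvi_span = config.ndvi_closure - config.ndvi_bare
    layer_edges = np.linspace(0.0, config.profile_depth_cm, n_layers + 1)

    for p in range(n_plots):
        plot = f"P{p + 1:02d}"
        fc = float(depth_mm * rng.uniform(*fc_fraction_range))
        fc_true[plot] = fc
        for si, season in enumerate(seasons):
            calendar_rows.append(
                {
                    "plot_id": plot,
                    "crop": crops[si % len(crops)],
                    "sowing": season["sowing"],
                    "emergence": season["emergence"],
                    "harvest": season["harvest"],
                }
            )
        if not seasons:
            # degenerate short trial: an all-fallow calendar entry is invalid,
            # so require at least one season
            raise ValueError("trial period too short to contain one crop season")

        cover = _true_cover(dates, seasons)

        # forward model: deficit starts at 0 (field capacity at winter start);
        # the irrigation policy waters cropped days once the deficit passes
        # the trigger, using the previous day's state (decided before the day)
        smd = 0.0
        smd_arr = np.empty(len(dates))
        aet_arr = np.empty(len(dates))
        drain_arr = np.empty(len(dates))
        irr_arr = np.zeros(len(dates))
        for i in range(len(dates)):
            irr = 0.0
            if cover[i] > 0 and smd > IRRIGATION_TRIGGER_MM:
                irr = IRRIGATION_DEPTH_MM
                irr_arr[i] = irr
            forcing = wb.DailyForcing(
                date=dates[i],
                rain_mm=float(rain[i]),
                pet_mm=float(pet[i]),
                irrigation_mm=irr,
                cover=float(cover[i]),
            )
            smd, aet, drainage = wb.step(smd, forcing, config)
            smd_arr[i] = smd
            aet_arr[i] = aet
            drain_arr[i] = drainage

        cover_frames.append(pd.DataFrame({"plot_id": plot, "date": dates, "cover": cover}))
        balance_frames.append(
            pd.DataFrame(
                {
                    "plot_id": plot,
                    "date": dates,
                    "smd_mm": smd_arr,
                    "aet_mm": aet_arr,
                    "drainage_mm": drain_arr,
                }
            )
        )
        for i in np.nonzero(irr_arr)[0]:
            irrigation_rows.append(
                {"plot_id": plot, "date": dates[i], "amount_mm": float(irr_arr[i])}
            )

        # NDVI observations: fortnightly from emergence to harvest, via the
        # inverse cover map plus noise; instruments alternate to exercise
        # multi-instrument standardisation (identity calibration)
        for season in seasons:
            obs_date = season["emergence"]
            k = 0
            while obs_date <= season["harvest"]:
                idx = dates.get_loc(obs_date)
                ndvi = config.ndvi_bare + cover[idx] * ndvi_span
                if ndvi_sd > 0:
                    ndvi += rng.normal(0.0, ndvi_sd)
                ndvi_rows.append(
                    {
                        "plot_id": plot,
                        "date": obs_date,
                        "instrument": "greenseeker" if k % 2 == 0 else "handheld",
                        "ndvi_raw": float(np.clip(ndvi, -1.0, 1.0)),
                    }
                )
                obs_date += pd.Timedelta(days=14)
                k += 1

        # probe readings: fortnightly from the trial start (day 0 is 1 June
        # at field capacity, guaranteeing a winter reading with zero deficit,
        # which makes FC recoverable exactly at zero noise); per-layer noise
        obs_date = start
        while obs_date <= end:
            idx = dates.get_loc(obs_date)
            storage = fc - smd_arr[idx]
            theta_mean = storage / depth_mm
            for j in range(n_layers):
                theta = theta_mean
                if theta_sd > 0:
                    theta += rng.normal(0.0, theta_sd)
                probe_rows.append(
                    {
                        "plot_id": plot,
                        "date": obs_date,
                        "depth_top_cm": float(layer_edges[j]),
                        "depth_bottom_cm": float(layer_edges[j + 1]),
                        "theta": float(np.clip(theta, 0.0, 0.7)),
                    }
                )
            obs_date += pd.Timedelta(days=14)

    bundle = InputBundle(
        weather=weather,
        canopy_obs=pd.DataFrame(ndvi_rows, columns=["plot_id", "date", "instrument", "ndvi_raw"]),
        probe=pd.DataFrame(
            probe_rows, columns=["plot_id", "date", "depth_top_cm", "depth_bottom_cm", "theta"]
        ),
        irrigation=pd.DataFrame(irrigation_rows, columns=["plot_id", "date", "amount_mm"]),
        calendar=pd.DataFrame(
            calendar_rows, columns=["plot_id", "crop", "sowing", "emergence", "harvest"]
        ),
    )
    truth = SyntheticTruth(
        cover=pd.concat(cover_frames, ignore_index=True),
        balance=pd.concat(balance_frames, ignore_index=True),
        fc_mm=fc_true,
        ndvi_sd=ndvi_sd,
        theta_sd=theta_sd,
    )
    return bundle, truth


def generate_trial_files(directory, n_plots: int, seed: int, config: TrialConfig = TrialConfig(), **kwargs):
    """Generate a trial and write the five input CSVs plus ``truth.csv``.

    The truth file exists for test assertions only; the pipeline itself
    never reads it.  Returns (path map, truth).
    """
    bundle, truth = generate_trial(n_plots=n_plots, seed=seed, config=config, **kwargs)
    paths = write_bundle(bundle, directory)
    truth_df = truth.balance.merge(truth.cover, on=["plot_id", "date"])
    truth_df["fc_mm"] = truth_df["plot_id"].map(truth.fc_mm)
    out = truth_df.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    truth_path = Path(directory) / "truth.csv"
    out.to_csv(truth_path, index=False, float_format="%.12g")
    paths["truth"] = str(truth_path)
    return paths, truth
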