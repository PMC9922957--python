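"""End-to-end glue: validated tables -> trajectories, events, exports.

This is the library-level composition of the domain modules; the
orchestrator wraps the same steps as cached file-to-file stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd

from .balance import FROM_FIRST_OBSERVATION, run_balance
from .canopy import interpolate_all_plots, standardise_ndvi
from .config import TrialConfig
from .errors import InitializationError
from .events import DrainageEvent, detect_events, events_to_frame
from .io import InputBundle, export_long_table, is_crop_active
from .soil import FieldCapacity, estimate_field_capacity, storage_table


@dataclass
class PipelineResult:
    canopy_daily: pd.DataFrame
    storages: pd.DataFrame
    field_capacity: Dict[str, FieldCapacity]
    trajectories: pd.DataFrame  # all plots concatenated
    events: List[DrainageEvent]


def build_forcings(
    weather: pd.DataFrame,
    irrigation: pd.DataFrame,
    canopy_daily: pd.DataFrame,
    storages: pd.DataFrame,
    plot_id: str,
) -> pd.DataFrame:
    """Assemble the daily forcing frame for one plot over the weather period,
    sliced to start at the plot's first storage observation (the balance
    refuses to run blind before it can be anchored)."""
    plot_id = str(plot_id)
    df = weather[["date", "rain_mm", "pet_mm"]].copy()
    irr = irrigation[irrigation["plot_id"] == plot_id][["date", "amount_mm"]]
    df = df.merge(irr.rename(columns={"amount_mm": "irrigation_mm"}), on="date", how="left")
    df["irrigation_mm"] = df["irrigation_mm"].fillna(0.0)
    cov = canopy_daily[canopy_daily["plot_id"] == plot_id][["date", "cover"]]
    df = df.merge(cov, on="date", how="left")
    df["cover"] = df["cover"].fillna(0.0)
    sto = storages[storages["plot_id"] == plot_id][["date", "storage_mm"]]
    df = df.merge(sto.rename(columns={"storage_mm": "observed_storage_mm"}), on="date", how="left")
    observed = df["observed_storage_mm"].notna()
    if not observed.any():
        raise InitializationError(f"plot {plot_id}: no storage observation to anchor the balance")
    first = int(np.flatnonzero(observed.to_numpy())[0])
    return df.iloc[first:].reset_index(drop=True)


def fallow_storages(
    storages: pd.DataFrame, calendar: pd.DataFrame, plot_id: str
) -> pd.DataFrame:
    """Storage observations of one plot taken while no crop was standing."""
    plot_id = str(plot_id)
    sto = storages[storages["plot_id"] == plot_id].reset_index(drop=True)
    active = is_crop_active(calendar, plot_id, pd.DatetimeIndex(sto["date"]))
    return sto[~active].reset_index(drop=True)


def run_pipeline(bundle: InputBundle, config: TrialConfig, instrument_offsets=None) -> PipelineResult:
    """Run every transformation stage in dependency order."""
    dates = pd.DatetimeIndex(bundle.weather["date"])
    standardised = standardise_ndvi(bundle.canopy_obs, instrument_offsets)
    canopy_daily = interpolate_all_plots(standardised, bundle.calendar, config, dates)
    storages = storage_table(bundle.probe, config)

    plots = sorted(bundle.calendar["plot_id"].unique())
    fcs: Dict[str, FieldCapacity] = {}
    trajectories = []
    events: List[DrainageEvent] = []
    for plot in plots:
        winter = fallow_storages(storages, bundle.calendar, plot)
        fcs[plot] = estimate_field_capacity(winter, config)
        forcings = build_forcings(bundle.weather, bundle.irrigation, canopy_daily, storages, plot)
        traj = run_balance(forcings, fcs[plot], config, smd_init=FROM_FIRST_OBSERVATION)
        trajectories.append(traj)
        events.extend(detect_events(traj, config))

    return PipelineResult(
        canopy_daily=canopy_daily,
        storages=storages,
        field_capacity=fcs,
        trajectories=pd.concat(trajectories, ignore_index=True),
        events=events,
    )


def export_results(result: PipelineResult, out_path) -> int:
    """Write the merged long-format results table; returns rows written."""
    return export_long_table(result.trajectories, result.canopy_daily, out_path)


def events_table(result: PipelineResult) -> pd.DataFrame:
    return events_to_frame(result.events)
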