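"""Input-table readers, validation, and long-format export.

Column contract (all files CSV, RFC 4180, header row, ISO-8601 dates; any
other date format is rejected rather than coerced — silent coercion is how
field-data mishaps slip through):

``weather.csv``     date, rain_mm, pet_mm
``ndvi.csv``        plot_id, date, instrument, ndvi_raw
``probe.csv``       plot_id, date, depth_top_cm, depth_bottom_cm, theta
``irrigation.csv``  plot_id, date, amount_mm
``calendar.csv``    plot_id, crop, sowing, emergence, harvest

The crop calendar lists one row per crop season.  Days outside every
[sowing, harvest] window are fallow for that plot; this complement
representation makes "fallow intervals do not overlap crop intervals" true
by construction.

Validation is total: every contract violation raises a typed error from
:mod:`fieldwater.errors`; nothing is silently dropped or coerced, with one
documented exception — multiple irrigation records for one plot and day are
summed, because applied depths are physically additive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import TrialConfig
from .errors import (
    RowInvariantError,
    SchemaError,
    UnknownPlotError,
    WeatherGapError,
)

THETA_MAX = 0.7  # porosity bound on volumetric water content

WEATHER_COLUMNS = ("date", "rain_mm", "pet_mm")
NDVI_COLUMNS = ("plot_id", "date", "instrument", "ndvi_raw")
PROBE_COLUMNS = ("plot_id", "date", "depth_top_cm", "depth_bottom_cm", "theta")
IRRIGATION_COLUMNS = ("plot_id", "date", "amount_mm")
CALENDAR_COLUMNS = ("plot_id", "crop", "sowing", "emergence", "harvest")


@dataclass
class InputBundle:
    """The five validated input tables of one trial."""

    weather: pd.DataFrame
    canopy_obs: pd.DataFrame
    probe: pd.DataFrame
    irrigation: pd.DataFrame
    calendar: pd.DataFrame


def _read_csv(path, columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    return df


def _parse_dates(df: pd.DataFrame, column: str, origin: str) -> pd.Series:
    try:
        return pd.to_datetime(df[column], format="%Y-%m-%d")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{origin}: column '{column}' must hold ISO-8601 dates (YYYY-MM-DD): {exc}") from exc


def _parse_floats(df: pd.DataFrame, column: str, origin: str) -> pd.Series:
    raw = df[column]
    if (raw.str.strip() == "").any():
        raise SchemaError(f"{origin}: column '{column}' has empty values")
    try:
        return raw.astype(float)
    except ValueError as exc:
        raise SchemaError(f"{origin}: column '{column}' must be numeric: {exc}") from exc


def read_weather(path) -> pd.DataFrame:
    """Read and validate the daily weather forcing.

    The series must be strictly increasing and contiguous: the water balance
    steps once per calendar day and cannot bridge a missing day.  A missing
    PET value on any day (including rain-present days) is a hard error.
    """
    df = _read_csv(path, WEATHER_COLUMNS)
    origin = Path(path).name
    out = pd.DataFrame(
        {
            "date": _parse_dates(df, "date", origin),
            "rain_mm": _parse_floats(df, "rain_mm", origin),
            "pet_mm": _parse_floats(df, "pet_mm", origin),
        }
    )
    if out.empty:
        raise SchemaError(f"{origin}: weather table is empty")
    if not out["date"].is_monotonic_increasing or out["date"].duplicated().any():
        raise RowInvariantError(f"{origin}: dates must be strictly increasing")
    full = pd.date_range(out["date"].iloc[0], out["date"].iloc[-1], freq="D")
    if len(full) != len(out):
        missing = full.difference(pd.DatetimeIndex(out["date"]))
        raise WeatherGapError(missing)
    if (out[["rain_mm", "pet_mm"]] < 0).any().any():
        bad = out[(out["rain_mm"] < 0) | (out["pet_mm"] < 0)]["date"].iloc[0]
        raise RowInvariantError(f"{origin}: negative rain/PET on {bad.date()}")
    return out


def read_canopy_obs(path) -> pd.DataFrame:
    df = _read_csv(path, NDVI_COLUMNS)
    origin = Path(path).name
    out = pd.DataFrame(
        {
            "plot_id": df["plot_id"].astype(str),
            "date": _parse_dates(df, "date", origin),
            "instrument": df["instrument"].astype(str),
            "ndvi_raw": _parse_floats(df, "ndvi_raw", origin),
        }
    )
    bad = out[(out["ndvi_raw"] < -1) | (out["ndvi_raw"] > 1)]
    if not bad.empty:
        row = bad.iloc[0]
        raise RowInvariantError(
            f"{origin}: ndvi_raw outside [-1, 1] for plot {row['plot_id']} on {row['date'].date()}"
        )
    return out


def read_probe(path) -> pd.DataFrame:
    """Read layered neutron-probe readings; layers per plot/date must not overlap."""
    df = _read_csv(path, PROBE_COLUMNS)
    origin = Path(path).name
    out = pd.DataFrame(
        {
            "plot_id": df["plot_id"].astype(str),
            "date": _parse_dates(df, "date", origin),
            "depth_top_cm": _parse_floats(df, "depth_top_cm", origin),
            "depth_bottom_cm": _parse_floats(df, "depth_bottom_cm", origin),
            "theta": _parse_floats(df, "theta", origin),
        }
    )
    bad = out[out["depth_top_cm"] >= out["depth_bottom_cm"]]
    if not bad.empty:
        row = bad.iloc[0]
        raise RowInvariantError(
            f"{origin}: depth_top_cm ({row['depth_top_cm']:g}) must be < depth_bottom_cm "
            f"({row['depth_bottom_cm']:g}) for plot {row['plot_id']} on {row['date'].date()}"
        )
    bad = out[(out["theta"] < 0) | (out["theta"] > THETA_MAX)]
    if not bad.empty:
        row = bad.iloc[0]
        raise RowInvariantError(
            f"{origin}: theta {row['theta']:g} outside [0, {THETA_MAX}] for plot "
            f"{row['plot_id']} on {row['date'].date()}"
        )
    for (plot, date), grp in out.groupby(["plot_id", "date"], sort=False):
        layers = grp.sort_values("depth_top_cm")
        tops = layers["depth_top_cm"].to_numpy()
        bottoms = layers["depth_bottom_cm"].to_numpy()
        if (tops[1:] < bottoms[:-1] - 1e-9).any():
            raise RowInvariantError(f"{origin}: overlapping layers for plot {plot} on {date.date()}")
    return out


def read_irrigation(path) -> pd.DataFrame:
    """Read irrigation applications; duplicates per plot/date are summed."""
    df = _read_csv(path, IRRIGATION_COLUMNS)
    origin = Path(path).name
    out = pd.DataFrame(
        {
            "plot_id": df["plot_id"].astype(str),
            "date": _parse_dates(df, "date", origin),
            "amount_mm": _parse_floats(df, "amount_mm", origin),
        }
    )
    if (out["amount_mm"] < 0).any():
        raise RowInvariantError(f"{origin}: negative irrigation amount")
    out = out.groupby(["plot_id", "date"], as_index=False)["amount_mm"].sum()
    return out.sort_values(["plot_id", "date"]).reset_index(drop=True)


def read_calendar(path) -> pd.DataFrame:
    df = _read_csv(path, CALENDAR_COLUMNS)
    origin = Path(path).name
    out = pd.DataFrame(
        {
            "plot_id": df["plot_id"].astype(str),
            "crop": df["crop"].astype(str),
            "sowing": _parse_dates(df, "sowing", origin),
            "emergence": _parse_dates(df, "emergence", origin),
            "harvest": _parse_dates(df, "harvest", origin),
        }
    )
    bad = out[~((out["sowing"] <= out["emergence"]) & (out["emergence"] < out["harvest"]))]
    if not bad.empty:
        row = bad.iloc[0]
        raise RowInvariantError(
            f"{origin}: require sowing <= emergence < harvest for plot {row['plot_id']} crop {row['crop']}"
        )
    for plot, grp in out.groupby("plot_id", sort=False):
        g = grp.sort_values("sowing")
        if (g["sowing"].to_numpy()[1:] <= g["harvest"].to_numpy()[:-1]).any():
            raise RowInvariantError(f"{origin}: overlapping crop windows for plot {plot}")
    return out.sort_values(["plot_id", "sowing"]).reset_index(drop=True)


def crop_windows(calendar: pd.DataFrame, plot_id: str) -> pd.DataFrame:
    """The crop seasons of one plot, ordered by sowing date."""
    win = calendar[calendar["plot_id"] == str(plot_id)]
    return win.sort_values("sowing").reset_index(drop=True)


def is_crop_active(calendar: pd.DataFrame, plot_id: str, dates: pd.DatetimeIndex) -> np.ndarray:
    """Boolean mask: a crop window [sowing, harvest] covers the date.

    The complement of this mask is the plot's fallow period.
    """
    mask = np.zeros(len(dates), dtype=bool)
    for _, row in crop_windows(calendar, plot_id).iterrows():
        mask |= (dates >= row["sowing"]) & (dates <= row["harvest"])
    return mask


def read_input_tables(paths: Mapping[str, str], config: TrialConfig) -> InputBundle:
    """Read and cross-validate the five trial tables.

    ``paths`` maps the keys ``weather``, ``ndvi``, ``probe``, ``irrigation``,
    ``calendar`` to file locations.  Beyond the per-table invariants, every
    plot referenced in an observation table must appear in the calendar, and
    all observation dates must fall inside the weather period.
    """
    required = {"weather", "ndvi", "probe", "irrigation", "calendar"}
    missing = required - set(paths)
    if missing:
        raise SchemaError(f"missing input paths: {sorted(missing)}")
    bundle = InputBundle(
        weather=read_weather(paths["weather"]),
        canopy_obs=read_canopy_obs(paths["ndvi"]),
        probe=read_probe(paths["probe"]),
        irrigation=read_irrigation(paths["irrigation"]),
        calendar=read_calendar(paths["calendar"]),
    )
    known = set(bundle.calendar["plot_id"])
    for name, df in (("ndvi", bundle.canopy_obs), ("probe", bundle.probe), ("irrigation", bundle.irrigation)):
        unknown = set(df["plot_id"]) - known
        if unknown:
            raise UnknownPlotError(f"{name}: plot(s) {sorted(unknown)} not present in the crop calendar")
    return bundle


def write_bundle(bundle: InputBundle, directory) -> dict:
    """Write the five tables as CSV; returns the path map read_input_tables accepts."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "weather": directory / "weather.csv",
        "ndvi": directory / "ndvi.csv",
        "probe": directory / "probe.csv",
        "irrigation": directory / "irrigation.csv",
        "calendar": directory / "calendar.csv",
    }
    frames = {
        "weather": bundle.weather,
        "ndvi": bundle.canopy_obs,
        "probe": bundle.probe,
        "irrigation": bundle.irrigation,
        "calendar": bundle.calendar,
    }
    for key, df in frames.items():
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        out.to_csv(paths[key], index=False, float_format="%.12g")
    return {k: str(v) for k, v in paths.items()}


LONG_COLUMNS = ("plot_id", "date", "variable", "value")

#: Variables exported per plot-day from a balance trajectory.
BALANCE_VARIABLES = ("smd_mm", "aet_mm", "drainage_mm")


def export_long_table(trajectories: pd.DataFrame, canopy: pd.DataFrame | None, out_path) -> int:
    """Export balance trajectories (+ optional daily canopy) as a tidy long table.

    One row per (plot, date, variable, value); this is the table a dashboard
    or database loader would consume.  Returns the number of rows written.
    Reset residuals are exported as an additional ``reset_residual_mm``
    variable on reset days only.
    """
    if trajectories is None or trajectories.empty:
        raise ValueError("trajectories must be nonempty")
    pieces = []
    base = trajectories.melt(
        id_vars=["plot_id", "date"],
        value_vars=list(BALANCE_VARIABLES),
        var_name="variable",
        value_name="value",
    )
    pieces.append(base)
    resets = trajectories[trajectories["reset"].astype(bool)]
    if not resets.empty:
        pieces.append(
            pd.DataFrame(
                {
                    "plot_id": resets["plot_id"],
                    "date": resets["date"],
                    "variable": "reset_residual_mm",
                    "value": resets["reset_residual_mm"],
                }
            )
        )
    if canopy is not None and not canopy.empty:
        pieces.append(
            pd.DataFrame(
                {
                    "plot_id": canopy["plot_id"],
                    "date": canopy["date"],
                    "variable": "cover",
                    "value": canopy["cover"],
                }
            )
        )
    long = pd.concat(pieces, ignore_index=True)
    long = long.sort_values(["plot_id", "date", "variable"], kind="mergesort").reset_index(drop=True)
    out = long.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(out_path, index=False, float_format="%.12g")
    return len(long)


def read_long_table(path) -> pd.DataFrame:
    """Read a long-format results table back (round-trips export_long_table)."""
    df = _read_csv(path, LONG_COLUMNS)
    origin = Path(path).name
    return pd.DataFrame(
        {
            "plot_id": df["plot_id"].astype(str),
            "date": _parse_dates(df, "date", origin),
            "variable": df["variable"].astype(str),
            "value": _parse_floats(df, "value", origin),
        }
    )
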