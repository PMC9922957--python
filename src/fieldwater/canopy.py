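"""Canopy cover from sparse multi-instrument NDVI.

NDVI readings arrive fortnightly at best, from more than one instrument.
They are (1) standardised onto a common scale with per-instrument linear
calibrations, (2) mapped to a canopy-cover fraction f in [0, 1] by linear
rescaling between a bare-soil baseline and the closure threshold (closure is
assumed at NDVI 0.75 for all crops), and (3) interpolated to a daily series
assuming canopy development is linear in time between emergence and closure.
Cover drives the evapotranspiration reduction in the water balance, so this
module decides how much of PET the crop can actually use on each day.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Tuple

import numpy as np
import pandas as pd

from .config import TrialConfig
from .errors import CalibrationError
from .io import crop_windows


def standardise_ndvi(
    obs: pd.DataFrame,
    instrument_offsets: Mapping[str, Tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Put multi-instrument NDVI on a common scale.

    ``instrument_offsets`` maps instrument name to a ``(gain, offset)`` linear
    calibration: standardised = gain * raw + offset.  Instruments absent from
    the mapping default to identity when the mapping is None; with an explicit
    mapping every instrument present in ``obs`` must have an entry.

    Returns a copy with an added ``ndvi`` column; row order and count are
    preserved.
    """
    out = obs.copy()
    if instrument_offsets is None:
        out["ndvi"] = out["ndvi_raw"].astype(float)
        return out
    unknown = set(out["instrument"]) - set(instrument_offsets)
    if unknown:
        raise CalibrationError(f"no calibration entry for instrument(s): {sorted(unknown)}")
    gains = out["instrument"].map(lambda i: instrument_offsets[i][0]).astype(float)
    offsets = out["instrument"].map(lambda i: instrument_offsets[i][1]).astype(float)
    out["ndvi"] = gains * out["ndvi_raw"].astype(float) + offsets
    return out


def cover_fraction(ndvi, config: TrialConfig):
    """Map standardised NDVI to canopy-cover fraction in [0, 1].

    Linear between the bare-soil baseline (cover 0) and the closure threshold
    (cover 1), clamped outside; total on finite input and non-decreasing in
    NDVI.  Scalar in, scalar out; array in, array out.
    """
    ndvi_arr = np.asarray(ndvi, dtype=float)
    frac = (ndvi_arr - config.ndvi_bare) / (config.ndvi_closure - config.ndvi_bare)
    clipped = np.clip(frac, 0.0, 1.0)
    if np.ndim(ndvi) == 0:
        return float(clipped)
    return clipped


def interpolate_daily(
    obs: pd.DataFrame,
    calendar: pd.DataFrame,
    config: TrialConfig,
    dates: pd.DatetimeIndex,
    plot_id: str | None = None,
) -> pd.DataFrame:
    """Daily canopy-cover series for one plot over the trial period.

    Rules, applied per crop season [emergence, harvest]:

    * cover is 0 before emergence, after harvest, and on every fallow day;
    * observations dated outside any [emergence, harvest] window (i.e. in a
      fallow interval or the pre-emergence gap) are dropped with a warning;
    * retained observations are converted via :func:`cover_fraction` and the
      series is piecewise-linear in time between them, anchored at
      (emergence, 0) when no observation falls on the emergence day;
    * once the series reaches cover 1 it is held at 1 until the next
      observation (whose own value is honoured exactly, so an observed
      senescence decline appears) or until harvest;
    * after the last observation the last value is held until harvest.

    ``obs`` must already be standardised (have an ``ndvi`` column).  The
    result passes exactly through every retained observation.
    """
    if plot_id is None:
        plots = obs["plot_id"].unique() if len(obs) else []
        if len(plots) > 1:
            raise ValueError("obs spans multiple plots; pass plot_id explicitly")
        plot_id = str(plots[0]) if len(plots) else None
    if plot_id is None:
        raise ValueError("plot_id required when obs is empty")

    cover = np.zeros(len(dates))
    windows = crop_windows(calendar, plot_id)
    obs = obs[obs["plot_id"] == str(plot_id)] if len(obs) else obs

    in_any_window = pd.Series(False, index=range(len(obs)))
    if len(obs):
        obs = obs.sort_values("date").reset_index(drop=True)
        for _, win in windows.iterrows():
            in_any_window |= (obs["date"] >= win["emergence"]) & (obs["date"] <= win["harvest"])
        dropped = obs[~in_any_window]
        if not dropped.empty:
            days = ", ".join(d.strftime("%Y-%m-%d") for d in dropped["date"].head(5))
            warnings.warn(
                f"plot {plot_id}: dropped {len(dropped)} canopy observation(s) outside "
                f"crop windows (fallow or pre-emergence), e.g. {days}",
                stacklevel=2,
            )

    for _, win in windows.iterrows():
        emergence, harvest = win["emergence"], win["harvest"]
        day_mask = (dates >= emergence) & (dates <= harvest)
        if not day_mask.any():
            continue
        season = obs[(obs["date"] >= emergence) & (obs["date"] <= harvest)] if len(obs) else obs
        if len(season) == 0:
            continue  # no observations: cover stays 0 for this season
        knot_dates = list(season["date"])
        knot_cover = list(cover_fraction(season["ndvi"].to_numpy(), config))
        if knot_dates[0] > emergence:
            knot_dates.insert(0, emergence)
            knot_cover.insert(0, 0.0)
        season_dates = dates[day_mask]
        values = _interp_with_closure_hold(season_dates, knot_dates, knot_cover)
        cover[day_mask] = values

    return pd.DataFrame({"plot_id": str(plot_id), "date": dates, "cover": cover})


def _interp_with_closure_hold(dates: pd.DatetimeIndex, knot_dates, knot_cover) -> np.ndarray:
    """Piecewise-linear through the knots; full closure is an absorbing state
    between knots (held at 1 until the next knot), and the last knot's value
    is held to the end."""
    out = np.empty(len(dates))
    t = dates.view("int64")
    kt = pd.DatetimeIndex(knot_dates).view("int64")
    kv = np.asarray(knot_cover, dtype=float)
    for i, ti in enumerate(t):
        j = np.searchsorted(kt, ti, side="right") - 1
        if j < 0:
            out[i] = kv[0]
        elif j >= len(kt) - 1:
            out[i] = kv[-1]
        elif ti == kt[j]:
            out[i] = kv[j]
        elif kv[j] >= 1.0:
            out[i] = 1.0  # closure holds until the next observation
        else:
            frac = (ti - kt[j]) / (kt[j + 1] - kt[j])
            out[i] = kv[j] + frac * (kv[j + 1] - kv[j])
    return np.clip(out, 0.0, 1.0)


def interpolate_all_plots(
    obs: pd.DataFrame,
    calendar: pd.DataFrame,
    config: TrialConfig,
    dates: pd.DatetimeIndex,
) -> pd.DataFrame:
    """Daily cover for every plot in the calendar, concatenated."""
    frames = [
        interpolate_daily(obs, calendar, config, dates, plot_id=plot)
        for plot in sorted(calendar["plot_id"].unique())
    ]
    return pd.concat(frames, ignore_index=True)
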