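"""Daily soil-moisture-deficit bucket model.

Single-store water balance in the lineage of Horne & Scotter's daily
accounting, tracked as a deficit: SMD >= 0 mm, with 0 meaning the profile is
at field capacity and the deficit growing as the soil dries.  Each day

    AET      = PET * cover * stress(SMD_prev)
    d        = SMD_prev + AET - Rain - Irrigation     (provisional deficit)
    Drainage = max(0, -d)
    SMD_next = max(0, d)

so any water in excess of the remaining deficit leaves the profile as
drainage the same day.  Two corrections tie the model to the field:

* PET is scaled by the canopy-cover fraction, because actual
  evapotranspiration is well below PET before full canopy closure; and
* whenever an observed profile storage is available, the modelled deficit is
  reset to max(0, FC - observed) after that day's step, and the signed
  residual (prediction - observation-implied deficit) is recorded as a
  measure of model drift between observations.

The optional linear stress model multiplies a further factor
clamp((TAW - SMD)/(TAW - RAW), 0, 1): transpiration is unrestricted until
the readily available water RAW is exhausted and declines linearly to zero
at the total available water TAW.  It is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .config import TrialConfig
from .errors import InitializationError
from .soil import FieldCapacity

logger = logging.getLogger(__name__)

FROM_FIRST_OBSERVATION = "from first observation"


@dataclass(frozen=True)
class DailyForcing:
    """One day of inputs to the bucket: water in, atmospheric demand, canopy
    state, and (optionally) an observed profile storage to reset against."""

    date: pd.Timestamp
    rain_mm: float
    pet_mm: float
    irrigation_mm: float
    cover: float
    observed_storage_mm: Optional[float] = None

    def __post_init__(self):
        if min(self.rain_mm, self.pet_mm, self.irrigation_mm) < 0:
            raise ValueError("rain, PET and irrigation must be >= 0")
        if not (0.0 <= self.cover <= 1.0):
            raise ValueError("cover must be in [0, 1]")
        if self.observed_storage_mm is not None and self.observed_storage_mm < 0:
            raise ValueError("observed_storage_mm must be >= 0")


def _stress_factor(smd_prev: float, config: TrialConfig) -> float:
    if config.stress_model == "off":
        return 1.0
    taw, raw = config.taw_mm, config.raw_mm
    return float(np.clip((taw - smd_prev) / (taw - raw), 0.0, 1.0))


def step(smd_prev: float, forcing: DailyForcing, config: TrialConfig):
    """Advance the deficit one day; returns (smd_next, aet, drainage)."""
    if smd_prev < 0:
        raise ValueError("smd_prev must be >= 0")
    aet = forcing.pet_mm * forcing.cover * _stress_factor(smd_prev, config)
    water_in = forcing.rain_mm + forcing.irrigation_mm
    provisional = smd_prev + aet - water_in
    drainage = max(0.0, -provisional)
    smd_next = max(0.0, provisional)
    return smd_next, aet, drainage


def apply_reset(smd_model: float, observed_storage_mm: float, fc: FieldCapacity):
    """Correct the modelled deficit to an observed storage.

    Returns (smd_reset, residual) with residual = smd_model - smd_reset.
    An observation wetter than field capacity resets the deficit to 0 and is
    logged as supersaturation; no retroactive drainage is invented for it.
    """
    if observed_storage_mm < 0:
        raise ValueError("observed_storage_mm must be >= 0")
    if observed_storage_mm > fc.fc_mm:
        logger.warning(
            "plot %s: observed storage %.1f mm exceeds field capacity %.1f mm "
            "(supersaturation); deficit reset to 0",
            fc.plot_id,
            observed_storage_mm,
            fc.fc_mm,
        )
    smd_reset = max(0.0, fc.fc_mm - observed_storage_mm)
    return smd_reset, smd_model - smd_reset


def run_balance(
    forcings: Union[pd.DataFrame, Sequence[DailyForcing]],
    fc: FieldCapacity,
    config: TrialConfig,
    smd_init: Union[float, str] = FROM_FIRST_OBSERVATION,
) -> pd.DataFrame:
    """Run the bucket model over a contiguous daily forcing sequence.

    ``smd_init`` is either a starting deficit (mm) or the sentinel
    ``"from first observation"``, in which case the first forcing day must
    carry an observed storage that anchors the initial state — running blind
    before the first observation is refused rather than guessed.

    On any day with an observed storage the reset is applied after that
    day's model step; the reset flag is set and the signed residual stored.

    Returns a trajectory frame with one row per forcing day: date, smd_mm,
    aet_mm, drainage_mm, reset, reset_residual_mm.
    """
    seq = _as_forcing_sequence(forcings)
    if not seq:
        raise InitializationError("empty forcing sequence")
    deltas = np.diff(pd.DatetimeIndex([f.date for f in seq]).view("int64"))
    if len(deltas) and (deltas != 86_400_000_000_000).any():
        raise InitializationError("forcings must be contiguous daily")

    if isinstance(smd_init, str):
        if smd_init != FROM_FIRST_OBSERVATION:
            raise InitializationError(f"unknown smd_init sentinel: {smd_init!r}")
        if seq[0].observed_storage_mm is None:
            raise InitializationError(
                "smd_init='from first observation' but the first forcing day has "
                "no observed storage; slice the run to start at an observation"
            )
        smd, _ = apply_reset(0.0, seq[0].observed_storage_mm, fc)
    else:
        if smd_init < 0:
            raise InitializationError("smd_init must be >= 0")
        smd = float(smd_init)

    n = len(seq)
    smd_out = np.empty(n)
    aet_out = np.empty(n)
    drain_out = np.empty(n)
    reset_out = np.zeros(n, dtype=bool)
    residual_out = np.full(n, np.nan)
    warned_taw = False

    for i, forcing in enumerate(seq):
        smd, aet, drainage = step(smd, forcing, config)
        if forcing.observed_storage_mm is not None:
            smd, residual = apply_reset(smd, forcing.observed_storage_mm, fc)
            reset_out[i] = True
            residual_out[i] = residual
        if (
            config.stress_model == "off"
            and config.taw_mm is not None
            and smd > config.taw_mm
            and not warned_taw
        ):
            logger.warning(
                "plot %s: SMD %.1f mm exceeds taw_mm %.1f mm with stress model off",
                fc.plot_id,
                smd,
                config.taw_mm,
            )
            warned_taw = True
        smd_out[i] = smd
        aet_out[i] = aet
        drain_out[i] = drainage

    return pd.DataFrame(
        {
            "plot_id": fc.plot_id,
            "date": pd.DatetimeIndex([f.date for f in seq]),
            "smd_mm": smd_out,
            "aet_mm": aet_out,
            "drainage_mm": drain_out,
            "reset": reset_out,
            "reset_residual_mm": residual_out,
        }
    )


def _as_forcing_sequence(forcings) -> list:
    if isinstance(forcings, pd.DataFrame):
        out = []
        has_obs = "observed_storage_mm" in forcings.columns
        for row in forcings.itertuples(index=False):
            obs = getattr(row, "observed_storage_mm", None) if has_obs else None
            if obs is not None and pd.isna(obs):
                obs = None
            out.append(
                DailyForcing(
                    date=pd.Timestamp(row.date),
                    rain_mm=float(row.rain_mm),
                    pet_mm=float(row.pet_mm),
                    irrigation_mm=float(getattr(row, "irrigation_mm", 0.0)),
                    cover=float(row.cover),
                    observed_storage_mm=None if obs is None else float(obs),
                )
            )
        return out
    return list(forcings)
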