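"""Profile water storage and field-capacity estimation.

Neutron-probe readings give volumetric water content theta per depth layer.
Storage over the accounting profile is the sum of theta times layer
thickness (mm) over the layers intersected with [0, profile_depth_cm];
layers reaching deeper contribute only their intersected thickness.

Field capacity is estimated from winter-fallow storages, on the assumption
that the profile drains back to field capacity during winter when
evaporation is minimal: the wettest winter reading (rule "max") or an
empirical quantile of winter readings (rule "quantile", robust to a single
outlier) is taken as FC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import TrialConfig
from .errors import FieldCapacityError, ProfileCoverageError
from .io import THETA_MAX


@dataclass(frozen=True)
class FieldCapacity:
    """Per-plot field capacity: water stored (mm) at the bucket's full mark."""

    plot_id: str
    fc_mm: float
    n_obs: int

    def __post_init__(self):
        if self.fc_mm <= 0:
            raise ValueError("fc_mm must be positive")
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")


def profile_storage(readings: pd.DataFrame, config: TrialConfig) -> float:
    """Water stored (mm) in the top profile_depth_cm, for one plot and date.

    Layers must cover [0, profile_depth_cm] without gaps; a partial bottom
    layer is truncated at the profile depth.  Additive over layer partitions.
    """
    depth = config.profile_depth_cm
    layers = readings.sort_values("depth_top_cm")
    tops = layers["depth_top_cm"].to_numpy(dtype=float)
    bottoms = layers["depth_bottom_cm"].to_numpy(dtype=float)
    thetas = layers["theta"].to_numpy(dtype=float)

    covered = 0.0  # how far down contiguous coverage extends
    storage = 0.0
    for top, bottom, theta in zip(tops, bottoms, thetas):
        if top >= depth:
            break
        if top > covered + 1e-9:
            raise ProfileCoverageError(
                f"probe layers leave a gap [{covered:g}, {top:g}] cm inside the "
                f"{depth:g} cm profile"
            )
        effective_bottom = min(bottom, depth)
        if effective_bottom > covered:
            # only the part of the layer below previous coverage and above the
            # profile depth counts; theta is uniform within a layer
            storage += theta * (effective_bottom - max(top, covered)) * 10.0
            covered = effective_bottom
    if covered < depth - 1e-9:
        raise ProfileCoverageError(
            f"probe layers cover only [0, {covered:g}] cm of the {depth:g} cm profile"
        )
    return storage


def storage_table(probe: pd.DataFrame, config: TrialConfig) -> pd.DataFrame:
    """Profile storage for every (plot, date) group in a probe table."""
    records = []
    for (plot, date), grp in probe.groupby(["plot_id", "date"], sort=True):
        records.append(
            {"plot_id": plot, "date": date, "storage_mm": profile_storage(grp, config)}
        )
    out = pd.DataFrame.from_records(records, columns=["plot_id", "date", "storage_mm"])
    bound = config.profile_depth_cm * 10.0 * THETA_MAX
    if not out.empty and (out["storage_mm"] > bound + 1e-9).any():
        raise ProfileCoverageError(f"storage exceeds porosity bound {bound:g} mm")
    return out


def estimate_field_capacity(storages: pd.DataFrame, config: TrialConfig) -> FieldCapacity:
    """Field capacity of one plot from its winter-fallow storages.

    Winter is the recurring config.fallow_window month range.  Raises
    :class:`FieldCapacityError` when no storage falls in winter — FC must
    never default silently, because every deficit downstream is relative
    to it.
    """
    plots = storages["plot_id"].unique()
    if len(plots) != 1:
        raise ValueError("estimate_field_capacity expects storages for exactly one plot")
    plot = str(plots[0])
    months = config.fallow_months()
    winter = storages[storages["date"].dt.month.isin(months)]
    if winter.empty:
        raise FieldCapacityError(
            f"plot {plot}: no storage observation in the winter fallow window "
            f"(months {sorted(months)}); field capacity cannot be estimated"
        )
    values = winter["storage_mm"].to_numpy(dtype=float)
    if config.fc_rule == "max":
        fc = float(values.max())
    else:
        fc = float(np.quantile(values, config.fc_quantile))
    return FieldCapacity(plot_id=plot, fc_mm=fc, n_obs=len(values))
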