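"""Trial-level configuration.

A single :class:`TrialConfig` object carries every tunable parameter of the
pipeline: the accounting profile depth, the NDVI-to-cover mapping endpoints,
the recurring winter fallow window used for field-capacity estimation, the
drainage-event segmentation thresholds, and the optional soil-dryness stress
model.  It mirrors a flat YAML/JSON config file field-for-field.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ConfigFileError


class TrialConfig(BaseModel):
    """Global configuration for one field trial.

    Parameters
    ----------
    profile_depth_cm:
        Depth of the accounted soil profile (cm).  All storage, field-capacity
        and deficit quantities refer to the water held in the top
        ``profile_depth_cm`` of soil.
    ndvi_closure:
        Standardised NDVI at which the canopy is considered fully closed
        (cover fraction 1).  One threshold for all crops.
    ndvi_bare:
        Standardised NDVI of bare soil (cover fraction 0).
    fallow_window:
        Inclusive month range ``(first, last)`` treated as winter fallow for
        field-capacity estimation; may wrap the year end.  Southern-hemisphere
        default June-August.
    fc_rule, fc_quantile:
        How field capacity is summarised from winter-fallow storages:
        ``"max"`` takes the wettest reading, ``"quantile"`` the empirical
        ``fc_quantile`` quantile (guards against a single outlier).
    event_min_mm, event_merge_gap_days:
        Drainage-event segmentation: runs of draining days separated by at
        most ``event_merge_gap_days`` dry days are merged, and merged events
        totalling less than ``event_min_mm`` are discarded.
    stress_model, taw_mm, raw_mm:
        Optional linear soil-dryness reduction of evapotranspiration.  With
        ``stress_model="linear"``, transpiration is unrestricted until the
        deficit exceeds the readily available water ``raw_mm`` and declines
        linearly to zero at the total available water ``taw_mm``.
    seed:
        Seed forwarded to the synthetic-trial generator.
    """

    model_config = ConfigDict(frozen=True)

    profile_depth_cm: float = 60.0
    ndvi_closure: float = 0.75
    ndvi_bare: float = 0.15
    fallow_window: Tuple[int, int] = (6, 8)
    fc_rule: Literal["max", "quantile"] = "max"
    fc_quantile: float = 0.95
    event_min_mm: float = 1.0
    event_merge_gap_days: int = 1
    stress_model: Literal["off", "linear"] = "off"
    taw_mm: Optional[float] = None
    raw_mm: Optional[float] = None
    seed: int = 0

    @model_validator(mode="after")
    def _check_invariants(self) -> "TrialConfig":
        if self.profile_depth_cm <= 0:
            raise ValueError("profile_depth_cm must be positive")
        if not (0.0 <= self.ndvi_bare < self.ndvi_closure <= 1.0):
            raise ValueError("require 0 <= ndvi_bare < ndvi_closure <= 1")
        a, b = self.fallow_window
        if not (1 <= a <= 12 and 1 <= b <= 12):
            raise ValueError("fallow_window months must be in 1..12")
        if not (0.0 < self.fc_quantile <= 1.0):
            raise ValueError("fc_quantile must be in (0, 1]")
        if self.event_min_mm < 0:
            raise ValueError("event_min_mm must be >= 0")
        if self.event_merge_gap_days < 0:
            raise ValueError("event_merge_gap_days must be >= 0")
        if self.stress_model == "linear":
            if self.taw_mm is None or self.raw_mm is None:
                raise ValueError("stress_model='linear' requires taw_mm and raw_mm")
            if not (0.0 <= self.raw_mm < self.taw_mm):
                raise ValueError("require 0 <= raw_mm < taw_mm")
        return self

    def fallow_months(self) -> frozenset:
        """Months (1-12) inside the recurring fallow window, wrap-safe."""
        a, b = self.fallow_window
        if a <= b:
            return frozenset(range(a, b + 1))
        return frozenset(list(range(a, 13)) + list(range(1, b + 1)))

    def params_subset(self, keys) -> dict:
        """The named parameter values, for stage fingerprinting."""
        data = self.model_dump()
        unknown = set(keys) - set(data)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return {k: data[k] for k in sorted(keys)}

    @classmethod
    def from_file(cls, path) -> "TrialConfig":
        """Load from a flat YAML (or JSON, a YAML subset) mapping."""
        text = Path(path).read_text()
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigFileError(f"cannot parse config file {path}: {exc}") from exc
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigFileError(f"config file {path} must contain a mapping")
        if "fallow_window" in raw and isinstance(raw["fallow_window"], list):
            raw["fallow_window"] = tuple(raw["fallow_window"])
        try:
            return cls(**raw)
        except ValueError as exc:
            raise ConfigFileError(f"invalid configuration in {path}: {exc}") from exc

    def to_file(self, path) -> None:
        data = self.model_dump()
        data["fallow_window"] = list(data["fallow_window"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
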