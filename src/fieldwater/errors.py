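"""Typed error hierarchy.

Every validation failure in the pipeline raises one of these; a malformed
input never passes silently.  Messages carry enough context (column name,
missing dates, offending row) for the operations team to fix the source file.
"""

from __future__ import annotations


class FieldWaterError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(FieldWaterError):
    """An input table is missing a required column or has an unreadable value."""


class WeatherGapError(FieldWaterError):
    """The daily weather series has missing dates; the balance cannot step."""

    def __init__(self, missing_dates):
        self.missing_dates = list(missing_dates)
        shown = ", ".join(str(d.date()) for d in self.missing_dates[:10])
        more = "" if len(self.missing_dates) <= 10 else f" (+{len(self.missing_dates) - 10} more)"
        super().__init__(f"weather series has gaps: {shown}{more}")


class RowInvariantError(FieldWaterError):
    """A row violates a type invariant (e.g. depth_top >= depth_bottom)."""


class UnknownPlotError(FieldWaterError):
    """An observation references a plot that is absent from the crop calendar."""


class CalibrationError(FieldWaterError):
    """An NDVI instrument has no calibration entry."""


class ProfileCoverageError(FieldWaterError):
    """Probe layers leave a gap inside the accounting profile depth."""


class FieldCapacityError(FieldWaterError):
    """Field capacity cannot be estimated (no winter-fallow storages)."""


class InitializationError(FieldWaterError):
    """The water balance has no derivable initial condition."""


class GraphCycleError(FieldWaterError):
    """The stage graph contains a cycle."""

    def __init__(self, stages):
        self.stages = sorted(stages)
        super().__init__(f"stage graph contains a cycle involving: {', '.join(self.stages)}")


class StageFailedError(FieldWaterError):
    """A pipeline stage raised during execution; downstream stages are blocked."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause!r}")


class ConfigFileError(FieldWaterError):
    """The declarative configuration file is malformed."""
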