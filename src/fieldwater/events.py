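"""Drainage-event detection, lag times, and seasonal summaries.

A drainage event is a maximal run of days with modelled drainage, with runs
separated by at most ``event_merge_gap_days`` dry days merged into one event
and merged events totalling less than ``event_min_mm`` discarded.  Events
tell the operations team when leachate sampling is due; the lag from an
event's end to the next scheduled sampling date is reported in whole days.

Season names follow the southern hemisphere: winter Jun-Aug, spring Sep-Nov,
summer Dec-Feb, autumn Mar-May.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import pandas as pd

from .config import TrialConfig

SEASONS = {
    12: "summer", 1: "summer", 2: "summer",
    3: "autumn", 4: "autumn", 5: "autumn",
    6: "winter", 7: "winter", 8: "winter",
    9: "spring", 10: "spring", 11: "spring",
}


@dataclass(frozen=True)
class DrainageEvent:
    plot_id: str
    label: str
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    total_mm: float
    peak_mm: float

    @property
    def season(self) -> str:
        return SEASONS[self.start_date.month]


def segment_runs(values: Sequence[float], min_total: float, merge_gap: int):
    """Segment a daily drainage series into events.

    Returns a list of (start_index, end_index, total, peak) with inclusive
    indices.  Pure-python single pass; kept lean because the exhaustive
    oracle comparison calls it millions of times.
    """
    runs = []  # [start, end, total, peak], end inclusive
    current = None
    for i, v in enumerate(values):
        if v > 0:
            if current is None:
                current = [i, i, v, v]
            else:
                current[1] = i
                current[2] += v
                if v > current[3]:
                    current[3] = v
        elif current is not None:
            runs.append(current)
            current = None
    if current is not None:
        runs.append(current)

    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
            last = merged[-1]
            last[1] = run[1]
            last[2] += run[2]
            if run[3] > last[3]:
                last[3] = run[3]
        else:
            merged.append(run)

    return [(s, e, t, p) for s, e, t, p in merged if t >= min_total]


def detect_events(
    trajectory: pd.DataFrame,
    config: TrialConfig,
    label_prefix: Optional[str] = None,
) -> List[DrainageEvent]:
    """Detect labelled drainage events in one plot's balance trajectory.

    Labels are ``<prefix>-<ordinal>`` ordered by start date; the prefix
    defaults to the plot id and is typically the nitrogen-treatment code
    (e.g. ``"N2"``) when plotting by treatment.
    """
    plots = trajectory["plot_id"].unique()
    if len(plots) != 1:
        raise ValueError("detect_events expects a single-plot trajectory")
    plot = str(plots[0])
    prefix = label_prefix if label_prefix is not None else plot
    dates = trajectory["date"].reset_index(drop=True)
    drains = trajectory["drainage_mm"].tolist()
    events = []
    for ordinal, (s, e, total, peak) in enumerate(
        segment_runs(drains, config.event_min_mm, config.event_merge_gap_days), start=1
    ):
        events.append(
            DrainageEvent(
                plot_id=plot,
                label=f"{prefix}-{ordinal}",
                start_date=dates.iloc[s],
                end_date=dates.iloc[e],
                total_mm=float(total),
                peak_mm=float(peak),
            )
        )
    return events


def lag_days(events: Iterable[DrainageEvent], reference_dates) -> List[Optional[int]]:
    """Whole-day lag from each event's end to the first reference date on or
    after it; None when no later reference exists (sampling happens after
    drainage completes, so lags are measured from the event end)."""
    refs = sorted(pd.Timestamp(d) for d in reference_dates)
    if not refs:
        raise ValueError("reference_dates must be nonempty")
    lags: List[Optional[int]] = []
    for event in events:
        later = [r for r in refs if r >= event.end_date]
        lags.append((later[0] - event.end_date).days if later else None)
    return lags


def summarise_events(events: Iterable[DrainageEvent]) -> pd.DataFrame:
    """Event counts and cumulative drainage grouped by (plot, season)."""
    rows = [
        {"plot_id": ev.plot_id, "season": ev.season, "total_mm": ev.total_mm}
        for ev in events
    ]
    if not rows:
        return pd.DataFrame(columns=["plot_id", "season", "n_events", "total_mm"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["plot_id", "season"], as_index=False)
        .agg(n_events=("total_mm", "size"), total_mm=("total_mm", "sum"))
        .sort_values(["plot_id", "season"])
        .reset_index(drop=True)
    )
    return out


def events_to_frame(events: Iterable[DrainageEvent]) -> pd.DataFrame:
    """Tabulate events for export."""
    return pd.DataFrame(
        [
            {
                "plot_id": ev.plot_id,
                "label": ev.label,
                "start_date": ev.start_date,
                "end_date": ev.end_date,
                "total_mm": ev.total_mm,
                "peak_mm": ev.peak_mm,
                "season": ev.season,
            }
            for ev in events
        ],
        columns=["plot_id", "label", "start_date", "end_date", "total_mm", "peak_mm", "season"],
    )
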