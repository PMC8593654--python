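"""Segmentation of the monitoring period into large events, small events
and dry periods.

An event is a maximal wet spell: consecutive rain steps (> 0 mm) that are
never interrupted by a dry spell of at least ``event_gap`` (default 2 h).
An event is *large* when its maximum 10-min intensity exceeds
``intensity_threshold`` (default 1 mm/10 min), otherwise *small*.  Each
event carries an analysis window starting at the event start: 3 h for
small events and 14 h for large ones — windows are attached for analysis,
they are not event boundaries.

A *dry* calendar day has zero rainfall and a water-level standard
deviation within a configurable threshold (so recession days after storms,
when groundwater still drives the level down, do not count as dry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EventConfig",
    "EventCatalog",
    "segment_events",
    "find_dry_periods",
    "event_summary",
]


@dataclass(frozen=True)
class EventConfig:
    """Thresholds and windows for hydro-meteorological classification."""

    intensity_threshold: float = 1.0  # mm per 10 min
    event_gap: pd.Timedelta = pd.Timedelta("2h")
    small_window: pd.Timedelta = pd.Timedelta("3h")
    large_window: pd.Timedelta = pd.Timedelta("14h")
    dry_level_sd_threshold: float = 0.5  # cm; no literature value, see docs

    def __post_init__(self) -> None:
        if self.intensity_threshold <= 0:
            raise ValueError("intensity_threshold must be > 0")
        for name in ("event_gap", "small_window", "large_window"):
            if pd.Timedelta(getattr(self, name)) <= pd.Timedelta(0):
                raise ValueError(f"{name} must be > 0")


@dataclass
class EventCatalog:
    """Classified events and dry periods.

    ``events`` columns: start, end (timestamp of last wet step + one step,
    half-open), kind ('large'/'small'), max_intensity, total_rain,
    window_end, partial.  ``dry_periods`` columns: start, end.
    """

    events: pd.DataFrame
    dry_periods: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["start", "end"])
    )

    @property
    def n_large(self) -> int:
        return int((self.events["kind"] == "large").sum()) if len(self.events) else 0

    @property
    def n_small(self) -> int:
        return int((self.events["kind"] == "small").sum()) if len(self.events) else 0


_EVENT_COLUMNS = [
    "start",
    "end",
    "kind",
    "max_intensity",
    "total_rain",
    "window_end",
    "partial",
]


def segment_events(rain: pd.Series, cfg: EventConfig | None = None) -> EventCatalog:
    """Partition wet steps into events and classify them by peak intensity.

    Every wet step belongs to exactly one event; events end at the last wet
    step before a dry spell of at least ``cfg.event_gap``.  Events touching
    the record boundaries are kept and flagged ``partial`` (the separating
    dry spell cannot be verified there).
    """
    cfg = cfg or EventConfig()
    r = rain.to_numpy(dtype=float)
    if len(r) == 0 or not (r > 0).any():
        return EventCatalog(events=pd.DataFrame(columns=_EVENT_COLUMNS))
    step = rain.index[1] - rain.index[0] if len(rain) > 1 else pd.Timedelta("10min")
    gap_steps = int(np.ceil(cfg.event_gap / step))

    wet_idx = np.flatnonzero(r > 0)
    # split wherever the dry run between consecutive wet steps reaches the gap
    breaks = np.flatnonzero(np.diff(wet_idx) > gap_steps)
    starts = np.concatenate([[wet_idx[0]], wet_idx[breaks + 1]])
    ends = np.concatenate([wet_idx[breaks], [wet_idx[-1]]])  # inclusive wet step

    rows = []
    for s, e in zip(starts, ends):
        chunk = r[s : e + 1]
        max_int = float(chunk.max())
        kind = "large" if max_int > cfg.intensity_threshold else "small"
        window = cfg.large_window if kind == "large" else cfg.small_window
        start_t = rain.index[s]
        partial = (s < gap_steps) or (e + gap_steps >= len(r))
        rows.append(
            {
                "start": start_t,
                "end": rain.index[e] + step,
                "kind": kind,
                "max_intensity": max_int,
                "total_rain": float(chunk.sum()),
                "window_end": start_t + window,
                "partial": bool(partial),
            }
        )
    return EventCatalog(events=pd.DataFrame(rows, columns=_EVENT_COLUMNS))


def find_dry_periods(
    rain: pd.Series, level: pd.Series, cfg: EventConfig | None = None
) -> pd.DataFrame:
    """Calendar days with zero rain and level sd within the threshold,
    merged into contiguous (start, end) periods (end exclusive).

    Only days fully covered by both series are considered.
    """
    cfg = cfg or EventConfig()
    rain_day = rain.resample("1D").agg(["sum", "count"])
    level_day = level.resample("1D").agg([lambda s: s.std(ddof=0), "count"])
    level_day.columns = ["sd", "count"]

    rain_step = rain.index[1] - rain.index[0] if len(rain) > 1 else pd.Timedelta("10min")
    level_step = (
        level.index[1] - level.index[0] if len(level) > 1 else pd.Timedelta("15min")
    )
    full_rain = int(pd.Timedelta("1D") / rain_step)
    full_level = int(pd.Timedelta("1D") / level_step)

    days = rain_day.index.intersection(level_day.index)
    dry_days = []
    for day in days:
        if rain_day.loc[day, "count"] < full_rain or level_day.loc[day, "count"] < full_level:
            continue
        if rain_day.loc[day, "sum"] == 0 and level_day.loc[day, "sd"] <= cfg.dry_level_sd_threshold:
            dry_days.append(day)

    periods = []
    for day in dry_days:
        if periods and day == periods[-1][1]:
            periods[-1][1] = day + pd.Timedelta("1D")
        else:
            periods.append([day, day + pd.Timedelta("1D")])
    return pd.DataFrame(periods, columns=["start", "end"])


def event_summary(catalog: EventCatalog, rain: pd.Series) -> pd.DataFrame:
    """Per-event durations and totals plus a campaign-total row.

    The 'campaign' row reports the full series rain sum, so the table is
    self-checking: per-event totals must add up to the total wet rainfall.
    """
    rows = []
    for _, ev in catalog.events.iterrows():
        rows.append(
            {
                "event": ev["kind"],
                "start": ev["start"],
                "duration_h": (ev["end"] - ev["start"]) / pd.Timedelta("1h"),
                "max_intensity": ev["max_intensity"],
                "total_rain": ev["total_rain"],
            }
        )
    total = float(rain.sum())
    rows.append(
        {
            "event": "campaign",
            "start": rain.index[0] if len(rain) else pd.NaT,
            "duration_h": (len(rain) * (rain.index[1] - rain.index[0]) / pd.Timedelta("1h"))
            if len(rain) > 1
            else 0.0,
            "max_intensity": float(rain.max()) if len(rain) else 0.0,
            "total_rain": total,
        }
    )
    return pd.DataFrame(rows)
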