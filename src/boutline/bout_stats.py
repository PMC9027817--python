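"""Bout segmentation and per-animal behavior statistics.

Given an inter-bout criterion, consecutive events whose separating pause is
*shorter than* the criterion belong to the same bout (strict inequality: a gap
exactly equal to the criterion splits).  Bout characteristics follow the
standard definitions for interval-based bout analysis:

* total time — observed use plus intra-bout pauses (an intermediate used for
  bout duration, not reported on its own);
* bout frequency — by default the number of bouts in the window (a
  ``frequency_convention`` flag offers bouts - 1, the literal count of
  between-bout intervals);
* bout duration — total time divided by bout frequency.

Animals with a single event in a window, or whose every inter-event gap meets
or exceeds the criterion, are flagged excluded for total time and bout
duration (their bout frequency is still reported), mirroring the exclusion
rule used with coded video data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, RosterLookupError
from .bout_criterion import BoutCriterion
from .ethogram_io import Behavior, EventTable

__all__ = [
    "Bout",
    "BoutSummary",
    "UseDurations",
    "segment_bouts",
    "bout_characteristics",
    "summarize_all_bouts",
    "use_durations",
    "all_use_durations",
    "first_contact_latency",
    "latency_summary",
]


@dataclass
class Bout:
    """One bout: a run of events whose internal pauses are all sub-criterion."""

    animal_id: str
    period_index: int
    start_s: float
    stop_s: float
    n_events: int
    event_time_s: float
    intra_gap_time_s: float

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s


@dataclass
class BoutSummary:
    animal_id: str
    period_index: int
    total_time_s: float
    bout_frequency: int
    bout_duration_s: float
    excluded: bool
    exclusion_reason: str  # single_event | no_intra_bout_intervals | no_events | none


@dataclass
class UseDurations:
    animal_id: str
    period_index: int
    groom_s: float
    oral_s: float

    @property
    def total_s(self) -> float:
        return self.groom_s + self.oral_s


def segment_bouts(events: pd.DataFrame, criterion: BoutCriterion) -> list[Bout]:
    """Partition one animal x period event sequence into bouts.

    ``events`` must be the normalized, sorted events of a single animal in a
    single period.  A gap < criterion_s keeps the next event in the current
    bout; a gap >= criterion_s starts a new one.
    """
    if events.empty:
        return []
    animals = events["animal_id"].unique()
    periods = events["period"].unique() if "period" in events.columns else [pd.NA]
    if len(animals) != 1 or len(periods) != 1:
        raise ContractError("segment_bouts expects a single animal x period")
    starts = events["start_s"].to_numpy(float)
    stops = events["stop_s"].to_numpy(float)
    if (np.diff(starts) < 0).any():
        raise ContractError("events are not sorted by start time")
    crit = criterion.criterion_s
    animal = str(animals[0])
    period = int(periods[0]) if pd.notna(periods[0]) else -1
    bouts: list[Bout] = []
    bout_start = 0
    for i in range(1, len(starts)):
        gap = starts[i] - stops[i - 1]
        if gap >= crit:  # strict "shorter than" keeps; equal splits
            bouts.append(_make_bout(animal, period, starts, stops, bout_start, i - 1))
            bout_start = i
    bouts.append(_make_bout(animal, period, starts, stops, bout_start, len(starts) - 1))
    return bouts


def _make_bout(animal, period, starts, stops, i, j) -> Bout:
    event_time = float(np.sum(stops[i:j + 1] - starts[i:j + 1]))
    intra = float(np.sum(starts[i + 1:j + 1] - stops[i:j])) if j > i else 0.0
    return Bout(animal_id=animal, period_index=period,
                start_s=float(starts[i]), stop_s=float(stops[j]),
                n_events=j - i + 1, event_time_s=event_time,
                intra_gap_time_s=intra)


def bout_characteristics(bouts: list[Bout],
                         frequency_convention: str = "bouts") -> BoutSummary:
    """Summarize one animal x period's bouts into the three characteristics.

    ``frequency_convention="bouts"`` (default) counts bouts;
    ``"inter_bout_intervals"`` counts bouts - 1.  Exclusion flags:
    ``single_event`` (exactly one event observed), ``no_intra_bout_intervals``
    (several events but no sub-criterion gap, i.e. every bout is a singleton),
    ``no_events`` (empty input).  Excluded summaries still report frequency.
    """
    if frequency_convention not in ("bouts", "inter_bout_intervals"):
        raise ValueError(f"unknown frequency_convention {frequency_convention!r}")
    if not bouts:
        return BoutSummary("", -1, 0.0, 0, float("nan"), True, "no_events")
    animal = bouts[0].animal_id
    period = bouts[0].period_index
    n_events = sum(b.n_events for b in bouts)
    total_time = sum(b.event_time_s + b.intra_gap_time_s for b in bouts)
    n_bouts = len(bouts)
    freq = n_bouts if frequency_convention == "bouts" else n_bouts - 1
    if n_events == 1:
        reason = "single_event"
    elif all(b.n_events == 1 for b in bouts):
        reason = "no_intra_bout_intervals"
    else:
        reason = "none"
    excluded = reason != "none"
    duration = total_time / freq if (freq > 0 and not excluded) else float("nan")
    return BoutSummary(animal_id=animal, period_index=period,
                       total_time_s=total_time, bout_frequency=freq,
                       bout_duration_s=duration, excluded=excluded,
                       exclusion_reason=reason)


def summarize_all_bouts(table: EventTable, criteria,
                        frequency_convention: str = "bouts") -> pd.DataFrame:
    """Segment and summarize every animal x period in the table.

    ``criteria`` is a :class:`~boutline.bout_criterion.CriteriaReport` (the
    period's novelty selects the pooled criterion) or a single
    :class:`BoutCriterion` applied everywhere.  Returns one row per
    animal x period that has at least one in-window event.
    """
    ev = table.events
    if "period" not in ev.columns:
        raise ContractError("events are not period-labeled")
    ev = ev[ev["period"].notna()]
    rows = []
    for (animal, period), sub in ev.groupby(["animal_id", "period"], sort=True):
        sub = sub.sort_values("start_s", kind="mergesort")
        crit = _criterion_for(criteria, sub)
        bouts = segment_bouts(sub, crit)
        s = bout_characteristics(bouts, frequency_convention)
        rows.append({
            "animal_id": animal, "period": int(period),
            "criterion_s": crit.criterion_s,
            "n_events": int(sum(b.n_events for b in bouts)),
            "total_time_s": s.total_time_s,
            "bout_frequency": s.bout_frequency,
            "bout_duration_s": s.bout_duration_s,
            "excluded": s.excluded,
            "exclusion_reason": s.exclusion_reason,
        })
    return pd.DataFrame(rows)


def _criterion_for(criteria, sub: pd.DataFrame) -> BoutCriterion:
    if isinstance(criteria, BoutCriterion):
        return criteria
    novelty = sub["novelty"].iloc[0]
    return criteria.criterion_for(novelty)


# ---------------------------------------------------------------------------
# Use durations
# ---------------------------------------------------------------------------

def use_durations(table: EventTable, animal, period) -> UseDurations:
    """Seconds of grooming and oral manipulation for one animal x period.

    Uses the clipped in-period fragments; an animal absent from the period
    yields zeros.
    """
    ev = table.events
    if "period" not in ev.columns:
        raise ContractError("events are not period-labeled")
    sub = ev[(ev["animal_id"] == animal) & (ev["period"] == period)]
    dur = sub["stop_s"].astype(float) - sub["start_s"].astype(float)
    groom = float(dur[sub["behavior"] == Behavior.GROOM.value].sum())
    oral = float(dur[sub["behavior"] == Behavior.ORAL.value].sum())
    return UseDurations(animal_id=str(animal), period_index=int(period),
                        groom_s=groom, oral_s=oral)


def all_use_durations(table: EventTable) -> pd.DataFrame:
    """Use durations for every roster animal x study period, zeros included."""
    ev = table.events[table.events["period"].notna()]
    periods = sorted(int(p) for p in ev["period"].dropna().unique())
    animals = (table.roster["animal_id"].tolist() if len(table.roster)
               else sorted(ev["animal_id"].unique()))
    rows = []
    for animal in animals:
        for period in periods:
            u = use_durations(table, animal, period)
            rows.append({"animal_id": u.animal_id, "period": u.period_index,
                         "groom_s": u.groom_s, "oral_s": u.oral_s,
                         "total_s": u.total_s})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Latency
# ---------------------------------------------------------------------------

def first_contact_latency(table: EventTable, animal) -> float | None:
    """Seconds from pen entry to the first brush contact, or None if never.

    The animal must be in the roster; event times are entry-relative, so the
    roster's ``entry_time_s`` (normally 0) is subtracted for generality.
    """
    roster = table.roster
    match = roster[roster["animal_id"] == animal]
    if not len(match):
        raise RosterLookupError(f"animal {animal!r} not in roster")
    entry = float(match["entry_time_s"].iloc[0])
    ev = table.events[table.events["animal_id"] == animal]
    if not len(ev):
        return None
    return float(ev["start_s"].astype(float).min()) - entry


def latency_summary(table: EventTable) -> dict:
    """Group-level latency descriptives in minutes (mean, sd, min, max, n).

    Animals that never contact a brush are excluded from the summary.
    """
    vals = []
    for animal in table.roster["animal_id"]:
        lat = first_contact_latency(table, animal)
        if lat is not None:
            vals.append(lat / 60.0)
    arr = np.asarray(vals)
    if not arr.size:
        return {"n": 0, "mean_min": float("nan"), "sd_min": float("nan"),
                "min_min": float("nan"), "max_min": float("nan")}
    return {"n": int(arr.size), "mean_min": float(arr.mean()),
            "sd_min": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "min_min": float(arr.min()), "max_min": float(arr.max())}
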