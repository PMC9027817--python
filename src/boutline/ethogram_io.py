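"""Event data model and CSV I/O for brush-directed behavior logs.

The pipeline works on three tables:

* behavior events — one timed interval of brush-directed behavior (grooming or
  oral manipulation) by one animal, with start/stop in seconds relative to that
  animal's entry into the pen;
* displacement events — one animal (actor) ending another's (receiver) brush
  contact through physical contact, a point event in time;
* roster — one row per animal with group, treatment and entry time.

Observation windows are four 6 h periods on the first and sixth days of brush
exposure; periods 1-2 (0-6 h, 18-24 h) are the *novel* phase, periods 3-4
(120-126 h, 138-144 h) the *non-novel* phase.  Windows are half-open
``[start, end)`` so a boundary second is never counted twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError, ValidationError

__all__ = [
    "Behavior",
    "EndCause",
    "Novelty",
    "Treatment",
    "ObservationPeriod",
    "EventTable",
    "DEFAULT_PERIODS",
    "BEHAVIOR_COLUMNS",
    "DISPLACEMENT_COLUMNS",
    "ROSTER_COLUMNS",
    "read_events",
    "write_events",
    "read_roster",
    "load_study",
    "assign_periods",
    "normalize_events",
    "link_displacements",
]


class Behavior(str, Enum):
    GROOM = "groom"
    ORAL = "oral"


class EndCause(str, Enum):
    VOLUNTARY = "voluntary"
    DISPLACED = "displaced"


class Treatment(str, Enum):
    TWO_BRUSH = "two_brush"
    FOUR_BRUSH = "four_brush"


class Novelty(str, Enum):
    NOVEL = "novel"
    NON_NOVEL = "non_novel"


@dataclass(frozen=True)
class ObservationPeriod:
    """One 6 h observation window, offsets in seconds from pen entry."""

    index: int
    label: str
    start_offset_s: float
    end_offset_s: float
    novelty: Novelty

    def contains(self, t: float) -> bool:
        return self.start_offset_s <= t < self.end_offset_s


#: The study's four observation windows: 0-6 h and 18-24 h on day 1 (novel),
#: 120-126 h and 138-144 h on day 6 (non-novel).
DEFAULT_PERIODS: tuple[ObservationPeriod, ...] = (
    ObservationPeriod(1, "0-6 h", 0 * 3600, 6 * 3600, Novelty.NOVEL),
    ObservationPeriod(2, "18-24 h", 18 * 3600, 24 * 3600, Novelty.NOVEL),
    ObservationPeriod(3, "120-126 h", 120 * 3600, 126 * 3600, Novelty.NON_NOVEL),
    ObservationPeriod(4, "138-144 h", 138 * 3600, 144 * 3600, Novelty.NON_NOVEL),
)

BEHAVIOR_COLUMNS = [
    "animal_id", "group_id", "treatment", "behavior",
    "brush_id", "start_s", "stop_s", "end_cause",
]
DISPLACEMENT_COLUMNS = ["actor_id", "receiver_id", "brush_id", "time_s", "group_id"]
ROSTER_COLUMNS = ["animal_id", "group_id", "treatment", "entry_time_s"]

_SCHEMAS = {"behavior": BEHAVIOR_COLUMNS, "displacement": DISPLACEMENT_COLUMNS,
            "roster": ROSTER_COLUMNS}


@dataclass
class EventTable:
    """Container for the three study tables plus free-form metadata.

    ``events`` and ``displacements`` gain ``period`` / ``novelty`` columns once
    :func:`assign_periods` has run.  ``meta`` carries bookkeeping such as the
    merge count from :func:`normalize_events`.
    """

    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=BEHAVIOR_COLUMNS))
    displacements: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=DISPLACEMENT_COLUMNS))
    roster: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=ROSTER_COLUMNS))
    meta: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def copy(self) -> "EventTable":
        return EventTable(self.events.copy(), self.displacements.copy(),
                          self.roster.copy(), dict(self.meta))


# ---------------------------------------------------------------------------
# Reading / writing / validation
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _coerce_numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = coerced.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: header line plus 1-based counting
        raise ValidationError(
            f"{path}: non-numeric value {df[col].iloc[row]!r} in column {col!r}",
            line=row + 2,
        )
    if coerced.isna().any():
        row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
        raise ValidationError(f"{path}: empty value in column {col!r}", line=row + 2)
    # to_numeric's fast parser can be one ulp off; astype uses the correctly
    # rounded strtod so written files round-trip bit-identically
    return df[col].astype(float)


def _validate_behavior(df: pd.DataFrame, path) -> pd.DataFrame:
    df = df.copy()
    df["start_s"] = _coerce_numeric(df, "start_s", path)
    df["stop_s"] = _coerce_numeric(df, "stop_s", path)
    bad = df["stop_s"] <= df["start_s"]
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: stop_s ({df['stop_s'].iloc[row]}) <= start_s "
            f"({df['start_s'].iloc[row]})", line=row + 2)
    if (df["start_s"] < 0).any():
        row = int(np.flatnonzero((df["start_s"] < 0).to_numpy())[0])
        raise ValidationError(f"{path}: negative start_s", line=row + 2)
    valid_behaviors = {b.value for b in Behavior}
    bad = ~df["behavior"].isin(valid_behaviors)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: behavior {df['behavior'].iloc[row]!r} not in {sorted(valid_behaviors)}",
            line=row + 2)
    valid_causes = {c.value for c in EndCause}
    bad = ~df["end_cause"].isin(valid_causes)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: end_cause {df['end_cause'].iloc[row]!r} not in {sorted(valid_causes)}",
            line=row + 2)
    return df


def _validate_displacement(df: pd.DataFrame, path) -> pd.DataFrame:
    df = df.copy()
    df["time_s"] = _coerce_numeric(df, "time_s", path)
    bad = df["actor_id"].astype(str) == df["receiver_id"].astype(str)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"{path}: actor_id equals receiver_id", line=row + 2)
    return df


def read_events(path, schema: str = "behavior") -> EventTable:
    """Read and validate a CSV event log.

    Parameters
    ----------
    path
        CSV file (UTF-8, comma-separated, header row required, ``.`` decimal).
    schema : {"behavior", "displacement"}
        Which table the file holds.

    Returns an :class:`EventTable` with the corresponding slot filled.  Row
    order is preserved and unknown columns are retained.  Missing columns raise
    :class:`~boutline.errors.SchemaError`; bad values raise
    :class:`~boutline.errors.ValidationError` carrying the 1-based line number.
    """
    if schema not in ("behavior", "displacement"):
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    _require_columns(df, _SCHEMAS[schema], path)
    if schema == "behavior":
        df = _validate_behavior(df, path)
        return EventTable(events=df.reset_index(drop=True))
    df = _validate_displacement(df, path)
    return EventTable(displacements=df.reset_index(drop=True))


def read_roster(path) -> pd.DataFrame:
    """Read the animal roster (animal_id, group_id, treatment, entry_time_s)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    _require_columns(df, ROSTER_COLUMNS, path)
    df = df.copy()
    df["entry_time_s"] = _coerce_numeric(df, "entry_time_s", path)
    return df.reset_index(drop=True)


def write_events(table: EventTable, path, schema: str = "behavior") -> None:
    """Write one table slot back to CSV (inverse of :func:`read_events`)."""
    df = {"behavior": table.events, "displacement": table.displacements,
          "roster": table.roster}[schema]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def load_study(events_path, displacements_path=None, roster_path=None) -> EventTable:
    """Load behavior events plus optional displacement and roster files."""
    table = read_events(events_path, "behavior")
    if displacements_path is not None:
        table.displacements = read_events(displacements_path, "displacement").displacements
    if roster_path is not None:
        table.roster = read_roster(roster_path)
    return table


# ---------------------------------------------------------------------------
# Period assignment
# ---------------------------------------------------------------------------

def _check_periods(periods) -> list[ObservationPeriod]:
    periods = sorted(periods, key=lambda p: p.start_offset_s)
    for p in periods:
        if p.end_offset_s <= p.start_offset_s:
            raise ConfigurationError(f"period {p.index}: end <= start")
    for a, b in zip(periods, periods[1:]):
        if b.start_offset_s < a.end_offset_s:
            raise ConfigurationError(
                f"periods {a.index} and {b.index} overlap")
    return periods


def assign_periods(table: EventTable,
                   periods=DEFAULT_PERIODS) -> EventTable:
    """Label events and displacements with their observation period.

    Events straddling a window boundary are clipped at the boundary and each
    fragment labeled separately; fragments outside every window get a missing
    period label.  Windows are half-open ``[start, end)``, so the within-window
    duration is conserved exactly.  Displacements, being point events, are
    labeled by containment.
    """
    periods = _check_periods(periods)
    ev = table.events
    if len(ev):
        starts = ev["start_s"].to_numpy(float)
        stops = ev["stop_s"].to_numpy(float)
        p_starts = np.array([p.start_offset_s for p in periods], dtype=float)
        p_ends = np.array([p.end_offset_s for p in periods], dtype=float)
        idx = np.searchsorted(p_starts, starts, side="right") - 1
        safe = np.clip(idx, 0, None)
        in_window = (idx >= 0) & (starts < p_ends[safe])
        # fast path: event fully contained in the window holding its start
        contained = in_window & (stops <= p_ends[safe])
        p_idx = np.array([p.index for p in periods])
        p_nov = np.array([p.novelty.value for p in periods], dtype=object)
        events = ev.copy()
        events["period"] = pd.array(
            np.where(contained, p_idx[safe], -1), dtype="Int64")
        events["novelty"] = np.where(contained, p_nov[safe], "")
        straddler = ~contained
        if straddler.any():
            frags = []
            for pos in np.flatnonzero(straddler):
                r = ev.iloc[pos]
                start, stop = starts[pos], stops[pos]
                cuts = {start, stop}
                for p in periods:
                    for edge in (p.start_offset_s, p.end_offset_s):
                        if start < edge < stop:
                            cuts.add(edge)
                cuts = sorted(cuts)
                for sub, (a, b) in enumerate(zip(cuts, cuts[1:])):
                    frag = r.copy()
                    frag["start_s"], frag["stop_s"] = a, b
                    label = next((p for p in periods if p.contains(a)), None)
                    frag["period"] = label.index if label else pd.NA
                    frag["novelty"] = label.novelty.value if label else pd.NA
                    frag["_order"] = pos + sub / 1e6
                    frags.append(frag)
            frag_df = pd.DataFrame(frags)
            frag_df["period"] = frag_df["period"].astype("Int64")
            kept = events[~straddler].copy()
            kept["_order"] = np.flatnonzero(~straddler).astype(float)
            events = (pd.concat([kept, frag_df], ignore_index=True)
                      .sort_values("_order", kind="mergesort")
                      .drop(columns="_order").reset_index(drop=True))
        events.loc[events["period"] == -1, "period"] = pd.NA
        events.loc[events["novelty"] == "", "novelty"] = pd.NA
    else:
        events = ev.copy()
        events["period"] = pd.Series(dtype="Int64")
        events["novelty"] = pd.Series(dtype=object)

    disp = table.displacements.copy()
    if len(disp):
        p_starts = np.array([p.start_offset_s for p in periods], dtype=float)
        p_ends = np.array([p.end_offset_s for p in periods], dtype=float)
        p_idx = np.array([p.index for p in periods])
        p_nov = np.array([p.novelty.value for p in periods], dtype=object)
        t = disp["time_s"].to_numpy(float)
        idx = np.searchsorted(p_starts, t, side="right") - 1
        safe = np.clip(idx, 0, None)
        inside = (idx >= 0) & (t < p_ends[safe])
        disp["period"] = pd.array(np.where(inside, p_idx[safe], -1), dtype="Int64")
        disp["novelty"] = np.where(inside, p_nov[safe], "")
        disp.loc[disp["period"] == -1, "period"] = pd.NA
        disp.loc[disp["novelty"] == "", "novelty"] = pd.NA
    else:
        disp["period"] = pd.Series(dtype="Int64")
        disp["novelty"] = pd.Series(dtype=object)
    return EventTable(events, disp, table.roster.copy(), dict(table.meta))


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_events(table: EventTable, merge_gap_s: float = 0.0) -> EventTable:
    """Merge overlapping or near-contiguous same-animal events.

    Two consecutive events of one animal are merged when the gap between them
    is <= ``merge_gap_s`` (overlaps and exact abutment always merge).  The
    merged record spans the union and keeps the behavior, brush and group of
    the longest constituent; its ``end_cause`` is that of the last constituent.
    Needed because a zero gap has no log10 and the interval extraction contract
    requires strictly positive gaps.

    The merge count is reported in ``result.meta["n_merges"]``.  After this
    operation every same-animal gap is strictly greater than ``merge_gap_s``.
    """
    ev = table.events
    if not len(ev):
        out = table.copy()
        out.meta["n_merges"] = 0
        return out
    ev = ev.sort_values(["animal_id", "start_s", "stop_s"], kind="mergesort")
    merged_rows = []
    n_merges = 0
    for _, sub in ev.groupby("animal_id", sort=False):
        cluster: list[pd.Series] = []
        cluster_stop = -np.inf
        for _, r in sub.iterrows():
            if cluster and float(r["start_s"]) - cluster_stop > merge_gap_s:
                merged_rows.append(_merge_cluster(cluster))
                n_merges += len(cluster) - 1
                cluster = []
                cluster_stop = -np.inf
            cluster.append(r)
            cluster_stop = max(cluster_stop, float(r["stop_s"]))
        if cluster:
            merged_rows.append(_merge_cluster(cluster))
            n_merges += len(cluster) - 1
    events = pd.DataFrame(merged_rows).sort_values(
        ["animal_id", "start_s"], kind="mergesort").reset_index(drop=True)
    out = EventTable(events, table.displacements.copy(), table.roster.copy(),
                     dict(table.meta))
    out.meta["n_merges"] = n_merges
    return out


def link_displacements(table: EventTable, tolerance_s: float = 1.0) -> EventTable:
    """Cross-link each displacement to the receiver event it terminated.

    A displacement matches a behavior event when the event belongs to the
    receiver at the same brush, ended as ``displaced``, and its stop time lies
    within ``tolerance_s`` of the displacement time (logs code the two streams
    separately, so timestamps may disagree by a second).  The matched event's
    row index is stored in a new ``event_index`` column; unlinked
    displacements are kept with a missing index and a warning, and their count
    reported in ``meta["n_unlinked_displacements"]``.
    """
    out = table.copy()
    disp = out.displacements
    if not len(disp):
        out.meta["n_unlinked_displacements"] = 0
        return out
    ev = out.events
    candidates = ev[ev["end_cause"] == EndCause.DISPLACED.value]
    links: list = []
    for _, d in disp.iterrows():
        sub = candidates[(candidates["animal_id"] == d["receiver_id"])
                         & (candidates["brush_id"] == d["brush_id"])]
        if len(sub):
            dt = (sub["stop_s"].astype(float) - float(d["time_s"])).abs()
            best = dt.idxmin()
            links.append(best if dt.loc[best] <= tolerance_s else pd.NA)
        else:
            links.append(pd.NA)
    disp["event_index"] = pd.array(links, dtype="Int64")
    n_unlinked = int(disp["event_index"].isna().sum())
    if n_unlinked:
        warnings.warn(f"{n_unlinked} displacement(s) could not be linked to a "
                      "receiver event; kept unlinked", stacklevel=2)
    out.meta["n_unlinked_displacements"] = n_unlinked
    return out


def _merge_cluster(cluster: list[pd.Series]) -> pd.Series:
    if len(cluster) == 1:
        return cluster[0]
    longest = max(cluster, key=lambda r: float(r["stop_s"]) - float(r["start_s"]))
    merged = longest.copy()
    merged["start_s"] = min(float(r["start_s"]) for r in cluster)
    merged["stop_s"] = max(float(r["stop_s"]) for r in cluster)
    last = max(cluster, key=lambda r: float(r["stop_s"]))
    merged["end_cause"] = last["end_cause"]
    return merged
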