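"""Displacement counting, the competitive index, and its correlation with use.

A displacement is one animal (actor) ending another's (receiver) brush contact
by physical contact.  The competitive index for an animal is

    index = 100 * n_actor / (n_actor + n_receiver)

counted over the whole study; an animal involved in no displacements has an
undefined index and is excluded from index-based analyses.  Pearson
correlations between the index and mean brush use per period are computed both
pooled and within each treatment, with the exact t-transform of r (n - 2 df)
for two-sided p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BoutlineError, InsufficientDataError
from .ethogram_io import EventTable

__all__ = [
    "CompetitiveIndex",
    "CompetitionSummary",
    "UndefinedCorrelationError",
    "count_displacements",
    "competitive_index",
    "all_competitive_indices",
    "correlate_index_use",
]


class UndefinedCorrelationError(BoutlineError):
    """One correlation input has zero variance; r is undefined."""


@dataclass
class CompetitiveIndex:
    animal_id: str
    n_actor: int
    n_receiver: int

    @property
    def involved(self) -> int:
        return self.n_actor + self.n_receiver

    @property
    def index(self) -> float | None:
        """Percent of involvements initiated, or None when uninvolved."""
        if self.involved == 0:
            return None
        return 100.0 * self.n_actor / self.involved

    @property
    def excluded(self) -> bool:
        return self.involved == 0


@dataclass
class CompetitionSummary:
    group_id: str
    period_index: int | None
    n_displacements: int
    per_brush: dict


def count_displacements(table: EventTable, group=None, period=None) -> CompetitionSummary:
    """Count displacement events in a group x period scope (None = all)."""
    disp = table.displacements
    if group is not None:
        disp = disp[disp["group_id"] == group]
    if period is not None:
        if "period" not in disp.columns:
            raise BoutlineError("displacements are not period-labeled")
        disp = disp[disp["period"] == period]
    per_brush = disp.groupby("brush_id").size().to_dict() if len(disp) else {}
    return CompetitionSummary(group_id=str(group) if group is not None else "all",
                              period_index=int(period) if period is not None else None,
                              n_displacements=int(len(disp)),
                              per_brush={str(k): int(v) for k, v in per_brush.items()})


def competitive_index(table: EventTable, animal, periods=None) -> CompetitiveIndex:
    """Actor/receiver counts and index for one animal.

    Default scope is the entire study; pass ``periods`` for the per-period
    variant.
    """
    disp = table.displacements
    if periods is not None:
        if "period" not in disp.columns:
            raise BoutlineError("displacements are not period-labeled")
        disp = disp[disp["period"].isin(set(periods))]
    n_actor = int((disp["actor_id"] == animal).sum())
    n_receiver = int((disp["receiver_id"] == animal).sum())
    return CompetitiveIndex(animal_id=str(animal), n_actor=n_actor,
                            n_receiver=n_receiver)


def all_competitive_indices(table: EventTable, periods=None) -> list[CompetitiveIndex]:
    """Competitive index for every roster animal (or every animal seen)."""
    if len(table.roster):
        animals = table.roster["animal_id"].tolist()
    else:
        animals = sorted(set(table.displacements["actor_id"])
                         | set(table.displacements["receiver_id"]))
    return [competitive_index(table, a, periods) for a in animals]


def _pearson(x: np.ndarray, y: np.ndarray) -> dict:
    if len(x) < 3:
        raise InsufficientDataError(f"{len(x)} pairs < 3 required for correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input vector; r undefined")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(x))}


def correlate_index_use(indices: list[CompetitiveIndex],
                        use_means: dict,
                        treatments: dict | None = None) -> dict:
    """Pearson correlation of competitive index vs mean brush use.

    Parameters
    ----------
    indices
        Per-animal indices; animals with an undefined index are dropped.
    use_means
        Mapping animal_id -> total brush use averaged across the observation
        periods (seconds or minutes; correlation is scale-free).
    treatments
        Optional mapping animal_id -> treatment; when given, within-treatment
        correlations are reported alongside the pooled one.

    Returns ``{"pooled": {r, p, n}, "by_treatment": {treatment: {r, p, n}}}``.
    """
    pairs = [(ci.animal_id, ci.index, use_means[ci.animal_id])
             for ci in indices
             if ci.index is not None and ci.animal_id in use_means]
    if not pairs:
        raise InsufficientDataError("no animal has both a defined index and a use value")
    animals, xs, ys = zip(*pairs)
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    out = {"pooled": _pearson(x, y), "by_treatment": {}}
    if treatments is not None:
        for trt in sorted(set(treatments.values())):
            sel = [i for i, a in enumerate(animals) if treatments.get(a) == trt]
            if sel:
                out["by_treatment"][trt] = _pearson(x[sel], y[sel])
    return out
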