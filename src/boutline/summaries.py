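"""Group-level descriptive tables and the inter-observer reliability check.

The experimental unit is the group of animals, so per-animal outputs are
averaged to one row per group x period.  Durations are reported in minutes per
6 h window, bout duration in seconds per bout.  Two standard errors are
emitted with distinct names: ``se_*_within`` is the between-animal SE inside a
group row, while figure-style error bars across groups should use the SD of
the group means themselves.

Inter-observer reliability regresses one observer's values on the other's and
requires R^2 at or above a threshold with slope and intercept not differing
from 1 and 0 (two-sided t-tests at alpha = 0.05) for a pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, DegenerateRegressionError, InsufficientDataError
from .ethogram_io import EventTable

__all__ = [
    "GroupSummary",
    "ReliabilityReport",
    "summarize_groups",
    "model_ready_table",
    "interobserver_reliability",
]


@dataclass
class GroupSummary:
    group_id: str
    treatment: str
    period_index: int
    mean_oral_min: float
    mean_groom_min: float
    mean_total_min: float
    mean_bout_frequency: float
    mean_bout_duration_s: float
    n_displacements: int
    n_animals: int


def summarize_groups(table: EventTable, bout_summaries: pd.DataFrame,
                     use: pd.DataFrame) -> pd.DataFrame:
    """One row per group x period averaging the per-animal outputs.

    ``bout_summaries`` comes from
    :func:`~boutline.bout_stats.summarize_all_bouts` and ``use`` from
    :func:`~boutline.bout_stats.all_use_durations`.  Animals flagged excluded
    are omitted from the bout-duration mean only; their bout frequency and use
    durations still contribute.  Displacement counts require period-labeled
    displacements.
    """
    roster = table.roster
    if not len(roster):
        raise ConfigurationError("roster required to define groups")
    use = use.merge(roster[["animal_id", "group_id", "treatment"]], on="animal_id")
    bouts = bout_summaries.merge(roster[["animal_id", "group_id", "treatment"]],
                                 on="animal_id")
    disp = table.displacements
    rows = []
    periods = sorted(int(p) for p in use["period"].unique())
    for (group, trt), roster_sub in roster.groupby(["group_id", "treatment"]):
        if not len(roster_sub):
            raise ConfigurationError(f"group {group!r} has no animals")
        for period in periods:
            u = use[(use["group_id"] == group) & (use["period"] == period)]
            b = bouts[(bouts["group_id"] == group) & (bouts["period"] == period)]
            b_dur = b[~b["excluded"]]
            n_disp = 0
            if len(disp) and "period" in disp.columns:
                n_disp = int(((disp["group_id"] == group)
                              & (disp["period"] == period)).sum())
            rows.append({
                "group_id": group, "treatment": trt, "period": period,
                "mean_oral_min": u["oral_s"].mean() / 60.0,
                "mean_groom_min": u["groom_s"].mean() / 60.0,
                "mean_total_min": u["total_s"].mean() / 60.0,
                "se_oral_min_within": u["oral_s"].sem() / 60.0,
                "se_groom_min_within": u["groom_s"].sem() / 60.0,
                "se_total_min_within": u["total_s"].sem() / 60.0,
                "mean_bout_frequency": (b["bout_frequency"].mean()
                                        if len(b) else float("nan")),
                "mean_bout_duration_s": (b_dur["bout_duration_s"].mean()
                                         if len(b_dur) else float("nan")),
                "n_displacements": n_disp,
                "n_animals": int(len(roster_sub)),
            })
    return pd.DataFrame(rows)


def model_ready_table(group_summary: pd.DataFrame) -> pd.DataFrame:
    """Long-format (group, treatment, period, variable, value) export for
    external mixed-model tools."""
    value_cols = ["mean_oral_min", "mean_groom_min", "mean_total_min",
                  "mean_bout_frequency", "mean_bout_duration_s",
                  "n_displacements"]
    return group_summary.melt(
        id_vars=["group_id", "treatment", "period"], value_vars=value_cols,
        var_name="variable", value_name="value").sort_values(
        ["variable", "group_id", "period"]).reset_index(drop=True)


@dataclass
class ReliabilityReport:
    r_squared: float
    slope: float
    intercept: float
    p_slope_eq_1: float
    p_intercept_eq_0: float
    r2_threshold: float

    @property
    def passed(self) -> bool:
        return (self.r_squared >= self.r2_threshold
                and self.p_slope_eq_1 > 0.05
                and self.p_intercept_eq_0 > 0.05)


def interobserver_reliability(paired, r2_threshold: float = 0.89) -> ReliabilityReport:
    """OLS of observer B on observer A with agreement tests.

    ``paired`` is a sequence of ``(observer_a_value, observer_b_value)``.
    Tests slope = 1 and intercept = 0 via t-statistics on the OLS estimates;
    passing requires R^2 >= ``r2_threshold`` and both p-values > 0.05
    (agreement without systematic bias).
    """
    arr = np.asarray(list(paired), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise InsufficientDataError("need at least 3 (a, b) pairs")
    a, b = arr[:, 0], arr[:, 1]
    if np.ptp(a) == 0:
        raise DegenerateRegressionError("observer A values are constant")
    model = sm.OLS(b, sm.add_constant(a)).fit()
    intercept, slope = model.params
    # identical observers: zero residual variance makes the t-tests 0/0;
    # perfect agreement passes by definition
    if model.ssr <= 1e-12 * max(1.0, float(np.sum(b ** 2))):
        p_slope = 1.0 if abs(slope - 1) < 1e-8 else 0.0
        p_int = 1.0 if abs(intercept) < 1e-8 else 0.0
    else:
        p_slope = float(model.t_test("x1 = 1").pvalue)
        p_int = float(model.t_test("const = 0").pvalue)
    return ReliabilityReport(r_squared=float(model.rsquared), slope=float(slope),
                             intercept=float(intercept), p_slope_eq_1=p_slope,
                             p_intercept_eq_0=p_int, r2_threshold=r2_threshold)
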