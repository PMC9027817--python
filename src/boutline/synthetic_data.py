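"""Synthetic brush-use study generator with exact ground-truth bookkeeping.

Each animal x observation-period stream is an alternating renewal process on
two timescales: bouts of brush use whose internal pauses are short, separated
by long between-bout breaks.  Within-bout and between-bout gaps are drawn
log10-normally with well-separated means, so the pooled log10 gaps follow the
exact two-component normal mixture the criterion estimator assumes; events per
bout are geometric (mean ``events_per_bout_mean``, single-event bouts
possible), event durations gamma, behavior a groom/oral Bernoulli, and each
event may end in a displacement by a random group mate.

Defaults are the *paper-like* operating point: 4 groups of 8 animals per
brush-quantity treatment (2 vs 4 brushes), four 6 h windows, ~15-18 bouts per
animal per window of ~30 s each, a ~3:1 groom:oral duration ratio, roughly one
displacement per group-hour, and a 75% preference for feeder-side brushes in
the 4-brush treatment.

The generator keeps exact ledgers (per-animal durations, per-group
displacement counts, per-animal bouts) and the analytic criterion implied by
its own parameters, so every downstream stage can be tested against ground
truth rather than re-estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .bout_criterion import MixtureFit, intersection_criterion
from .ethogram_io import DEFAULT_PERIODS, EventTable, Treatment

__all__ = ["SimConfig", "SimTruth", "simulate_study", "analytic_truth",
           "paper_like_config", "load_config", "save_config"]

LOG10 = math.log(10.0)


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the paper-like operating point."""

    n_groups_per_treatment: int = 4
    group_size: int = 8
    n_brushes: dict = field(default_factory=lambda: {"two_brush": 2, "four_brush": 4})
    period_length_s: float = 21600.0
    # log10-seconds of the two gap regimes
    mu_intra: float = 0.6
    sigma_intra: float = 0.25
    mu_inter: float = 2.95
    sigma_inter: float = 0.35
    events_per_bout_mean: float = 3.0
    # gamma event durations, seconds (mean = shape * scale)
    event_duration_shape: float = 2.0
    event_duration_scale: float = 4.0
    p_groom: float = 0.75
    p_displacement_per_event: float = 0.015
    brush_preference_near_feeder: float = 0.75
    gap_distribution: str = "log10_normal"   # or "exponential" (misspecified)
    dominance_exponent: float = 0.0          # 0 -> uniform actor choice
    seed: int = 0

    def validate(self) -> None:
        if self.n_groups_per_treatment < 1:
            raise ConfigurationError("n_groups_per_treatment must be >= 1")
        if self.group_size < 2:
            raise ConfigurationError("group_size must be >= 2 (actors need a target)")
        if set(self.n_brushes) != {"two_brush", "four_brush"}:
            raise ConfigurationError("n_brushes must map the two treatments")
        if self.period_length_s <= 0:
            raise ConfigurationError("period_length_s must be positive")
        if not self.mu_intra < self.mu_inter:
            raise ConfigurationError("mu_intra must be below mu_inter")
        if self.sigma_intra <= 0 or self.sigma_inter <= 0:
            raise ConfigurationError("sigmas must be positive")
        if self.events_per_bout_mean <= 1:
            raise ConfigurationError("events_per_bout_mean must exceed 1")
        if self.event_duration_shape <= 0 or self.event_duration_scale <= 0:
            raise ConfigurationError("gamma duration parameters must be positive")
        for name in ("p_groom", "p_displacement_per_event",
                     "brush_preference_near_feeder"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.gap_distribution not in ("log10_normal", "exponential"):
            raise ConfigurationError(
                f"unknown gap_distribution {self.gap_distribution!r}")


def paper_like_config(seed: int = 0, **overrides) -> SimConfig:
    """The default study-scale configuration (see module docstring)."""
    return replace(SimConfig(seed=seed), **overrides)


@dataclass
class SimTruth:
    """Exact bookkeeping of one generated study.

    Ledgers record what was generated, not re-estimates: ``use_ledger`` has
    groom/oral seconds per animal x period, ``displacement_ledger`` counts per
    group x period, ``involvement_ledger`` actor/receiver counts per animal,
    and ``bout_ledger`` generated bouts and their total time per
    animal x period.
    """

    true_log10_criterion: float
    true_criterion_s: float
    pi_intra: float
    use_ledger: pd.DataFrame
    displacement_ledger: pd.DataFrame
    involvement_ledger: pd.DataFrame
    bout_ledger: pd.DataFrame

    def as_dict(self) -> dict:
        return {
            "true_log10_criterion": self.true_log10_criterion,
            "true_criterion_s": self.true_criterion_s,
            "pi_intra": self.pi_intra,
            "use_ledger": self.use_ledger.to_dict(orient="records"),
            "displacement_ledger": self.displacement_ledger.to_dict(orient="records"),
            "involvement_ledger": self.involvement_ledger.to_dict(orient="records"),
            "bout_ledger": self.bout_ledger.to_dict(orient="records"),
        }


# ---------------------------------------------------------------------------
# Analytic ground truth
# ---------------------------------------------------------------------------

def _log10_normal_mean(mu: float, sigma: float) -> float:
    """Mean of 10**Normal(mu, sigma) in seconds."""
    return 10.0 ** mu * math.exp((LOG10 * sigma) ** 2 / 2.0)


def expected_mixture_weight(cfg: SimConfig) -> float:
    """Implied intra-bout weight among *observed* gaps, truncation-adjusted.

    A bout of k events contributes k-1 intra gaps; bouts observed in one
    window contribute one fewer inter gap than there are bouts (the gap after
    the last bout falls outside the window).  With m = events_per_bout_mean
    and B expected bouts per window this gives

        pi_intra = (m - 1) B / ((m - 1) B + (B - 1)),

    which tends to (m - 1) / m as the window grows.
    """
    m = cfg.events_per_bout_mean
    e_dur = cfg.event_duration_shape * cfg.event_duration_scale
    e_intra = _log10_normal_mean(cfg.mu_intra, cfg.sigma_intra)
    e_inter = _log10_normal_mean(cfg.mu_inter, cfg.sigma_inter)
    cycle = m * e_dur + (m - 1.0) * e_intra + e_inter
    b = cfg.period_length_s / cycle
    if b <= 1.0:
        return (m - 1.0) / m
    return (m - 1.0) * b / ((m - 1.0) * b + (b - 1.0))


def analytic_truth(cfg: SimConfig) -> SimTruth:
    """Criterion implied by the configuration, via the same density-crossing
    quadratic the estimator uses; ledgers are empty (no stream generated)."""
    cfg.validate()
    pi = expected_mixture_weight(cfg)
    fit = MixtureFit(mu_intra=cfg.mu_intra, sigma_intra=cfg.sigma_intra,
                     mu_inter=cfg.mu_inter, sigma_inter=cfg.sigma_inter,
                     pi_intra=pi)
    crit = intersection_criterion(fit)
    empty = pd.DataFrame()
    return SimTruth(true_log10_criterion=crit.log10_criterion,
                    true_criterion_s=crit.criterion_s, pi_intra=pi,
                    use_ledger=empty, displacement_ledger=empty,
                    involvement_ledger=empty, bout_ledger=empty)


# ---------------------------------------------------------------------------
# Stream generation
# ---------------------------------------------------------------------------

def _draw_gap(rng: np.random.Generator, mu: float, sigma: float,
              distribution: str) -> float:
    if distribution == "log10_normal":
        return 10.0 ** rng.normal(mu, sigma)
    # misspecified mode: exponential with the matched mean
    return rng.exponential(_log10_normal_mean(mu, sigma))


def _brush_ids(treatment: str, n: int) -> list[str]:
    # feeder-side brushes first; in the 2-brush layout both sit near the feeder
    half = n if treatment == "two_brush" else n // 2
    return ([f"feeder_{i + 1}" for i in range(half)]
            + [f"gate_{i + 1}" for i in range(n - half)])


def _choose_brush(rng, treatment, brushes, pref):
    if treatment == "two_brush":
        return brushes[rng.integers(len(brushes))]
    n_feeder = sum(1 for b in brushes if b.startswith("feeder"))
    if rng.random() < pref:
        return brushes[rng.integers(n_feeder)]
    return brushes[n_feeder + rng.integers(len(brushes) - n_feeder)]


def simulate_study(cfg: SimConfig) -> tuple[EventTable, SimTruth]:
    """Generate a full study: events, displacements, roster, and truth.

    Each animal has its own random substream keyed by ``(cfg.seed, animal
    index)``, so enlarging the study does not perturb the streams of existing
    animals; identical configurations yield identical output.
    """
    cfg.validate()
    events, displacements, roster = [], [], []
    use_rows, bout_rows = [], []
    animal_index = 0
    for treatment in (Treatment.TWO_BRUSH.value, Treatment.FOUR_BRUSH.value):
        short = "2B" if treatment == "two_brush" else "4B"
        brushes = _brush_ids(treatment, cfg.n_brushes[treatment])
        for g in range(cfg.n_groups_per_treatment):
            group_id = f"{short}-G{g + 1}"
            animal_ids = [f"{group_id}-A{a + 1}" for a in range(cfg.group_size)]
            for a, animal_id in enumerate(animal_ids):
                roster.append({"animal_id": animal_id, "group_id": group_id,
                               "treatment": treatment, "entry_time_s": 0.0})
                rng = np.random.Generator(np.random.PCG64(
                    np.random.SeedSequence((cfg.seed, animal_index))))
                animal_index += 1
                for period in DEFAULT_PERIODS:
                    _simulate_animal_period(
                        cfg, rng, animal_id, a, animal_ids, group_id, treatment,
                        brushes, period, events, displacements, use_rows,
                        bout_rows)
    events_df = pd.DataFrame(events, columns=[
        "animal_id", "group_id", "treatment", "behavior", "brush_id",
        "start_s", "stop_s", "end_cause"])
    disp_df = pd.DataFrame(displacements, columns=[
        "actor_id", "receiver_id", "brush_id", "time_s", "group_id"])
    roster_df = pd.DataFrame(roster)
    table = EventTable(events=events_df, displacements=disp_df, roster=roster_df)

    truth = analytic_truth(cfg)
    truth.use_ledger = (pd.DataFrame(use_rows)
                        .groupby(["animal_id", "period"], as_index=False)
                        [["groom_s", "oral_s"]].sum())
    if len(disp_df):
        labels = [_period_of(t) for t in disp_df["time_s"]]
        truth.displacement_ledger = (
            pd.DataFrame({"group_id": disp_df["group_id"], "period": labels})
            .groupby(["group_id", "period"], as_index=False).size()
            .rename(columns={"size": "n_displacements"}))
        actor = disp_df.groupby("actor_id").size()
        recv = disp_df.groupby("receiver_id").size()
        inv = pd.DataFrame({
            "animal_id": roster_df["animal_id"],
            "n_actor": [int(actor.get(a, 0)) for a in roster_df["animal_id"]],
            "n_receiver": [int(recv.get(a, 0)) for a in roster_df["animal_id"]],
        })
        truth.involvement_ledger = inv
    else:
        truth.displacement_ledger = pd.DataFrame(
            columns=["group_id", "period", "n_displacements"])
        truth.involvement_ledger = pd.DataFrame({
            "animal_id": roster_df["animal_id"], "n_actor": 0, "n_receiver": 0})
    truth.bout_ledger = pd.DataFrame(
        bout_rows, columns=["animal_id", "period", "n_bouts", "total_time_s"])
    return table, truth


def _period_of(t: float):
    for p in DEFAULT_PERIODS:
        if p.contains(float(t)):
            return p.index
    return None


def _simulate_animal_period(cfg, rng, animal_id, a_idx, animal_ids, group_id,
                            treatment, brushes, period, events, displacements,
                            use_rows, bout_rows):
    L = cfg.period_length_s
    offset = period.start_offset_s
    # forward-recurrence-style initial delay: the window opens at an arbitrary
    # point of the ongoing renewal process
    t = rng.random() * _draw_gap(rng, cfg.mu_inter, cfg.sigma_inter,
                                 cfg.gap_distribution)
    groom_s = oral_s = 0.0
    n_bouts = 0
    total_time = 0.0
    mates = [x for x in animal_ids if x != animal_id]
    if cfg.dominance_exponent:
        w = np.array([(animal_ids.index(x) + 1.0) ** cfg.dominance_exponent
                      for x in mates])
        actor_p = w / w.sum()
    else:
        actor_p = None
    while t < L:
        k = 1 + int(rng.geometric(1.0 / cfg.events_per_bout_mean)) - 1
        bout_event_time = 0.0
        bout_gap_time = 0.0
        n_kept = 0
        truncated = False
        for j in range(k):
            dur = rng.gamma(cfg.event_duration_shape, cfg.event_duration_scale)
            if t + dur > L:
                truncated = True
                break
            behavior = "groom" if rng.random() < cfg.p_groom else "oral"
            brush = _choose_brush(rng, treatment, brushes,
                                  cfg.brush_preference_near_feeder)
            displaced = rng.random() < cfg.p_displacement_per_event
            events.append({
                "animal_id": animal_id, "group_id": group_id,
                "treatment": treatment, "behavior": behavior,
                "brush_id": brush, "start_s": offset + t,
                "stop_s": offset + t + dur,
                "end_cause": "displaced" if displaced else "voluntary"})
            if displaced:
                if actor_p is None:
                    actor = mates[rng.integers(len(mates))]
                else:
                    actor = mates[rng.choice(len(mates), p=actor_p)]
                displacements.append({
                    "actor_id": actor, "receiver_id": animal_id,
                    "brush_id": brush, "time_s": offset + t + dur,
                    "group_id": group_id})
            if behavior == "groom":
                groom_s += dur
            else:
                oral_s += dur
            bout_event_time += dur
            n_kept += 1
            t += dur
            if j < k - 1:
                gap = _draw_gap(rng, cfg.mu_intra, cfg.sigma_intra,
                                cfg.gap_distribution)
                if t + gap >= L:
                    truncated = True
                    t += gap
                    break
                bout_gap_time += gap
                t += gap
        if n_kept:
            n_bouts += 1
            total_time += bout_event_time + bout_gap_time
        if truncated:
            break
        t += _draw_gap(rng, cfg.mu_inter, cfg.sigma_inter, cfg.gap_distribution)
    use_rows.append({"animal_id": animal_id, "period": period.index,
                     "groom_s": groom_s, "oral_s": oral_s})
    bout_rows.append({"animal_id": animal_id, "period": period.index,
                      "n_bouts": n_bouts, "total_time_s": total_time})


# ---------------------------------------------------------------------------
# Config (de)serialization for the CLI
# ---------------------------------------------------------------------------

def load_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = SimConfig(**data)
    cfg.validate()
    return cfg


def save_config(cfg: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
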