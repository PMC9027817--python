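"""Inter-bout criterion estimation.

Brush use arrives as short events separated by pauses on two timescales:
pauses *within* a bout (seconds) and breaks *between* bouts (minutes).  On a
log10 scale the pooled inter-event intervals are well described by a mixture
of two normal densities,

    f(x) = pi_1 N(x; mu_1, s_1) + (1 - pi_1) N(x; mu_2, s_2),   mu_1 < mu_2,

fitted here by maximum likelihood via EM.  The inter-bout criterion is the
point between the two means where the weighted component densities cross,

    pi_1 N(x; mu_1, s_1) = pi_2 N(x; mu_2, s_2),

a quadratic in x when the standard deviations differ and linear when they are
equal; the criterion in seconds is 10**x.  Gaps shorter than the criterion are
within-bout pauses, longer gaps separate bouts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import (ContractError, DegenerateFitError, InsufficientDataError,
                     IntersectionNotFoundError)
from .ethogram_io import EventTable, Novelty

__all__ = [
    "IntervalSet",
    "MixtureFit",
    "BoutCriterion",
    "FitOptions",
    "CriteriaReport",
    "extract_intervals",
    "fit_log_mixture",
    "intersection_criterion",
    "pooled_criteria",
]

LOG10 = math.log(10.0)


# ---------------------------------------------------------------------------
# Interval extraction
# ---------------------------------------------------------------------------

@dataclass
class IntervalSet:
    """Positive inter-event gaps pooled over an animal-set x period-set scope."""

    scope: str
    gaps_s: np.ndarray

    def __post_init__(self):
        self.gaps_s = np.asarray(self.gaps_s, dtype=float)

    @property
    def log10_gaps(self) -> np.ndarray:
        return np.log10(self.gaps_s)

    @property
    def n(self) -> int:
        return self.gaps_s.size


def extract_intervals(table: EventTable, animals=None, periods=None) -> IntervalSet:
    """Pool inter-event gaps for the requested animals and periods.

    Gaps are formed independently within each animal x period (start of event
    k+1 minus stop of event k, any brush, any behavior) and then pooled; no
    gap ever spans two animals or two periods.  Events must be normalized and
    period-labeled first; a non-positive gap therefore indicates a breached
    normalization contract and raises :class:`ContractError`.
    """
    ev = table.events
    if "period" not in ev.columns:
        raise ContractError("events are not period-labeled; run assign_periods first")
    ev = ev[ev["period"].notna()]
    if animals is not None:
        ev = ev[ev["animal_id"].isin(set(animals))]
    if periods is not None:
        ev = ev[ev["period"].isin(set(periods))]
    gaps: list[np.ndarray] = []
    for (_, _), sub in ev.groupby(["animal_id", "period"], sort=False):
        if len(sub) < 2:
            continue
        sub = sub.sort_values("start_s", kind="mergesort")
        g = sub["start_s"].to_numpy(float)[1:] - sub["stop_s"].to_numpy(float)[:-1]
        if (g <= 0).any():
            raise ContractError(
                "non-positive inter-event gap; events were not normalized")
        gaps.append(g)
    pooled = np.concatenate(gaps) if gaps else np.empty(0)
    scope = (f"animals={'all' if animals is None else sorted(set(animals))}, "
             f"periods={'all' if periods is None else sorted(set(periods))}")
    return IntervalSet(scope=scope, gaps_s=pooled)


# ---------------------------------------------------------------------------
# Two-component normal mixture fit (EM)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitOptions:
    """Tuning knobs for :func:`fit_log_mixture`.

    ``mode="raw"`` runs EM on the individual log10 gaps; ``mode="binned"``
    maximizes the grouped-data likelihood of histogram counts with the given
    bin width (0.1 log10 units mirrors the granularity at which such interval
    histograms are conventionally displayed and fitted).
    """

    mode: str = "raw"               # "raw" | "binned"
    bin_width: float = 0.1          # log10 units, binned mode only
    tol: float = 1e-8               # relative loglik change for convergence
    max_iter: int = 500
    min_n: int = 10                 # floor on number of gaps
    sigma_floor: float = 1e-3       # log10 units
    pi_floor: float = 0.02


@dataclass
class MixtureFit:
    """Fitted two-component normal mixture on log10 seconds.

    Component 1 is always the within-bout (shorter-gap) component:
    ``mu_intra < mu_inter`` after relabeling.
    """

    mu_intra: float
    sigma_intra: float
    mu_inter: float
    sigma_inter: float
    pi_intra: float
    loglik: float = float("nan")
    n: int = 0
    converged: bool = True
    n_iter: int = 0
    mode: str = "raw"
    loglik_trace: tuple = ()   # per-iteration loglik (raw EM mode only)

    @property
    def pi_inter(self) -> float:
        return 1.0 - self.pi_intra

    def pdf(self, x) -> np.ndarray:
        """Mixture density on the log10 scale."""
        x = np.asarray(x, dtype=float)
        return (self.pi_intra * stats.norm.pdf(x, self.mu_intra, self.sigma_intra)
                + self.pi_inter * stats.norm.pdf(x, self.mu_inter, self.sigma_inter))

    def component_pdfs(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Weighted component densities (intra, inter) on the log10 scale."""
        x = np.asarray(x, dtype=float)
        return (self.pi_intra * stats.norm.pdf(x, self.mu_intra, self.sigma_intra),
                self.pi_inter * stats.norm.pdf(x, self.mu_inter, self.sigma_inter))

    def as_dict(self) -> dict:
        return {
            "mu_intra": self.mu_intra, "sigma_intra": self.sigma_intra,
            "mu_inter": self.mu_inter, "sigma_inter": self.sigma_inter,
            "pi_intra": self.pi_intra, "loglik": self.loglik, "n": self.n,
            "converged": self.converged, "n_iter": self.n_iter, "mode": self.mode,
        }


def _check_degenerate(mu1, s1, mu2, s2, pi1, opts: FitOptions) -> None:
    if s1 < opts.sigma_floor:
        raise DegenerateFitError(
            f"sigma_intra = {s1:.3g} below floor {opts.sigma_floor}",
            parameter="sigma_intra")
    if s2 < opts.sigma_floor:
        raise DegenerateFitError(
            f"sigma_inter = {s2:.3g} below floor {opts.sigma_floor}",
            parameter="sigma_inter")
    if not (opts.pi_floor < pi1 < 1.0 - opts.pi_floor):
        raise DegenerateFitError(
            f"pi_intra = {pi1:.3g} outside ({opts.pi_floor}, {1 - opts.pi_floor})",
            parameter="pi_intra")


def _median_split_init(x: np.ndarray, opts: FitOptions):
    """Deterministic starting point: split at the median, moments per half."""
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if len(lo) < 2 or len(hi) < 2:
        raise DegenerateFitError("median split leaves an empty half",
                                 parameter="init")
    mu1, s1 = float(np.mean(lo)), float(np.std(lo))
    mu2, s2 = float(np.mean(hi)), float(np.std(hi))
    s1 = max(s1, opts.sigma_floor)
    s2 = max(s2, opts.sigma_floor)
    return mu1, s1, mu2, s2, 0.5


def _em_raw(x: np.ndarray, opts: FitOptions):
    mu1, s1, mu2, s2, pi1 = _median_split_init(x, opts)
    if np.ptp(x) == 0:
        raise DegenerateFitError("all gaps identical (zero variance)",
                                 parameter="sigma_intra")
    loglik = -np.inf
    converged = False
    it = 0
    trace = []
    for it in range(1, opts.max_iter + 1):
        # E-step via logsumexp for stability
        la = np.log(pi1) + stats.norm.logpdf(x, mu1, s1)
        lb = np.log1p(-pi1) + stats.norm.logpdf(x, mu2, s2)
        m = np.maximum(la, lb)
        lse = m + np.log(np.exp(la - m) + np.exp(lb - m))
        new_loglik = float(np.sum(lse))
        # EM guarantees a non-decreasing likelihood; a decrease beyond float
        # noise means the update is wrong, so it is asserted every iteration.
        if new_loglik < loglik - 1e-8 * max(1.0, abs(loglik)):
            raise AssertionError(
                f"EM log-likelihood decreased: {loglik} -> {new_loglik}")
        rel_change = abs(new_loglik - loglik) / max(1.0, abs(new_loglik))
        loglik = new_loglik
        trace.append(loglik)
        r1 = np.exp(la - lse)
        # M-step
        w1 = float(np.sum(r1))
        w2 = float(len(x) - w1)
        if w1 <= 0 or w2 <= 0:
            raise DegenerateFitError("a component lost all weight",
                                     parameter="pi_intra")
        pi1 = w1 / len(x)
        mu1 = float(np.sum(r1 * x) / w1)
        mu2 = float(np.sum((1 - r1) * x) / w2)
        s1 = math.sqrt(max(float(np.sum(r1 * (x - mu1) ** 2) / w1),
                           opts.sigma_floor ** 2))
        s2 = math.sqrt(max(float(np.sum((1 - r1) * (x - mu2) ** 2) / w2),
                           opts.sigma_floor ** 2))
        if rel_change < opts.tol and it > 1:
            converged = True
            break
    return mu1, s1, mu2, s2, pi1, loglik, converged, it, tuple(trace)


def _binned_negloglik(theta, edges, counts):
    mu1, ls1, mu2, ls2, logit_pi = theta
    s1, s2 = math.exp(ls1), math.exp(ls2)
    pi1 = 1.0 / (1.0 + math.exp(-logit_pi))
    cdf = (pi1 * stats.norm.cdf(edges, mu1, s1)
           + (1 - pi1) * stats.norm.cdf(edges, mu2, s2))
    p = np.diff(cdf)
    p = np.clip(p, 1e-300, None)
    return -float(np.sum(counts * np.log(p)))


def _fit_binned(x: np.ndarray, opts: FitOptions):
    w = opts.bin_width
    lo = math.floor(x.min() / w) * w
    hi = math.ceil(x.max() / w) * w
    nbins = max(int(round((hi - lo) / w)), 1)
    edges = lo + w * np.arange(nbins + 1)
    counts, _ = np.histogram(x, bins=edges)
    mu1, s1, mu2, s2, pi1 = _median_split_init(x, opts)
    theta0 = np.array([mu1, math.log(s1), mu2, math.log(s2), 0.0])
    res = optimize.minimize(
        _binned_negloglik, theta0, args=(edges, counts), method="Nelder-Mead",
        options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-10})
    mu1, ls1, mu2, ls2, logit_pi = res.x
    s1, s2 = math.exp(ls1), math.exp(ls2)
    pi1 = 1.0 / (1.0 + math.exp(-logit_pi))
    return mu1, s1, mu2, s2, pi1, -res.fun, bool(res.success), int(res.nit)


def fit_log_mixture(iv: IntervalSet, opts: FitOptions | None = None) -> MixtureFit:
    """Maximum-likelihood two-component normal fit to log10 gaps.

    Raw mode runs EM with a deterministic median-split start; binned mode
    maximizes the grouped-data (histogram) likelihood at ``opts.bin_width``.
    Components are relabeled so ``mu_intra < mu_inter``.  Raises
    :class:`InsufficientDataError` below ``opts.min_n`` gaps and
    :class:`DegenerateFitError` when a variance or weight collapses.
    """
    opts = opts or FitOptions()
    if iv.n < opts.min_n:
        raise InsufficientDataError(
            f"{iv.n} gaps < required minimum {opts.min_n} ({iv.scope})")
    x = iv.log10_gaps
    if np.ptp(x) == 0:
        raise DegenerateFitError("all gaps identical (zero variance)",
                                 parameter="sigma_intra")
    trace: tuple = ()
    if opts.mode == "raw":
        mu1, s1, mu2, s2, pi1, ll, conv, it, trace = _em_raw(x, opts)
    elif opts.mode == "binned":
        mu1, s1, mu2, s2, pi1, ll, conv, it = _fit_binned(x, opts)
    else:
        raise ValueError(f"unknown fit mode {opts.mode!r}")
    if mu1 > mu2:  # relabel: component 1 is the short-gap component
        mu1, s1, mu2, s2, pi1 = mu2, s2, mu1, s1, 1.0 - pi1
    _check_degenerate(mu1, s1, mu2, s2, pi1, opts)
    return MixtureFit(mu_intra=mu1, sigma_intra=s1, mu_inter=mu2,
                      sigma_inter=s2, pi_intra=pi1, loglik=ll, n=iv.n,
                      converged=conv, n_iter=it, mode=opts.mode,
                      loglik_trace=trace)


# ---------------------------------------------------------------------------
# Density intersection -> criterion
# ---------------------------------------------------------------------------

@dataclass
class BoutCriterion:
    """Inter-bout criterion: the log10 crossing point and its back-transform."""

    log10_criterion: float
    novelty_scope: str = "custom"
    rounding: str = "none"          # "none" | "paper_mode"

    @property
    def criterion_s(self) -> float:
        return 10.0 ** self.log10_criterion


def intersection_criterion(fit: MixtureFit, rounding: str = "none") -> BoutCriterion:
    """Solve for the crossing of the weighted component densities.

    Equating ``pi_1 N(x; mu_1, s_1) = pi_2 N(x; mu_2, s_2)`` and taking logs
    gives ``a x^2 + b x + c = 0`` with

        a = 1/(2 s_2^2) - 1/(2 s_1^2)
        b = mu_1/s_1^2 - mu_2/s_2^2
        c = mu_2^2/(2 s_2^2) - mu_1^2/(2 s_1^2) + log(pi_1 s_2 / (pi_2 s_1))

    For equal sigmas the equation is linear; with equal weights as well the
    root is exactly the mid-point of the means.  Only the root strictly
    between the two means separates the regimes; if no real root lies there
    (components too overlapped) :class:`IntersectionNotFoundError` is raised.

    ``rounding="paper_mode"`` rounds the log10 crossing to one decimal before
    back-transforming, so every reported criterion is a power of 10**0.1.
    """
    if not fit.converged:
        raise ContractError("mixture fit did not converge; criterion undefined")
    mu1, s1 = fit.mu_intra, fit.sigma_intra
    mu2, s2 = fit.mu_inter, fit.sigma_inter
    pi1, pi2 = fit.pi_intra, fit.pi_inter
    if s1 == s2:
        # linear case, rearranged so the symmetric crossing is exact:
        # x = (mu1 + mu2)/2 + s^2 log(pi1/pi2) / (mu2 - mu1)
        if mu1 == mu2:
            raise IntersectionNotFoundError("identical components; no crossing")
        roots = [(mu1 + mu2) / 2.0
                 + s1 ** 2 * math.log(pi1 / pi2) / (mu2 - mu1)]
    else:
        a = 1.0 / (2 * s2 ** 2) - 1.0 / (2 * s1 ** 2)
        b = mu1 / s1 ** 2 - mu2 / s2 ** 2
        c = (mu2 ** 2 / (2 * s2 ** 2) - mu1 ** 2 / (2 * s1 ** 2)
             + math.log(pi1 * s2 / (pi2 * s1)))
        disc = b * b - 4 * a * c
        if disc < 0:
            raise IntersectionNotFoundError(
                "no real root: component densities do not cross")
        sq = math.sqrt(disc)
        roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = [r for r in roots if mu1 < r < mu2]
    if not inside:
        raise IntersectionNotFoundError(
            f"no crossing strictly between the means ({mu1:.3g}, {mu2:.3g}); "
            "components too overlapped")
    x = inside[0]
    if rounding == "paper_mode":
        x = round(x * 10.0) / 10.0
    elif rounding != "none":
        raise ValueError(f"unknown rounding {rounding!r}")
    return BoutCriterion(log10_criterion=x, rounding=rounding)


# ---------------------------------------------------------------------------
# Pooled (novel / non-novel) criteria
# ---------------------------------------------------------------------------

NOVELTY_PERIODS = {Novelty.NOVEL: (1, 2), Novelty.NON_NOVEL: (3, 4)}


@dataclass
class CriteriaReport:
    """Per-period diagnostic fits plus the two pooled criteria actually used."""

    per_period: dict = field(default_factory=dict)   # period -> (fit, criterion)
    pooled: dict = field(default_factory=dict)       # novelty -> (fit, criterion)

    def criterion_for(self, novelty) -> BoutCriterion:
        key = Novelty(novelty)
        return self.pooled[key][1]

    def as_dict(self) -> dict:
        return {
            "per_period": {
                str(p): {"fit": f.as_dict(),
                         "criterion_s": c.criterion_s,
                         "log10_criterion": c.log10_criterion}
                for p, (f, c) in self.per_period.items()},
            "pooled": {
                k.value: {"fit": f.as_dict(),
                          "criterion_s": c.criterion_s,
                          "log10_criterion": c.log10_criterion}
                for k, (f, c) in self.pooled.items()},
        }


def pooled_criteria(table: EventTable, opts: FitOptions | None = None,
                    rounding: str = "none") -> CriteriaReport:
    """Fit per-period criteria (diagnostics) and the two pooled criteria.

    Intervals are pooled across all animals within each period for the
    per-period fits, and within each novelty class (periods 1-2 novel,
    3-4 non-novel) for the final criteria used in bout segmentation.
    """
    report = CriteriaReport()
    for period in (1, 2, 3, 4):
        iv = extract_intervals(table, periods=[period])
        fit = fit_log_mixture(iv, opts)
        crit = intersection_criterion(fit, rounding)
        report.per_period[period] = (fit, crit)
    for novelty, periods in NOVELTY_PERIODS.items():
        iv = extract_intervals(table, periods=list(periods))
        fit = fit_log_mixture(iv, opts)
        crit = intersection_criterion(fit, rounding)
        crit.novelty_scope = novelty.value
        report.pooled[novelty] = (fit, crit)
    return report
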