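# Methods

## The bout model

Resource-use behavior is modelled as an alternating renewal process: an animal
performs runs ("bouts") of short contact events whose internal pauses come
from a fast regime, separated by long breaks from a slow regime. When both gap
regimes are log-normal on base 10 — intra-bout gaps 10^N(μ₁, σ₁), inter-bout
gaps 10^N(μ₂, σ₂) — the pooled log10 inter-event intervals follow a
two-component normal mixture

f(x) = π₁ N(x; μ₁, σ₁) + π₂ N(x; μ₂, σ₂),  π₂ = 1 − π₁,  μ₁ < μ₂,

with π₁ the fraction of observed gaps that are intra-bout. The inter-bout
criterion is the point between the means where the weighted component
densities cross: gaps shorter than 10^x* are more likely intra-bout than
inter-bout. Equating the weighted densities and taking logs yields a quadratic
in x,

a x² + b x + c = 0,  a = 1/(2σ₂²) − 1/(2σ₁²),  b = μ₁/σ₁² − μ₂/σ₂²,
c = μ₂²/(2σ₂²) − μ₁²/(2σ₁²) + log(π₁σ₂ / (π₂σ₁)),

whose root strictly inside (μ₁, μ₂) is the criterion; the other quadratic root
(where the heavier tail of one component re-crosses the other) does not
separate the regimes and is discarded. With equal σ the equation degenerates
to the linear closed form x* = (μ₁+μ₂)/2 + σ² log(π₁/π₂)/(μ₂−μ₁), implemented
directly so the symmetric case is exact to the last bit. If no real root lies
between the means the components are too overlapped for a meaningful
criterion and the operation fails loudly rather than guessing.

Segmentation applies the criterion with a strict inequality: a pause shorter
than the criterion continues the bout, a pause equal to or longer than it
starts a new bout. Bout *total time* is observed contact time plus intra-bout
pauses; *bout frequency* defaults to the number of bouts in the window;
*bout duration* is total time / frequency. Animals with a single event in a
window, or with no sub-criterion gap at all, give no information about bout
interiors and are flagged excluded for total time and bout duration (their
frequency is still reported). A `frequency_convention` switch provides the
alternative bouts − 1 reading ("number of intervals between bouts"); the
default counts bouts, the only convention consistent with duration =
total/frequency and with the magnitudes such studies report (order 12–19 per
6 h window).

## Estimation

The mixture is fitted by maximum likelihood with EM on the raw log10 gaps.
Initialization is deterministic and seed-free: split the sample at its median
and take each half's moments, with equal starting weights. Convergence is a
relative log-likelihood change below 1e−8 (cap 500 iterations); the
monotonicity of the EM objective is asserted at every iteration. Guard rails:
a minimum of 10 gaps, a σ floor of 1e−3 log10 units and a weight floor of
0.02 — breaching a floor raises a degenerate-fit error naming the offending
parameter instead of returning a collapsed solution. Components are relabeled
after fitting so component 1 is always the short-gap (intra-bout) one, making
the result invariant to label switching.

A binned mode maximizes the grouped-data likelihood of histogram counts
(Nelder-Mead on transformed parameters, default bin width 0.1 log10 units,
the granularity at which interval histograms are conventionally drawn and
fitted by grouped-likelihood tools). Raw EM is the default; the binned mode
exists because published criteria of this kind were historically computed
from binned frequency distributions, and the two agree closely on
well-separated data (covered by a test).

Criteria are estimated per 6 h period for diagnostics, but the criteria
actually applied pool intervals within the two novelty classes: periods 1–2
(0–6 h, 18–24 h of exposure, brushes novel) and periods 3–4 (120–126 h,
138–144 h, non-novel). Pooling gaps — not averaging per-period criteria — is
the intended convention and is asserted in tests.

`rounding="paper_mode"` rounds the log10 crossing to one decimal before
back-transforming, so reported criteria are powers of 10^0.1 (10^1.3 = 19.95 s,
10^1.4 = 25.12 s, 10^1.6 = 39.81 s, 10^1.8 = 63.10 s). Published values of
this kind are printed with small inconsistencies (25.11 for 10^1.4, 125.95
where 10^2.1 = 125.89); this package always reports the exact power of
10^0.1, which matches the printed values to within 0.01 s in the two-decimal
cases and is documented here rather than emulated digit-for-digit.

## Event-log handling

Times are float seconds relative to each animal's pen entry (input resolution
1 s). Observation windows are half-open [start, end) so boundary seconds are
never double-counted; events straddling a boundary are clipped and each
fragment labeled separately, conserving in-window duration exactly.
Overlapping or abutting same-animal records — observer slips, since one
animal uses one brush at a time — are merged rather than rejected
(`normalize_events`), keeping the behavior label of the longest constituent;
a zero gap would otherwise have no logarithm. Gap extraction then works per
animal × period and never forms a gap across animals or windows; a
non-positive gap at that stage is an internal contract violation, not a data
error.

## Competition and summaries

The competitive index is 100 × n_actor / (n_actor + n_receiver) over the
whole study (a per-period variant is available); uninvolved animals are
undefined and excluded. Pearson correlations between index and mean use per
window use the exact t-transform with n − 2 df, pooled and within treatment.
Inter-observer reliability is OLS of one observer on the other with t-tests
of slope = 1 and intercept = 0; a pass needs R² ≥ 0.89 (configurable) and
both p > 0.05. Group × period summary rows average over the group's animals,
omitting excluded animals only from the bout-duration mean; durations are
reported in minutes per 6 h window. Mixed-model inference itself is out of
scope by design — the `model_ready` long table is the hand-off point to any
standard LMM tool.

## The synthetic generator

`simulate_study` emulates the study design the analysis expects: two
treatments (2 vs 4 brushes per pen), 4 groups of 8 animals each by default,
four 6 h windows. Per animal × window it draws an alternating renewal stream:
events per bout 1 + Geometric (support ≥ 1, mean `events_per_bout_mean`, so
single-event bouts occur and exercise the exclusion rules), gamma event
durations, log10-normal gaps in both regimes, Bernoulli groom/oral labels,
categorical brush choice with a feeder-side preference in the 4-brush
treatment, and per-event displacement marks whose actor is a uniformly drawn
group mate. Streams are truncated at the window end by discarding partial
events and gaps (events are seconds long against 6 h windows, so the bias is
negligible). Each animal owns a substream seeded by (seed, animal index), so
enlarging a study never perturbs existing animals, and identical
configurations produce byte-identical CSVs.

Default parameters (the paper-like operating point, chosen to land at the
scale reported for weaned heifers with stationary brushes and asserted only
as broad ranges): μ₁ = 0.6, σ₁ = 0.25 (intra gaps ≈ 4 s), μ₂ = 2.95,
σ₂ = 0.35 (inter gaps ≈ 20 min), 3 events/bout, gamma(2, 4) durations
(mean 8 s), p_groom = 0.75, displacement probability 0.015 per event
(≈ 1 per group-hour), feeder-side preference 0.75. These imply ≈ 17 bouts per
animal per window of ≈ 33 s each and a true criterion of 41.6 s, inside the
20–126 s range published for this animal class.

The generator's analytic truth converts the mean events per bout m into the
implied mixture weight. A bout of k events contributes k − 1 intra gaps, and
B bouts observed in one window contribute B − 1 inter gaps (the break after
the window's last bout is unobserved), giving the truncation-adjusted weight
π₁ = (m−1)B / ((m−1)B + B−1) with B the expected bouts per window from the
renewal cycle length; π₁ → (m−1)/m as the window grows. The true criterion
then comes from the same quadratic used by the estimator — by construction,
not by fitting — and end-to-end calibration (truth inside the central 95% of
estimates across replicate simulations) is covered by a test.

What the generator does *not* emulate: diurnal activity rhythms, dominance
structure (actors are uniform by default; a dominance-weights exponent exists
for competition tests), spatial brush choice beyond the feeder/gate label,
inter-animal correlation in brush access (no queueing or interference), and
the 1 s coding resolution of human observers (times are continuous). Passing
tests therefore demonstrate correctness of the estimators under the assumed
two-timescale renewal model, not robustness to every field artifact; the
`gap_distribution="exponential"` mode provides a deliberately misspecified
stream for robustness checks.

## Problem sizes and numerical choices

Tests and the acceptance script run on simulated studies of 8 groups × 8
animals × 4 windows (≈ 13,000 events, ≈ 13,000 gaps) or smaller; mixture
benchmarks use 5,000 gaps, oracle sweeps 200 parameter sets and 1,000 random
event sequences. Root-finding oracle agreement is asserted at 1e−9 in log10
units, density normalization at 1e−6, conservation identities at exact or
1e−15 relative tolerance. CSV round-trips are bit-identical: numeric parsing
uses correctly rounded string conversion (a fast approximate parser is used
only to locate bad rows for error messages).

## Known limitations

- The two-component normal mixture is assumed, not selected; data generated
  by one regime or by heavy-tailed gaps will fit poorly and may trigger the
  degenerate-fit or intersection-not-found errors (by design there is no
  silent fallback to a 1-component model).
- Bouts cannot span window boundaries because events are clipped first;
  behavior genuinely straddling a boundary is split.
- Displacement cross-linking to receiver events (±1 s) is a convention for
  logs coded as separate observation streams; unlinked displacements are kept
  and counted.
- Reliability regression assumes observer A is measured without error
  (ordinary, not errors-in-variables, regression), the standard convention
  for this check.
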