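# boutline

Bout-criterion estimation and bout statistics for brush-use event logs from
group-housed cattle.

Cattle use stationary brushes in short events separated by pauses on two very
different timescales: seconds-long pauses *within* a sustained grooming bout,
and minutes-long breaks *between* bouts. Reporting raw events therefore
misrepresents how the animals actually use the resource. `boutline` implements
the standard interval-based bout analysis for this setting: it pools the
inter-event intervals, fits a two-component normal mixture to their log10
distribution by maximum likelihood,

    f(x) = π₁ N(x; μ₁, σ₁) + (1 − π₁) N(x; μ₂, σ₂),    μ₁ < μ₂,

and takes the crossing point of the weighted component densities,

    π₁ N(x; μ₁, σ₁) = π₂ N(x; μ₂, σ₂),

as the inter-bout criterion (back-transformed to seconds as 10^x). Events
separated by pauses shorter than the criterion belong to the same bout. On top
of the criterion the package computes bout frequency and duration, grooming /
oral-manipulation time budgets, first-contact latency, displacement counts and
the competitive index (100 × displacements initiated / displacements involved
in), and group-level tables ready for external mixed-model tools.

It is written for applied ethologists and animal-welfare scientists analysing
continuously coded resource-use logs (brushes, feeders, enrichment objects),
and ships a fully book-kept synthetic study generator so every stage can be
validated against exact ground truth.

## Worked example

```python
import boutline as bl

# simulate a study: 4 groups of 8 heifers per treatment (2 vs 4 brushes),
# four 6 h observation windows, with exact bookkeeping
table, truth = bl.simulate_study(bl.paper_like_config(seed=1))
table = bl.assign_periods(bl.normalize_events(table))

report = bl.pooled_criteria(table)
for novelty, (fit, crit) in report.pooled.items():
    print(f"{novelty.value:>9}: criterion {crit.criterion_s:5.2f} s "
          f"(n={fit.n} gaps, pi_intra={fit.pi_intra:.3f})")
print(f"analytic truth: {truth.true_criterion_s:.2f} s")

bouts = bl.summarize_all_bouts(table, report)
live = bouts[~bouts["excluded"]]
print(f"bouts/6 h: {bouts['bout_frequency'].mean():.1f}, "
      f"duration: {live['bout_duration_s'].mean():.1f} s/bout")
```

prints

```
    novel: criterion 42.07 s (n=6589 gaps, pi_intra=0.678)
non_novel: criterion 42.00 s (n=6622 gaps, pi_intra=0.684)
analytic truth: 41.64 s
bouts/6 h: 17.5, duration: 33.5 s/bout
```

Both pooled criteria recover the generator's analytic crossing (41.64 s) to
about 1%, and the bout statistics land at the scale typical for weaned heifers
with stationary brushes (roughly 12–19 bouts per animal per 6 h, tens of
seconds per bout). The same pipeline runs on real CSV logs via
`bl.load_study(...)` or the CLI:

```sh
boutline simulate --seed 1 --out-events ev.csv --out-displacements d.csv \
    --out-roster r.csv --out-truth truth.json
boutline fit-criterion --events ev.csv --rounding paper
boutline bouts --events ev.csv --out summaries.csv
boutline summarize --events ev.csv --displacements d.csv --roster r.csv \
    --out groups.csv --model-ready long.csv
```

`--rounding paper` reports criteria as powers of 10^0.1 (e.g. a fitted
crossing of 10^1.79 s is reported as 10^1.8 = 63.10 s), the convention used
when publishing such criteria.

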