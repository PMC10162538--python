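# agritrain

Attendance modelling and gender-inclusive scheduling for agricultural
extension training events.

Government extension services in developing countries run village-level
training sessions (often ICT-delivered video shows) whose turnout depends
heavily on *when*, *where* and *by whom* the training is delivered — and
those preferences differ sharply by gender. Scheduling for maximum total
turnout (male-led, marketplaces, late afternoon) suppresses female
participation; scheduling for women (female-led, farmers' houses, mornings)
reduces total turnout. `agritrain` is a decision-support pipeline for this
trade-off, aimed at analysts of extension programmes: it models male and
female attendance separately from event-level records and simulates
scheduling policies that mix "best for total attendance" with "best for
female attendance".

## Method

One row of data is one training event: six categorical inputs (trainer
gender; time of day in 3 bins; day of week; month; venue type, 8 levels;
administrative division, 4 levels) and two count outcomes, male and female
attendance.

1. **Input selection.** Dummy columns are grouped by factor (and by
   factor-pair interaction), and inputs are selected per outcome by
   group-penalized least squares
   `(1/2n)‖y − β₀ − Xβ‖² + λ Σ_g √K_g ‖β_g‖₂`
   with group Lasso, group MCP or group SCAD penalties, solved by block
   coordinate descent along a decreasing λ path. λ is chosen by 10-fold
   cross-validation; the penalty is chosen by test-set error (SMSE, a
   root-mean-square error on the count scale) on a held-out 20% split.
2. **Attendance models.** A quasi-Poisson GLM per gender:
   `E[Y] = exp(x'β)`, `Var[Y] = φ·E[Y]`, with φ estimated from the Pearson
   statistic. Overdispersion scales standard errors, never point estimates.
3. **Uncertainty.** The whole fit-and-predict step is bootstrapped
   (B = 1,000 resamples of events by default) and every prediction carries
   a percentile 95% confidence interval.
4. **Policy simulation.** All feasible event configurations form a mesh
   (Cartesian product of the retained factors' levels); mesh points are
   ranked by predicted total and by predicted female attendance, and the
   X% mixing policy builds an event list of size N from the top X% of the
   female ranking plus the top (100−X)% of the total ranking, for
   N ∈ {100, 50, 10} and X = 0…100%. Each scenario is scored against the
   observed per-event benchmark (122 total / 23 female attendees under
   intuition-based scheduling).

Because real event records of this kind are rarely shareable, the package
includes a calibrated synthetic generator (`agritrain.synthetic`) with
known ground-truth models — negative-binomial counts with quasi-Poisson
variance `φμ`, factor frequencies matching the observed study marginals,
and a configurable excess of zero-female events — so every stage is
testable end to end.

## Worked example

```python
import agritrain as at

table = at.generate_events(at.GeneratorConfig(n_events=1067, seed=7))
ens = at.bootstrap_models(table, at.DEFAULT_MALE_TERMS,
                          at.DEFAULT_FEMALE_TERMS, B=500, seed=1)
mesh = at.build_mesh(at.DEFAULT_MALE_TERMS, at.DEFAULT_FEMALE_TERMS)
summary = at.summarize_mesh(ens, mesh)
tl, fl = at.rank_mesh(summary, "total"), at.rank_mesh(summary, "female")
scen = at.evaluate_scenario(at.mix_lists(tl, fl, 50, 50), ens, mesh)
print(at.benchmark_compare(scen))
```

With these seeds the top of the total ranking is a male-led marketplace
event in Rangpur after 15:30, predicted 320 (95% CI 298–341) attendees;
the top of the female ranking is a female-led farmers'-house event in
Rajshahi before 11:00, predicted 88 (51–131) women. The recommended
half-and-half list of 50 events gives

```
total_mean 134.8 (123.5–147.3)   female_mean 33.6 (26.2–42.4)
{'exceeds_total': True, 'exceeds_female': True}
```

i.e. both lower confidence limits clear the 122/23 benchmark: the mixed
policy is predicted to raise female participation (here by ~46%) while
still raising total turnout (~11%), the central qualitative result.

The same run is available from the shell:

```bash
agritrain generate --n-events 1067 --seed 7 --out events.csv
agritrain simulate --events events.csv --list-size 50 --mix 50 -b 500
agritrain run --config config.yaml      # full pipeline, all artifacts
```

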