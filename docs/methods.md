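# Methods

This note documents the statistical procedure the package implements, the
choices made where the design was genuinely open, and what the synthetic
tests do and do not establish.

## Data model

The unit of observation is one training event with aggregated counts.
Six categorical inputs (trainer gender, time-of-day bin, day of week,
month, venue type, division) have closed level sets; labels are normalized
to `lower_snake_case` on read. Any row with a missing or unparseable
field is excluded whole, with a reason code (`missing_information`,
`negative_count`, `unknown_level`); the audit report compares mean male
and female attendance between included and excluded rows with Welch's
unequal-variance t-test (the conservative default when the excluded group
is small) and exposes both the included and the grand attendance totals
without attempting to reconcile them. Descriptive summaries use the
sample SD (n−1 denominator); the SD of a single observation is reported
as 0 with a `single_obs` flag rather than as undefined.

## Grouped penalized input selection

Treatment (reference-level) coding: a factor with L levels contributes
L−1 dummy columns in one penalty group; an interaction of L₁×L₂ levels
contributes (L₁−1)(L₂−1) columns in one group; the intercept is
unpenalized. The default candidate set is all six main factors plus the
division×time, division×venue and division×gender interactions — nine
penalized groups, 52 columns.

The selection objective is least squares on the raw counts,

    (1/2n)‖y − β₀ − Xβ‖² + λ Σ_g √K_g ‖β_g‖₂  (group Lasso)

with the MCP (γ = 3) and SCAD (γ = 4) analogues applied to ‖β_g‖.
Gaussian loss for selection, quasi-Poisson GLM for inference: the two
stages are deliberately separated, selection being a screening device.
Solver details:

* Each group's columns are centred and orthonormalized to
  `X_g'X_g/n = I` (SVD; directions with singular values below 1e−10 of
  the largest are dropped as rank-deficient and their coefficients fixed
  at zero), which makes every block update an exact groupwise threshold:
  soft (Lasso), firm (MCP), or the three-piece SCAD rule.
* Block coordinate descent with warm starts along a 100-point log-spaced
  λ grid from λ_max = max_g ‖X̃_g'(y−ȳ)‖/(n√K_g) down to 0.001·λ_max;
  convergence when the largest coefficient change is below 1e−8
  (non-convergence is flagged, the path continues).
* 10-fold cross-validation fixes the grid on the full data, records the
  per-λ mean and SD of held-out fold MSE, and selects the CV-minimum λ
  (no one-standard-error rule). CV-minimum is known to overselect
  mildly; on pure-noise simulations it retains all-null models in about
  three-quarters of replicates with ~0.5 spurious groups on average,
  which we accept as the documented behaviour of this rule.
* The penalty (Lasso vs MCP vs SCAD) is chosen by the smallest test-set
  SMSE after an 80/20 random split (train size = round(0.8n); the split
  is unstratified). SMSE is implemented as root-mean-square error on the
  count scale; a variance-normalized MSE (`nmse`) is also reported since
  "standardized" is ambiguous. Ties break toward fewer selected groups,
  then the fixed order MCP, SCAD, Lasso.
* Weak heredity: if an interaction group survives, its parent main
  effects are added to the final term set.

## Quasi-Poisson attendance models

Per gender, a log-link GLM fitted by IRLS (statsmodels, Poisson family);
dispersion φ = Pearson χ²/(n−p) — the conventional quasi-Poisson
estimator, preferred to the deviance version — scales the coefficient
covariance but not the point estimates. A degenerate perfect fit floors
φ at the smallest positive float so the φ > 0 invariant holds. Rank
deficiency aborts with the aliased columns named; prediction uses
exp(x'β) with delta-method standard errors on request. "Total
attendance" for an event configuration is defined as the sum of the two
model predictions (no separate total model is fitted). Models serialize
to JSON and round-trip bit-exactly.

Default term sets, used when data-driven selection is skipped: male —
trainer gender, venue, division, time of day, division×time (with all
lower-order terms); female — trainer gender, time of day, month, venue,
division.

## Bootstrap

Nonparametric: B = 1,000 (default) resamples of n events with
replacement; both GLMs are refit per replicate with the term sets held
fixed. Re-running the penalized selection inside every replicate would
multiply cost a thousandfold while the reported intervals attach to a
fixed model structure, so selection is run once on the original data;
`reselect_per_replicate=True` enables the expensive variant for
sensitivity analysis. Replicates whose refit fails (non-convergence, or
rank deficiency when a resample loses a sparse covariate cell) are
redrawn and counted; more than 5% failures aborts the run. Intervals
are percentile (2.5/97.5 empirical quantiles, linear interpolation), not
normal-approximation, BCa or studentized.

## Mesh and mixing policy

The mesh is the Cartesian product of the level sets of every factor
retained by either model; factors selected by neither model are dropped.
Month is treated as an effect modifier rather than a free axis: when the
female model retains it, predictions are pinned to the latest study
month (configurable) instead of quadrupling the mesh. With the default
terms the mesh has 2×3×8×4 = 192 points.

Rankings by bootstrap-mean predicted total and female attendance break
ties by the other criterion and then by lexicographic configuration, so
top lists are fully reproducible. The X% mixing rule takes
k = round(XN/100) (half rounds up) entries from the female ranking and
N−k from the total ranking; configurations present in both sub-lists are
deduplicated by backfilling from the next-ranked unused female entries,
preserving both the list size and the female-emphasis intent of X.
Scenario metrics are computed per bootstrap replicate (the proportion
female as Σfemale/Σtotal, attendance-weighted; the unweighted mean of
per-event ratios is also emitted) and summarized by means and percentile
intervals. A scenario "beats the benchmark" only if its lower 95% limit
strictly exceeds the observed per-event average (122 total, 23 female).
The division-balanced variant apportions the N slots across divisions by
largest remainder and applies the mixing rule within each division.

## Synthetic generator

The generator emulates the study conditions: 1,067 events by default;
factor frequencies equal to the observed marginal shares (the printed
venue counts sum to 999, so venue shares are normalized); counts drawn
from a gamma-Poisson mixture parameterized so that Var = φμ (NB1 — the
same variance law the quasi-Poisson analysis assumes; φ = 1 degenerates
to exact Poisson, φ < 1 is rejected); and a structural zero applied to
female counts with probability 0.238, the observed share of zero-female
events. Default true coefficients are documented constants chosen to
echo the observed per-level patterns qualitatively — male attendance up
at marketplaces and after 15:30, female attendance up with female
trainers, at farmers' houses and in later months — with intercepts
calibrated analytically so the marginal means land near the 122/23
benchmark; default dispersions (φ = 40 male, 15 female) are of the order
implied by the observed within-level SDs. They are not estimates of any
real-data fit. Covariates are sampled independently across factors
(only marginals are published); a `joint_table` hook accepts an explicit
joint distribution.

What passing tests on this generator do **not** show: robustness to
correlated covariates, spatial/temporal autocorrelation between events,
venue-level repeated measures, or zero-inflation mechanisms beyond the
single structural-zero switch. Real female counts may be zero-inflated
in ways quasi-Poisson absorbs only partially; the generator makes this a
switch precisely because the question is unresolved.

## Problem sizes in tests and the acceptance script

The test and acceptance workloads use scaled simulation sizes chosen as
the smallest that make the statistical assertions stable: selection
consistency with 50 replicates at n = 800; Wald-coverage and dispersion
recovery with 200 replicates at n = 1,000, φ = 2; nested bootstrap
calibration with 100 outer replicates at B = 200, n = 300; the policy
sweep on the calibrated default at n = 1,067 with B = 200–500. Library
defaults remain at the full study settings (B = 1,000, 10 folds, 80/20).

## Known limitations

* Selection uses Gaussian loss on counts; a Poisson-loss penalized path
  would be more efficient for skewed counts and is noted as an extension.
* CV-minimum λ overselects mildly (see above); no one-SE rule is offered.
* The bootstrap ignores selection uncertainty unless
  `reselect_per_replicate` is set.
* Mesh predictions extrapolate into unobserved covariate cells by
  construction; confidence intervals there are model-based only.
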