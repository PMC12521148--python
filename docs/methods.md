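# Methods

## Model structure

Each strategy is a *single-decision* tree: one chance node whose three
branches are the health states (hospitalization, outpatient exacerbation,
symptom-free), each branch carrying a probability, a cost and a utility.
This is not a Markov cohort model — there are no cycles, no transitions
and no half-cycle correction. The state occupied at a visit is treated as
carrying its utility for the whole 18-year horizon, which is how the
bundled study's utility parameters are constructed: the tabulated state
utilities equal `(0.867 + d) × 18` exactly, with no discounting. A
`discount_rate` field is reserved on `UtilityModel` (default 0) but any
non-zero value is currently rejected rather than silently half-supported.

Assumptions this structure implies:

* visits are exchangeable — the model uses only the marginal share of
  visits per state, not their order or timing;
* costs and utilities attach to states, not to individual trajectories;
* no mortality (the cohort recorded none) and no discounting.

## Parameters

| Parameter | Units | Default | Rationale |
|---|---|---|---|
| base utility | –/year | 0.867 | annual utility weight of controlled asthma |
| decrement, outpatient exacerbation | –/year | −0.1 | published exacerbation decrement |
| decrement, hospitalization | –/year | −0.22 | published severe-exacerbation decrement |
| horizon | years | 18 | full pediatric treatment span (0–18 y) |
| WTP threshold λ | CNY/QALY | 287,100 | 3× the 2024 Chinese per-capita GDP (95,700) |
| PSA iterations | – | 1,000 | the study's simulation size |
| PSA cost CV | – | 0.3 | fallback when a cost has no published sd |

State probabilities are derived as **per-visit shares**: the bundled
study never states how its probability parameters were obtained, but
dividing each group's per-state visit counts by its total visits
reproduces all 18 tabulated 4-decimal probability cells, so the package
adopts that reconstruction (and the cohort aggregator mirrors it). It is
an inference, not a documented procedure, and is flagged as such here.

Two cost bases exist — ICS-only and total medication (ICS + traditional
Chinese medicine + other chemical medicines) — and are typed: results on
different bases cannot be compared, because a ratio mixing them is
meaningless.

## Ratios, dominance and negative ICURs

`ICER`/`ICUR` are plain quotients ΔC/ΔE with the reference arm
conventionally the cheaper one. A ratio is left undefined (blank in
reports) when the effect difference is zero. The engine never interprets
a bare negative ratio: the sign of ΔC/ΔE cannot distinguish "cheaper and
more effective" from "costlier and less effective", so every comparison
carries a dominance quadrant label (`alt_dominates`, `ref_dominates`,
`tradeoff`, `equivalent`). In the bundled study's single-inhaler pair,
the negative medication-basis ratio for SF-vs-BF is published with the
reading that BF is preferred; in this package that same conclusion is
expressed as `ref_dominates` (BF cheaper *and* more effective on that
basis) rather than through the ratio. The study's narrative also quotes
¥20,632.18/QALY for the B2-vs-B1 comparison on *both* cost bases, while
its own parameter arithmetic gives ≈7,445 on the ICS basis; the package
reports the value consistent with the parameters.

For a tradeoff pair with ΔU > 0 the WTP verdict is `ICUR < λ`;
equivalently `NMB(alt) > NMB(ref)` with NMB = λ·E[U] − E[C] — an
algebraic identity that is property-tested. For the rarer tradeoff with
ΔU < 0 (cheaper but worse) the alternative is acceptable iff the savings
per QALY forgone exceed λ, i.e. `ICUR > λ`.

## Probabilistic sensitivity analysis

* **Costs** — Gamma, matched by moments: shape = (mean/sd)², scale =
  sd²/mean, so the fitted mean and variance equal the inputs exactly.
  Published per-state sds are used where a mapping to the cost tables
  exists (they are bundled alongside the means); otherwise sd = CV×mean
  with CV configurable (default 0.3). A zero sd (a fixed-price inhaler)
  degenerates to a point mass.
* **Probabilities** — the study specifies Beta marginals; a
  two-arm Beta does not generalise to three states without leaving the
  simplex, so the default is a Dirichlet with the visit counts as
  concentration, whose every marginal *is* Beta(nᵢ, N−nᵢ). A strict
  independent-Beta mode with renormalization is available
  (`prob_mode="beta"`).
* **Utilities** — fixed in the base case; the study lists only cost and
  probability distributions.
* **Seeding** — one root seed; each parameter gets an independent
  `numpy` `SeedSequence(seed, spawn_key=(crc32(name),))` stream keyed by
  `"{strategy}/cost/{state}"` etc., so adding or fixing one parameter
  does not reshuffle the draws of the others. Runs are bit-reproducible.
* **CE plane summary** — the "95% confidence interval" of the scatter is
  implemented as a bivariate normal-theory ellipse (χ²₂ quantile of the
  Mahalanobis distance under the sample mean/covariance); the study does
  not define its region, so this standard choice is documented rather
  than assumed to match. The CEAC at λ is the fraction of draws with
  λ·ΔU − ΔC > 0.

Because the study publishes no dispersion for its PSA priors, its
scatter plots and CEACs are not numerically reproducible; the PSA is
therefore validated by its distributional properties (degenerate priors
reproduce the base case exactly, CEAC endpoints equal the ΔC<0 / ΔU>0
draw fractions, Gamma moment round-trip is exact, Dirichlet marginal
moments match the Beta closed forms, seeded runs are identical), not by
matching figures.

## Synthetic cohort generator

The generator emulates the marginal structure the decision tree actually
consumes, per subgroup:

* **visit counts** — negative binomial matched by moments to the
  published per-patient mean ± sd (all four subgroup sds exceed their
  means, ruling out Poisson); dispersion r = m²/(s²−m). Draws of zero are
  raised to one visit, since every recorded patient has at least one.
* **states** — i.i.d. categorical per visit at the subgroup's visit
  shares. No within-patient serial correlation is simulated; the model
  uses only the marginals, so none is needed.
* **costs** — independent Gamma per category (ICS, TCM, other chemical,
  non-medication) with the published per-visit (mean, sd); categories
  are independent because no covariance is published. The three
  medication categories sum to the total-medication cost by
  construction.
* **longest symptom-free duration** — piecewise-exponential with
  constant hazard between the 3/6/12/24-month thresholds, chosen so the
  survival function passes through the configured exceedance targets
  exactly; beyond 24 months the last positive hazard continues. A target
  of 1.0 yields a zero-hazard (mass-free) segment; a target of 0 is
  floored at 1e-12 to keep hazards finite. Targets must be
  non-increasing or the config is rejected.
* **follow-up** — Gamma at the published moments, floored at the drawn
  symptom-free duration to keep records internally consistent.

What the generator does **not** emulate: seasonality, age and sex
structure, within-patient correlation between visit frequency, states
and costs, and any between-group covariate effects. Passing
recovery tests therefore show that the pipeline is a faithful
aggregate-preserving round trip — not that the generator reproduces
real patient heterogeneity.

Reproducibility: the root seed is split per subgroup via
`SeedSequence.spawn`, so subgroups are independent and stable.

## Numerical choices

* Internal arithmetic is full float64; tabulated-value comparisons in
  tests use ±0.01 for 2-decimal costs/ratios, ±5e-5 for 4-decimal
  probabilities/utilities, and 0.5% relative for expected values and
  ICURs computed from rounded printed inputs.
* Probability vectors read from 4-decimal tables may miss 1 by up to
  5e-4 and are accepted at that tolerance; derived vectors must sum to 1
  to 1e-8.
* A state with zero observed visits aggregates to probability 0 and an
  absent (NaN) mean cost; when such an aggregate is fed to the decision
  tree the absent cost is replaced by 0, which is inert under zero
  probability.
* Ties in dominance classification: ΔC = 0 with ΔE > 0 counts as
  dominance (weak inequality with one strict), mirroring the usual
  quadrant convention; exact equality of both deltas is `equivalent`.

## Problem sizes

The test suite exercises the synthetic round trip at 10³ patients per
subgroup (loose tolerances) and 10⁴ patients per subgroup (0.01 absolute
on shares, 5% on cost means, 2 percentage points on exceedance rates),
Dirichlet/Beta moment checks at 10⁵ draws, and Gamma mean recovery at
10⁶ draws; the full suite runs in well under a minute on one CPU. These
sizes were chosen as the smallest at which the law-of-large-numbers
tolerances above are comfortably non-flaky.

## Known limitations

* The decision tree inherits the study's construction wholesale —
  utilities scale linearly with an 18-year horizon regardless of each
  patient's actual follow-up, which overstates absolute QALYs for
  short-course patients (incremental comparisons are less affected).
* Costs are treatment-course aggregates, not annualized, so the ICURs
  mix an 18-year utility denominator with an observed-course cost
  numerator, exactly as published.
* No efficiency frontier over more than two strategies, no EVPI, no
  one-way tornado analysis: the analysis is strictly pairwise.
* The per-visit reading of the state cost parameters (rather than
  per-episode) is an interpretation; it is the one consistent with the
  visit-share probability reconstruction.
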