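# Methods

## Scope and viewpoint

The package compares two ways a public benefactor can obtain new
antibiotics: announcing a lump-sum entry reward that flips private
no-decisions into go-decisions (*indirect* funding), or paying
development costs as they arise (*direct* funding, with a plan-economy
inefficiency mark-up). All valuation is done from the outset of
pre-clinical development (t = 0), which is also why pre-clinical entry
rewards are excluded: they would be paid undiscounted at the decision
point and reduce to a transfer.

Everything is expected net present value (ENPV): probability-weighted,
discounted cashflows of a staged, risky project. The within-project
*difference* between the two funding routes is the quantity of interest,
so health benefits cancel and are never modelled. Drug reimbursement
costs, existing-grant offsets and candidate acquisition prices are out of
scope.

## Input tables

All inputs ship as CSV tables under `src/abxfund/data/` and are the
model's definition of its six indications:

* `phase_parameters.csv` — per phase × indication triangular (min, mode,
  max) triples for duration (months), cost (million USD) and success
  probability (%). The phase-4 cost prints only a most-likely value
  (1.9588) and is treated as a fixed constant. "Phase 4" covers all
  activities between the end of phase 3 and first sales.
* `market_size.csv` — annual market size (million USD). The table prints
  a per-indication lower bound and a single upper bound (9,230); market
  size is sampled **Uniform(lower bound, 9,230) for every indication**.
  This reading was adopted after the alternative (fixed sizes, with a
  range only where both cells print) produced baseline go-ratios
  incompatible with the reference results for every small-market
  indication while a shared uniform upper bound reproduces all six to
  within two percentage points; no mode is printed, so a triangular is
  unjustified either way.
* `market_share.csv` — lower/upper envelopes of captured market share,
  rising through year 10 and constant for years 10–20 (the `10:20` row
  expands to identical bounds).
* `additional_parameters.csv` — launch success probability, generic-entry
  year and revenue reduction, private discount rate (all triangular).
* `additional_costs.csv` — six extra cost items (sample preparation,
  process development, plant design/build, non-clinical work,
  post-approval studies) with their phase allocations; unweighted
  allocations split equally, plant design splits 75%/25% over P3/P4, and
  post-approval studies spread over exactly the first three market years.

Units are normalised on load (months → years, percent → fractions; money
stays in million USD) and every invariant (ordering of triples,
probability bounds, share monotonicity, allocation weights summing to 1)
is validated with an error naming the offending field. `dump_parameters`
writes the same layout back and round-trips exactly.

## Sampling

One project realization draws, in a fixed order from one generator:
per-phase duration, cost and success probability; market size; the
launch-success draw; generic entry year and reduction; the private rate
r ~ triangular(9%, 11%, 24%) and social rate r′ ~ Uniform(3.5%, 4.5%);
and the six extra-cost items. Triangular draws use an explicit
inverse-CDF (one uniform variate each, so degenerate triples consume the
same amount of stream; numpy's generator rejects degenerate triples),
cross-checked against `scipy.stats.triang` in the tests.

The market-share curve is not sampled per year. The launch-success draw
ℓ ~ triangular(0.40, 0.60, 0.80) is rescaled to f = (ℓ − 0.40)/0.40 and
share[y] = lower[y] + f·(upper[y] − lower[y]) for all years, so a
project's position between the envelopes is constant and the curve never
dips before peak sales. The launch draw is used only for this
interpolation; it is not an extra survival factor on revenues (the
technical probability of reaching market is defined by the five phase
probabilities alone, and that reading reproduces the reference baseline).

Prize sizes are sampled log-uniformly: 10^X USD with X ~ Uniform(5, 11),
i.e. 0.1–100,000 million USD — most of the go-response happens at small
prizes, so a log scale spends samples where they inform. A project never
carries more than one prize.

Reproducibility: every project is drawn from
`SeedSequence(seed, spawn_key=(stream, index))`, one stream per
experiment × indication (grid cells get their own streams), so results
are bit-identical for a given seed and unaffected by how many projects or
indications run before them.

## Periodization

A phase of duration d starting at calendar time s becomes ceil(d) yearly
points at s, s+1, …; the next phase starts at s + d, so points are
equidistant within but not across phases (2.5 y then 1.75 y gives
t = 0, 1, 2, 2.5, 3.5 and the next phase starts at 4.25). Each point
carries 1/n of the phase's cashflow even though the last sub-interval is
shorter. Phase success is split as a constant per-step conditional
survival p^(1/n) ("evenly distributed" read as constant hazard; an
additive split could not conserve the product), so the survival weight
P0/P_t is 1 at t = 0, decays geometrically within phases, and equals P0
on all 20 market years, which are unit steps from total development time.
Revenues are market size × share with the post-generic-entry years
(strictly later than the sampled real-valued entry year) cut by the
sampled reduction and held constant to year 20. Prizes are lump sums on
the first step of their phase (first market year for an MER). Discounting
uses (1+r)^t with real-valued t throughout; there is no continuous-time
discounting and no partial-year proration of market revenue.

## Response models and inversion

Per indication × prize phase:

* **improvement model** — OLS of log10(intervened − private ENPV) on
  log10(prize); the log-log transform removes the heteroscedasticity of
  the raw improvement. Prizes always improve the developer's view, so the
  left side is defined for every project.
* **P(go) model** — maximum-likelihood logistic regression of the
  post-prize go-decision on log10(prize), fitted **only on projects that
  faced a no-decision unaided**; it is the conditional conversion
  probability, not the unconditional go-rate. Each project contributes
  its single sampled prize size, evaluated at each of the five prize
  phases as separate treatments (this pools all no-decision projects into
  every phase's fit; an alternative that also randomises the phase would
  cut each fit's sample five-fold and, at these sizes, makes the 90%
  inversion extremely noisy). Complete separation — possible at small
  n — is rescued by a mild ridge penalty (α = 1) and flagged; flagged
  p-values are not trusted. No multiple-testing correction is applied to
  the reported maximum p-values.

The logistic is inverted in closed form at a target p:
z\* = 10^[(logit p − β0)/β1]. Solving at p = 0.9 extrapolates into the
upper tail of the data; its Monte Carlo standard deviation at 2,000
projects per indication is of order 10–40% for phase-4/market rewards
(see Limitations).

## Experiments

* **baseline** — 2,000 projects per indication (seeded): go/no ratios,
  both response fits per indication × phase, and the solved 90%-target
  prize schedule.
* **grid** — 40 go-targets on [0.5, 0.9875] × 41 inefficiencies on
  [0, 1] (uniform spacing; counts and endpoints are given, spacing is the
  natural default), 10 fresh projects per cell from a cell-indexed
  stream. Prizes come from the baseline fits, not per-cell refits (10
  samples cannot support a fit). Mean cost savings per cell are taken
  over the stimulated subset; cells with no stimulated sample are
  recorded as missing, never zero. The zero-savings frontier is a
  quadratic of go-target on inefficiency through each column's
  smallest-|savings| cell, fitted only where the column changes sign and
  flagged below three crossings.
* **scenario** — 1,000 projects per indication at inefficiency 0.5 and a
  90%-target prize schedule, reporting mean cost savings per market
  approval and the per-sample cost distributions. The schedule can be
  solved from a fresh fit (default) or supplied explicitly; the packaged
  `reference_prizes_p90.csv` is a reference schedule calibrated to these
  tables, and using it isolates the scenario's valuation from the
  inversion noise above. Filtering removes samples with intervened
  private ENPV < 0 — an ineffective prize is never paid, so its cost is
  meaningless.

Problem sizes used by the test suite and the acceptance script — 2,000
per indication for fits, 1,000 for the scenario, reduced grids in
tests — are the campaigns' own study scales; the full 40 × 41 grid
(≈ 0.5 M project valuations, about two minutes) is run from the CLI.

## Numerical choices and degenerate inputs

Go-decisions use ENPV ≥ 0 (ties go). ceil() on durations is guarded
against float noise (2.0 never becomes 3 steps). The prize shortcut used
by the experiments (a prize enters every perspective linearly through the
discount weight of its entry step) is exact and is tested against
rebuilding the schedule. Degenerate logistic inputs (one outcome class)
raise; β1 = 0 cannot be inverted and raises; p_reach_market = 0 cannot be
normalised and raises.

## What the generator does and does not emulate

The generator *is* the study's data source — there is no external data.
It emulates staged attrition, skewed parameter uncertainty, a bounded
share ramp with generic erosion, and heterogeneous time preference. It
does **not** emulate correlated draws across phases or indications,
time-varying discount rates, competition between entrants, reimbursement
or grant offsets, or any epidemiological feedback. Passing tests
therefore certify the pipeline's arithmetic and its agreement with the
reference tables under these assumptions, not forecasts about real
antibiotic markets.

## Known limitations

* The 90%-target inversion is noisy exactly where prizes are largest
  (phase 4 / market entry): the logistic's upper tail is data-sparse, so
  solved prizes for a given indication can move by tens of percent
  between seeds, and cross-indication extremes (largest-minus-smallest
  MER) are inflated by extreme-value effects. The reference prize
  schedule itself carries noise of this kind; the scenario's savings, by
  contrast, are stable to a few percent once the schedule is fixed.
* The shared-maximum uniform market-size reading (above) is an inference
  from reproducing the reference baseline, not a printed rule.
* Inefficiency scales cost only, never duration or success probability.
* The constant-hazard survival split and the strictly-after generic-entry
  rule are the simplest readings consistent with the stated behaviour;
  alternatives (whole-phase probability on one step; reduction from the
  entry year itself) change valuations by small amounts.
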