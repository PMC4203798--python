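# Methods

## Model structure

The model couples a 90-day decision tree to an annual-cycle Markov cohort
model over four health states defined by the modified Rankin Scale: mRS
0–1 (no disability), mRS 2–3 (minor/moderate), mRS 4–5 (severe), dead.
Cycle 0 spans days 0–90 (the decision tree); annual cycles 1..30 follow,
aging the cohort from 63 to 93. The perspective is the healthcare payer;
costs are 2011 CNY, outcomes QALYs, both discounted at 3%/yr from the
first annual cycle (cycle-0 flows are undiscounted).

### 90-day decision tree

The treated arm's 90-day state distribution, sICH rate and cohort share
per onset-to-needle window are observed inputs. The control arm is
derived per window through pooled-trial odds ratios and then pooled by
shares. Two conventions deserve explicit statement:

- **Favorable outcome (mRS 0–1) and sICH**: control odds = treated odds
  / OR. With OR > 1 the control arm has fewer good outcomes and fewer
  hemorrhages, as expected.
- **Death**: the published model's results are only reproducible when the
  printed death ORs (0.78 / 1.13 / 1.22) act in the opposite direction,
  control odds = treated odds × OR, i.e. 90-day control mortality
  (11.7% pooled) above the treated arm's (10.4%). Under the literal
  same-direction reading the incremental QALYs come out ~40% below the
  published values at every horizon, beyond any plausible life-table or
  utility variation (we verified this by solving the linear cohort model
  for the initial distribution implied by the published totals). The
  package therefore defaults to the inverted reading
  (`control_distribution(..., death_or_inverted=True)`) and exposes the
  literal one.

The mass remaining after control mRS 0–1 and death is split between mRS
2–3 and mRS 4–5 in the treated arm's proportions. If the two
back-transformed probabilities alone exceed 1 (inconsistent ORs at
extreme settings), the model raises rather than renormalizing. sICH is
priced as a cost add-on only, in both arms at each arm's own rate; its
clinical consequences are taken as already embedded in the observed
90-day distributions.

### Annual cycles

Within each annual cycle, events are sequential competing risks:

1. recurrent stroke with probability `0.1181 × 1.019^(y−1)` (capped at
   1), fatal with probability 0.2101; survivors are reallocated equally
   among states of equal or greater disability (mRS 0–1 → thirds across
   the three alive states; mRS 2–3 → half/half to mRS 2–3 and 4–5;
   mRS 4–5 stays);
2. non-stroke death for the non-recurring mass at the age- and
   state-specific probability (below). Recurrent-stroke survivors are
   not additionally exposed to non-stroke death in the same cycle, which
   avoids double-counting; the ordering is a modelling choice since no
   ordering is stated in the source.

Costs per annual cycle: annual post-hospitalization cost by state
(mRS 0–1: 6,773; mRS 2–5: 10,305), plus a one-time hospitalization per
expected recurrent event billed at the destination state's rate (deaths
at the mRS 6 rate, 10,794). QALYs: one year at the state utility.

**Accrual timing.** Annual flows accrue on the *start-of-cycle*
occupancy — membership at the start of a year earns that year's cost and
utility, transitions take effect at year end — and a reported horizon of
H years is cycle 0 plus annual cycles 1..H in full. These two
conventions reproduce the published 1-year per-arm QALYs and costs to
within ~1.5%; end-of-cycle accrual (available via `accrual="end"`) and
fractional final-year weighting do not. No half-cycle correction is
applied, matching the source's silence on it.

### Mortality

Only two points of the census-derived non-stroke mortality schedule are
published: q(63) = 0.0089 and q(93) = 0.1654. We interpolate
log-linearly (constant annual growth factor ≈ 1.102), the natural choice
for adult mortality whose hazard grows roughly exponentially with age;
a linear alternative (`method="linear"`) exists for sensitivity checks
and brackets the plausible range. Beyond age 93 the rate is held flat,
which the 30-year horizon never exercises from age 63. State adjustment
uses the hazard scale, `q_s = 1 − (1−q)^HR`, never probability
multiplication (which can exceed 1). This reconstruction is the dominant
honest uncertainty in long-horizon totals.

## Sensitivity analyses

**One-way (tornado).** Every ranged input — the Markov/cost/utility/
discount table entries and each window's three odds ratios — is set to
its low and high bound with all else at base, the 30-year model re-run,
and entries ranked by absolute ICER spread. A model failure at an
extreme is flagged in the output, not dropped.

**Probabilistic.** All uncertain inputs are drawn jointly and
independently, 10,000 times by default, the 30-year model re-run per
draw:

- probabilities and utilities: beta, method-of-moments with mean = base
  and SD = (high − low)/3.92 — ranges are read as central 95% intervals
  (the divisor is exposed as `psa.ci_divisor`); infeasible moments fall
  back to uniform(low, high) with a logged warning;
- costs, odds ratios, hazard ratios and the recurrence escalation
  factor: lognormal with log-mean ln(base), log-SD
  (ln high − ln low)/3.92. Where the base sits on a range bound (the
  mRS 0–1 hazard ratio, base 1.0 = low) the draw is truncated to the
  range; rare crossings of the sampled hazard ratios are projected onto
  the ordered set HR(0–1) ≤ HR(2–3) ≤ HR(4–5);
- treated-arm 90-day outcome vectors and sICH rates: the source prints
  no ranges for them, so they are resampled with binomial precision at
  the per-window registry sample size (share × 1,128), as independent
  beta margins renormalized to sum to 1 (`window_multivariate:
  independent_beta`; a Dirichlet with α_i = n_w·p_i is the exposed
  alternative, and `fixed` disables outcome resampling);
- window shares and discount rates are held fixed: the shares describe
  the treated cohort's composition rather than an uncertain parameter,
  and the source assigns distributions only to probabilities, utilities
  and costs. Discount-rate ranges feed the tornado only.

One seeded generator stream drives the entire PSA; results are bitwise
reproducible given the seed, which is recorded in all outputs. Draws
whose parameter set violates a model invariant are resampled and logged;
more than 1% failures aborts the run. The CEAC reports, per
willingness-to-pay value on a grid (0–200,000 CNY in 1,000 steps, with
35,100 and 105,000 included exactly), the fraction of draws with
positive incremental net monetary benefit `wtp·ΔE − ΔC`.

## Synthetic data and validation

`synthetic.simulate_patients` draws registry-like 90-day records (age ~
truncated normal 63.48 ± 11.34 on [18, 95], 39.01% female, windows by
share, outcomes from the arm's window distribution). Age, sex and
covariates are descriptive only — the cohort model runs at the single
start age — so passing recovery tests show the estimator and generator
agree, not that the model captures age heterogeneity in real cohorts.
`estimate_inputs` returns frequency estimates with 95% Wilson intervals;
across 200 cohort-sized replicates their empirical coverage is ~95%
(`analysis/05_parameter_recovery.py`).

`synthetic.microsim_oracle` replays the cohort engine's exact transition
probabilities, event ordering and accrual as per-patient Bernoulli/
categorical draws. Agreement of its means with the cohort totals (within
3 Monte-Carlo SEs at 10⁵ patients, both arms, horizons 1/5/30) is the
engine's correctness check: the cohort model is the expectation of the
microsimulation. Note that all horizons of a single seeded run share the
initial-draw fluctuation, so the per-horizon z-scores are strongly
correlated rather than six independent checks.

## Reproduction fidelity

With the conventions above, the model reproduces the published:

- 1-year per-arm QALYs and costs to ~1.5%;
- 2- and 30-year incremental QALYs to ~11% (0.090 vs 0.101; 0.379 vs
  0.422) and the 2-year incremental cost to ~7%;
- the tornado's top-two drivers (favorable-outcome OR in the 1.5–3 h
  window; annual mRS 2–5 care cost) and the ICER at the low annual-cost
  bound to ~4%;
- the PSA fraction cost-effective at CNY 105,000/QALY (99.4% vs 98.7%).

It does **not** reproduce the published 30-year incremental cost
(CNY ~10,200 vs 6,530) and hence overstates the 30-year ICER (~26,800 vs
15,474), the 2-year ICER (+19%), the one-way ICER at the low
favorable-outcome OR, and the PSA dominant fraction (2% vs 14.4%). The
published totals imply control-arm annual cost flows that decline far
more slowly than the treated arm's; no variant of the described engine
we tested (accrual timing, OR directions, reallocation rules,
hazard-ratio handling, life-table shapes) produces that pattern while
also matching the QALY gains. We report the discrepancy rather than
calibrating hidden parameters to the published outputs.

## Known limitations

- The real census life table, and any intermediate outputs of the
  original spreadsheet implementation, are unavailable; the two-anchor
  reconstruction bounds but does not remove this error.
- No informal-care or indirect costs, no non-stroke cardiovascular
  events, no functional improvement through rehabilitation — exclusions
  inherited from the source model.
- PSA parameterization from printed ranges (divisor 3.92, independence
  across parameters) is one defensible reading; correlation structure,
  if any was used originally, is unrecoverable.
- Problem sizes used by the test suite and drivers (10⁵-patient
  microsimulation, 10⁴ PSA draws, 200 recovery replicates) were chosen
  so Monte-Carlo error is well below every tolerance they are checked
  against.
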