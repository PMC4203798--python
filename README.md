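# strokecea

A decision-tree + Markov cohort cost-effectiveness model of intravenous
tissue-type plasminogen activator (tPA) given within 4.5 hours of acute
ischemic stroke in China, versus no thrombolysis, rebuilt entirely from
published model inputs.

**Who it is for.** Health-economic modellers and methods students who want a
fully transparent, tested re-implementation of a classic stroke
cost-utility analysis: every input is a printed number (90-day outcome
tables by onset-to-needle window, pooled-trial odds ratios, registry costs
and utilities), and every result — base case, tornado, probabilistic
sensitivity analysis — is recomputed from those inputs at run time.

## The model

A treated cohort (mean age 63) is split across three onset-to-needle
windows (0–1.5, 1.5–3, 3–4.5 h; shares 5.68/61.13/33.19%). For each
window the 90-day distribution over four health states — mRS 0–1 (no
disability), mRS 2–3, mRS 4–5, dead — is observed under tPA; the control
arm is reconstructed through the window's odds ratios. For a treated
probability `p` and odds ratio `OR` the favorable-outcome back-transform is

    p_control = odds / (1 + odds),   odds = [p/(1-p)] / OR

with the mass left over after mRS 0–1 and death split between mRS 2–3 and
mRS 4–5 in the treated arm's proportions (see `docs/methods.md` for how the
death OR is applied and why).

The 90-day distributions then enter a four-state annual-cycle Markov model
run to 30 years: each year survivors face recurrent stroke with probability
`0.1181 × 1.019^(y-1)` (case fatality 0.2101, survivors reallocated equally
among states of equal or greater disability) and non-stroke death at an
age-specific rate interpolated log-linearly between q(63) = 0.0089 and
q(93) = 0.1654, scaled per state by hazard ratios (1 / 1.19 / 2.04) on the
hazard scale: `q_s = 1 − (1−q)^HR`. Costs (2011 CNY: tPA add-on 10,830,
sICH add-on 2,300, one-time hospitalization and annual care by state) and
QALYs (utilities 0.80 / 0.58 / 0.28 / 0) are discounted at 3%/yr and
compared as the incremental cost-effectiveness ratio ICER = ΔC/ΔE against
willingness-to-pay thresholds of CNY 105,000 (3× 2011 GDP per capita) and
CNY 35,100 (1×).

## Worked example

```python
import strokecea as sc

cfg = sc.default_config()                  # all printed inputs built in
for r in sc.cea_at_horizons(cfg.windows, cfg.params, horizons=(2, 30)):
    print(f"{r.horizon_years:>2} y: dQALY={r.delta_qaly:.3f} "
          f"dCost=CNY {r.delta_cost:,.0f} ICER={r.icer:,.0f}")
```

prints

```
 2 y: dQALY=0.090 dCost=CNY 10,148 ICER=112,634
30 y: dQALY=0.379 dCost=CNY 10,161 ICER=26,796
```

i.e. thrombolysis is not cost-effective over two years (ICER above the
CNY 105,000/QALY threshold) but clearly cost-effective over a lifetime
horizon, as the disability difference compounds into 0.38 discounted
QALYs. The same numbers come from the CLI (`strokecea basecase`), and the
numbered drivers under `analysis/` walk through the full study:
base case (`01`), tornado (`02`), 10,000-draw PSA with CE-plane and CEAC
(`03`), microsimulation validation of the cohort engine (`04`) and
parameter-recovery calibration from synthetic registry cohorts (`05`).
Each writes plain CSVs under `results/`.

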