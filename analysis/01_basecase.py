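#!/usr/bin/env python
"""Deterministic base case: both arms, horizons 1/2/30 years, both utility sets.

Writes results/basecase_summary.csv (per horizon, arm and utility set),
results/outcomes_90d.csv (the decision-tree distributions) and both arms'
cohort traces. The headline finding: thrombolysis costs ~CNY 10k more
over the first two years for ~0.09 extra QALYs (ICER ~113k CNY/QALY,
above the 105k threshold), but the gap widens to ~0.38 QALYs by 30 years
while the incremental cost stays flat, bringing the long-run ICER to
~27k CNY/QALY — far below the threshold, i.e. cost-effective long term.
"""

from pathlib import Path

import pandas as pd

import strokecea as sc
from strokecea.decision_tree import outcome_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = sc.default_config()
    rows = []
    for uset in ("base", "upper"):
        params = sc.with_utilities(cfg.params, uset)
        for r in sc.cea_at_horizons(cfg.windows, params, horizons=(1, 2, 30)):
            rows.append(
                {
                    "utility_set": uset, "horizon_years": r.horizon_years,
                    "qaly_control": r.qaly_control, "qaly_tpa": r.qaly_tpa,
                    "cost_control": r.cost_control, "cost_tpa": r.cost_tpa,
                    "delta_qaly": r.delta_qaly, "delta_cost": r.delta_cost,
                    "icer": r.icer,
                }
            )
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "basecase_summary.csv", index=False)
    outcome_table(cfg.windows).to_csv(RESULTS / "outcomes_90d.csv", index=False)
    for arm, trace in sc.run_arms(cfg.windows, cfg.params).items():
        trace.to_frame().to_csv(RESULTS / f"trace_{arm}.csv", index=False)

    pd.set_option("display.float_format", lambda v: f"{v:,.3f}")
    print("Base case (costs in 2011 CNY, discounted at 3%/yr):")
    print(summary.to_string(index=False))
    r30 = summary.query("utility_set == 'base' and horizon_years == 30").iloc[0]
    verdict = "cost-effective" if r30["icer"] < 105_000 else "not cost-effective"
    print(
        f"\n30-year ICER {r30['icer']:,.0f} CNY/QALY "
        f"(US$ {sc.cny_to_usd(r30['icer']):,.0f}) -> {verdict} "
        f"at the 3x-GDP threshold of CNY 105,000/QALY."
    )


if __name__ == "__main__":
    main()
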