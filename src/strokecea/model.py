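"""End-to-end base-case pipeline: windows -> arms -> traces -> CEA summary."""

from __future__ import annotations

import dataclasses
import re
from typing import Sequence

import pandas as pd

from .cea import CEAResult, icer
from .decision_tree import pooled_arm_outcomes
from .markov import CohortTrace, run_cohort
from .mortality import build_life_table
from .params import ModelParams, OddsRatio, TimeWindowProfile, ValidationError

__all__ = ["run_arms", "cea_at_horizons", "summary_frame", "apply_override"]

_OR_OVERRIDE = re.compile(r"^or_(mrs01|death|sich)@(.+)$")


def run_arms(
    windows: Sequence[TimeWindowProfile],
    params: ModelParams,
    horizon_years: int | None = None,
    interp: str = "log_linear",
) -> dict[str, CohortTrace]:
    """Run both arms' cohorts from the pooled 90-day distributions."""
    life_table = build_life_table(params, method=interp)
    horizon = params.horizon_years if horizon_years is None else horizon_years
    return {
        arm: run_cohort(arm, pooled_arm_outcomes(windows, arm), params, life_table, horizon)
        for arm in ("control", "tpa")
    }


def cea_at_horizons(
    windows: Sequence[TimeWindowProfile],
    params: ModelParams,
    horizons: Sequence[int] = (1, 2, 30),
    interp: str = "log_linear",
) -> list[CEAResult]:
    """Base-case CEA results at each requested horizon (one cohort run)."""
    horizons = sorted(horizons)
    traces = run_arms(windows, params, horizon_years=max(horizons), interp=interp)
    results = []
    for h in horizons:
        cost_c, qaly_c = traces["control"].at_horizon(h)
        cost_t, qaly_t = traces["tpa"].at_horizon(h)
        results.append(icer((cost_c, qaly_c), (cost_t, qaly_t), horizon_years=h))
    return results


def summary_frame(results: Sequence[CEAResult]) -> pd.DataFrame:
    """Per-horizon, per-arm summary table (QALYs, cost, ICER vs control)."""
    rows = []
    for r in results:
        rows.append(
            {
                "horizon_years": r.horizon_years, "arm": "control",
                "qalys": r.qaly_control, "cost_cny": r.cost_control, "icer": "",
            }
        )
        rows.append(
            {
                "horizon_years": r.horizon_years, "arm": "tpa",
                "qalys": r.qaly_tpa, "cost_cny": r.cost_tpa, "icer": r.icer,
            }
        )
    return pd.DataFrame(rows)


def apply_override(
    windows: Sequence[TimeWindowProfile],
    params: ModelParams,
    name: str,
    value: float,
) -> tuple[list[TimeWindowProfile], ModelParams]:
    """Return (windows, params) with a single named input replaced.

    Scalar inputs address ModelParams fields directly; odds ratios use
    ``or_<endpoint>@<window label>`` and replace only that window's point
    estimate (CI bounds widened if needed so the profile stays valid).
    """
    m = _OR_OVERRIDE.match(name)
    if m:
        endpoint, label = m.groups()
        new_windows = []
        hit = False
        for w in windows:
            if w.label == label:
                old: OddsRatio = getattr(w, f"or_{endpoint}")
                new = OddsRatio(
                    base=value, low=min(old.low, value), high=max(old.high, value)
                )
                w = dataclasses.replace(w, **{f"or_{endpoint}": new})
                hit = True
            new_windows.append(w)
        if not hit:
            raise ValidationError(f"no window labelled {label!r}")
        return new_windows, params
    if hasattr(params, name):
        return list(windows), dataclasses.replace(params, **{name: value})
    raise ValidationError(f"unknown parameter {name!r}")
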