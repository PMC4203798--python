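"""One-way (tornado) and probabilistic sensitivity analysis.

The tornado re-runs the full 30-year base case with each parameter at its
range bounds. The PSA jointly resamples every uncertain input:
probabilities and utilities from beta distributions, costs and
ratio-scale quantities (odds ratios, hazard ratios, recurrence
escalation) from lognormals, with the printed ranges / CIs read as
central 95% intervals. Treated-arm 90-day outcome vectors, whose
sampling uncertainty the source tables do not print, are drawn with
binomial precision at the per-window cohort sample size, either as
independent beta margins renormalized to sum to 1 or as a Dirichlet.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import apply_override, cea_at_horizons
from .params import (
    ModelParams,
    ParamSpec,
    PSASettings,
    TimeWindowProfile,
    ValidationError,
)

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "one_way",
    "tornado",
    "draw_psa_params",
    "run_psa",
    "ceac",
    "default_wtp_grid",
    "WTP_PER_CAPITA_GDP",
    "WTP_3X_GDP",
]

log = logging.getLogger(__name__)

#: 1x and 3x 2011 China GDP per capita, CNY per QALY.
WTP_PER_CAPITA_GDP = 35_100.0
WTP_3X_GDP = 105_000.0


@dataclass(frozen=True)
class TornadoEntry:
    """One-way result for a single parameter over its plausible range."""

    name: str
    low_value: float
    high_value: float
    icer_at_low: float | str
    icer_at_high: float | str
    failed: bool = False

    @property
    def spread(self) -> float:
        if self.failed:
            return math.nan
        vals = [v for v in (self.icer_at_low, self.icer_at_high) if isinstance(v, float)]
        if len(vals) < 2:
            return math.inf  # a dominance flip counts as maximal spread
        return abs(vals[1] - vals[0])


def one_way(
    spec: ParamSpec,
    windows: Sequence[TimeWindowProfile],
    params: ModelParams,
    horizon: int = 30,
) -> TornadoEntry:
    """Re-run the deterministic model with one input at its low and high."""
    icers = []
    failed = False
    for value in (spec.low, spec.high):
        try:
            w2, p2 = apply_override(windows, params, spec.name, value)
            result = cea_at_horizons(w2, p2, horizons=(horizon,))[0]
            icers.append(result.icer)
        except (ValidationError, ValueError) as exc:
            log.warning("one-way failure for %s=%s: %s", spec.name, value, exc)
            icers.append(math.nan)
            failed = True
    return TornadoEntry(
        name=spec.name,
        low_value=spec.low,
        high_value=spec.high,
        icer_at_low=icers[0],
        icer_at_high=icers[1],
        failed=failed,
    )


def tornado(
    specs: Sequence[ParamSpec],
    windows: Sequence[TimeWindowProfile],
    params: ModelParams,
    horizon: int = 30,
    include_degenerate: bool = False,
) -> pd.DataFrame:
    """One-way analysis over all ranged specs, sorted by ICER spread."""
    entries = [
        one_way(s, windows, params, horizon)
        for s in specs
        if include_degenerate or not s.degenerate
    ]
    df = pd.DataFrame(
        {
            "param": [e.name for e in entries],
            "low_value": [e.low_value for e in entries],
            "high_value": [e.high_value for e in entries],
            "icer_at_low": [e.icer_at_low for e in entries],
            "icer_at_high": [e.icer_at_high for e in entries],
            "spread": [e.spread for e in entries],
            "failed": [e.failed for e in entries],
        }
    )
    return df.sort_values("spread", ascending=False, kind="mergesort").reset_index(drop=True)


# --- PSA -------------------------------------------------------------------


def _beta_moments(mean: float, sd: float) -> tuple[float, float] | None:
    """Method-of-moments beta shapes; None when infeasible (sd too large)."""
    if not 0 < mean < 1:
        return None
    var = sd * sd
    if var <= 0 or var >= mean * (1 - mean):
        return None
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


def _draw_one(spec: ParamSpec, rng: np.random.Generator, ci_divisor: float) -> float:
    if spec.degenerate or spec.dist_family == "fixed":
        return spec.base
    if spec.dist_family == "beta":
        sd = (spec.high - spec.low) / ci_divisor
        shapes = _beta_moments(spec.base, sd)
        if shapes is None:
            log.warning("beta moments infeasible for %s; falling back to uniform", spec.name)
            return float(rng.uniform(spec.low, spec.high))
        return float(rng.beta(*shapes))
    if spec.dist_family == "lognormal":
        sigma = (math.log(spec.high) - math.log(spec.low)) / ci_divisor
        if spec.base <= spec.low or spec.base >= spec.high:
            # base sits on a range bound (e.g. the mRS 0-1 mortality hazard
            # ratio, base 1.0 = low): a symmetric lognormal would put half
            # its mass outside the plausible range, so truncate to it
            while True:
                v = float(rng.lognormal(math.log(spec.base), sigma))
                if spec.low <= v <= spec.high:
                    return v
        return float(rng.lognormal(math.log(spec.base), sigma))
    raise ValidationError(f"{spec.name}: unknown dist_family {spec.dist_family}")


def draw_psa_params(
    specs: Sequence[ParamSpec],
    rng: np.random.Generator,
    ci_divisor: float = 3.92,
) -> dict[str, float]:
    """Independently sample every spec; returns name -> drawn value.

    Beta shapes are moment-matched to mean = base, SD = range/ci_divisor;
    lognormals use log-mean ln(base) and log-SD = (ln high - ln low)/ci_divisor;
    fixed and degenerate specs return their base.
    """
    for s in specs:
        s.validate()
    return {s.name: _draw_one(s, rng, ci_divisor) for s in specs}


def _draw_windows(
    windows: Sequence[TimeWindowProfile],
    rng: np.random.Generator,
    psa: PSASettings,
) -> list[TimeWindowProfile]:
    """Resample each window's treated-arm outcome vector and sICH rate.

    Precision matches binomial sampling at n_w = share * window_sample_size
    observed patients; shares themselves stay fixed (they describe the
    treated cohort's design, not an uncertain parameter).
    """
    if psa.window_multivariate == "fixed":
        return list(windows)
    out = []
    for w in windows:
        n_w = max(w.share * psa.window_sample_size, 2.0)
        p = w.p
        if psa.window_multivariate == "dirichlet":
            drawn = rng.dirichlet(np.maximum(p * n_w, 1e-3))
        else:
            margins = np.empty(4)
            for i, pi in enumerate(p):
                sd = math.sqrt(pi * (1 - pi) / n_w)
                shapes = _beta_moments(pi, sd)
                margins[i] = rng.beta(*shapes) if shapes else pi
            drawn = margins / margins.sum()
        sd = math.sqrt(w.p_sich * (1 - w.p_sich) / n_w)
        shapes = _beta_moments(w.p_sich, sd)
        p_sich = float(rng.beta(*shapes)) if shapes else w.p_sich
        out.append(
            dataclasses.replace(
                w,
                p_mrs01=float(drawn[0]), p_mrs23=float(drawn[1]),
                p_mrs45=float(drawn[2]), p_death=float(drawn[3]),
                p_sich=p_sich,
            )
        )
    return out


@dataclass(frozen=True)
class PSAResult:
    """Monte-Carlo cloud of incremental (cost, QALY) pairs plus the CEAC."""

    draws: int
    points: pd.DataFrame            # columns draw, delta_cost, delta_qaly
    ceac: pd.DataFrame              # columns wtp, probability
    seed: int
    failures: int = 0

    @property
    def frac_dominant(self) -> float:
        return float(
            ((self.points["delta_cost"] < 0) & (self.points["delta_qaly"] > 0)).mean()
        )

    def prob_cost_effective(self, wtp: float) -> float:
        dc = self.points["delta_cost"].to_numpy()
        dq = self.points["delta_qaly"].to_numpy()
        return float((wtp * dq - dc > 0).mean())


def default_wtp_grid() -> np.ndarray:
    """0 to 200,000 CNY in 1,000-CNY steps, with both GDP thresholds included."""
    return np.union1d(np.arange(0, 200_001, 1000, dtype=float),
                      [WTP_PER_CAPITA_GDP, WTP_3X_GDP])


def ceac(points: pd.DataFrame, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Fraction of draws with positive incremental net benefit per WTP."""
    if len(points) == 0:
        raise ValidationError("CEAC needs at least one PSA point")
    dc = points["delta_cost"].to_numpy()
    dq = points["delta_qaly"].to_numpy()
    wtp = np.asarray(wtp_grid, dtype=float)
    prob = [(w * dq - dc > 0).mean() for w in wtp]
    return pd.DataFrame({"wtp": wtp, "probability": prob})


def run_psa(
    n_draws: int,
    seed: int,
    windows: Sequence[TimeWindowProfile],
    params: ModelParams,
    specs: Sequence[ParamSpec],
    psa: PSASettings | None = None,
    horizon: int = 30,
    wtp_grid: Sequence[float] | None = None,
    interp: str = "log_linear",
) -> PSAResult:
    """Joint Monte-Carlo resampling of all inputs, 30-year model per draw.

    Fully reproducible given ``seed`` (one Generator stream). Draws whose
    sampled parameter set violates a model invariant (e.g. crossed hazard
    ratios) are resampled; more than 1% failures aborts.
    """
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    psa = psa or PSASettings()
    psa.validate()
    rng = np.random.default_rng(seed)
    wtp = np.asarray(wtp_grid, dtype=float) if wtp_grid is not None else default_wtp_grid()

    rows = np.empty((n_draws, 2))
    failures = 0
    max_failures = max(int(0.01 * n_draws), 1)
    i = 0
    while i < n_draws:
        sampled = draw_psa_params(specs, rng, psa.ci_divisor)
        # independent HR draws can rarely cross; project onto the ordered set
        if "hr_mrs01" in sampled and "hr_mrs23" in sampled:
            sampled["hr_mrs23"] = max(sampled["hr_mrs23"], sampled["hr_mrs01"])
        if "hr_mrs23" in sampled and "hr_mrs45" in sampled:
            sampled["hr_mrs45"] = max(sampled["hr_mrs45"], sampled["hr_mrs23"])
        try:
            w2 = _draw_windows(windows, rng, psa)
            p2 = params
            for name, value in sampled.items():
                w2, p2 = apply_override(w2, p2, name, value)
            p2.validate()
            result = cea_at_horizons(w2, p2, horizons=(horizon,), interp=interp)[0]
        except (ValidationError, ValueError) as exc:
            failures += 1
            log.warning("PSA draw failed (%d so far): %s", failures, exc)
            if failures > max_failures:
                raise RuntimeError(
                    f"PSA aborted: {failures} failed draws out of {i + failures}"
                ) from exc
            continue
        rows[i] = (result.delta_cost, result.delta_qaly)
        i += 1

    points = pd.DataFrame(
        {"draw": np.arange(n_draws), "delta_cost": rows[:, 0], "delta_qaly": rows[:, 1]}
    )
    return PSAResult(
        draws=n_draws,
        points=points,
        ceac=ceac(points, wtp),
        seed=seed,
        failures=failures,
    )
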