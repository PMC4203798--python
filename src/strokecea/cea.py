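"""Incremental cost-effectiveness metrics: ICER, dominance, net benefit."""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["CEAResult", "icer", "nmb", "DOMINANT", "DOMINATED"]

DOMINANT = "dominant"
DOMINATED = "dominated"


@dataclass(frozen=True)
class CEAResult:
    """Two-arm comparison at one horizon (costs in CNY, outcomes in QALYs)."""

    cost_control: float
    cost_tpa: float
    qaly_control: float
    qaly_tpa: float
    horizon_years: int

    @property
    def delta_cost(self) -> float:
        return self.cost_tpa - self.cost_control

    @property
    def delta_qaly(self) -> float:
        return self.qaly_tpa - self.qaly_control

    @property
    def icer(self) -> float | str:
        """Δcost/ΔQALY; dominance labels when the ratio is not meaningful.

        "dominant": cheaper and more effective; "dominated": costlier and
        less effective; ΔQALY == 0 gives a signed infinity.
        """
        dc, dq = self.delta_cost, self.delta_qaly
        if dq > 0 and dc < 0:
            return DOMINANT
        if dq < 0 and dc > 0:
            return DOMINATED
        if dq == 0:
            return math.copysign(math.inf, dc) if dc != 0 else math.nan
        return dc / dq

    def cost_effective(self, wtp: float) -> bool:
        """Strict ICER < willingness-to-pay rule (dominant always passes)."""
        val = self.icer
        if val == DOMINANT:
            return True
        if val == DOMINATED:
            return False
        return val < wtp


def icer(control: tuple[float, float], tpa: tuple[float, float], horizon_years: int = 30) -> CEAResult:
    """Build a CEAResult from (cost, qaly) pairs of the two arms."""
    return CEAResult(
        cost_control=control[0],
        cost_tpa=tpa[0],
        qaly_control=control[1],
        qaly_tpa=tpa[1],
        horizon_years=horizon_years,
    )


def nmb(result: CEAResult, wtp: float) -> float:
    """Incremental net monetary benefit at a willingness-to-pay threshold.

    wtp * ΔQALY - Δcost; positive exactly when treatment is cost-effective
    at that threshold.
    """
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * result.delta_qaly - result.delta_cost
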