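"""Age-specific non-stroke mortality and mRS-state hazard adjustment.

Only two points of the underlying census-derived schedule are published:
the annual non-stroke death probability at age 63 (0.0089) and at age 93
(0.1654). The schedule between them is reconstructed by log-linear
(geometric) interpolation, the natural choice for adult mortality, whose
hazard grows roughly exponentially with age (Gompertz). A linear
alternative is available for sensitivity checks. Beyond the upper anchor
the rate is held flat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ModelParams, ValidationError

__all__ = ["LifeTable", "build_life_table", "state_mortality"]

INTERP_METHODS = ("log_linear", "linear")


@dataclass(frozen=True)
class LifeTable:
    """Annual non-stroke death probability q(age) over the model horizon."""

    ages: np.ndarray
    q: np.ndarray

    def q_at(self, age: float) -> float:
        """q for the integer model age; flat beyond the tabulated range."""
        idx = int(round(age)) - int(self.ages[0])
        idx = min(max(idx, 0), len(self.q) - 1)
        return float(self.q[idx])

    def to_frame(self, params: ModelParams) -> pd.DataFrame:
        """Export as CSV-ready table with per-state adjusted probabilities."""
        return pd.DataFrame(
            {
                "age": self.ages,
                "q_nonstroke": self.q,
                "q_mrs01": state_mortality(self.q, params.hr_mrs01),
                "q_mrs23": state_mortality(self.q, params.hr_mrs23),
                "q_mrs45": state_mortality(self.q, params.hr_mrs45),
            }
        )


def build_life_table(params: ModelParams, method: str = "log_linear") -> LifeTable:
    """Interpolate the mortality schedule between the two printed anchors.

    log_linear: q(a) = q_lo * exp[(a - a_lo) * ln(q_hi/q_lo) / (a_hi - a_lo)],
    i.e. a constant annual growth factor. linear: straight line in q.
    Ages beyond the upper anchor keep the upper-anchor rate; values are
    capped strictly below 1.
    """
    if method not in INTERP_METHODS:
        raise ValueError(f"unknown interpolation method {method!r}")
    a_lo, a_hi = params.mort_anchor_age_lo, params.mort_anchor_age_hi
    q_lo, q_hi = params.mort_anchor_rate_lo, params.mort_anchor_rate_hi
    if not (q_lo > 0 and q_hi > q_lo and a_hi > a_lo):
        raise ValidationError("mortality anchors must satisfy 0 < q_lo < q_hi, a_lo < a_hi")
    last_age = int(params.start_age) + int(params.horizon_years)
    ages = np.arange(int(params.start_age), last_age + 1)
    frac = (np.minimum(ages, a_hi) - a_lo) / (a_hi - a_lo)
    if method == "log_linear":
        q = q_lo * np.exp(frac * math.log(q_hi / q_lo))
    else:
        q = q_lo + frac * (q_hi - q_lo)
    q = np.clip(q, None, 1.0 - 1e-12)
    return LifeTable(ages=ages, q=q)


def state_mortality(q_age, hr: float):
    """Adjust an annual death probability by a hazard ratio.

    Works on the hazard scale (probability -> cumulative hazard -> scale ->
    probability): 1 - (1 - q)^hr. Unlike probability multiplication this
    never exceeds 1. Accepts scalars or arrays.
    """
    if hr < 0:
        raise ValidationError("hazard ratio must be >= 0")
    return 1.0 - (1.0 - np.asarray(q_age)) ** hr if np.ndim(q_age) else 1.0 - (1.0 - q_age) ** hr
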