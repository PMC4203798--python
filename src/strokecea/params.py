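"""Model inputs: time-window outcome profiles, Markov parameters, PSA specs.

All defaults are the published base-case inputs of the Chinese tPA
cost-effectiveness model: three onset-to-needle windows (0-1.5, 1.5-3,
3-4.5 h) with observed 90-day modified-Rankin-Scale (mRS) outcome
distributions and pooled-trial odds ratios, plus the annual-cycle Markov
inputs (recurrence, case fatality, mortality hazard ratios and anchors,
costs in 2011 CNY, utilities, 3% discount rates).

A structured YAML config may override any value; unknown keys are
rejected and every parameter carries a provenance flag (default vs user).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "STATE_LABELS",
    "OddsRatio",
    "TimeWindowProfile",
    "ParamSpec",
    "ModelParams",
    "PSASettings",
    "ModelConfig",
    "ConfigError",
    "ValidationError",
    "normalize_distribution",
    "default_windows",
    "default_params",
    "default_param_specs",
    "default_config",
    "load_config",
    "save_config",
    "with_utilities",
    "cny_to_usd",
    "UPPER_UTILITIES",
]

#: Health-state order used everywhere: mRS 0-1, mRS 2-3, mRS 4-5, dead.
STATE_LABELS = ("mrs01", "mrs23", "mrs45", "dead")

#: CNY per USD conversion used for display only (2011 exchange rate).
CNY_PER_USD = 6.5

#: Column sums of printed percentages may miss 100% by rounding; anything
#: beyond half a percentage point is treated as a data error.
_RENORM_TOL = 0.005


class ConfigError(ValueError):
    """Raised when a config file cannot be parsed or contains unknown keys."""


class ValidationError(ValueError):
    """Raised when a parameter value violates a model invariant."""


def cny_to_usd(cny: float) -> float:
    """Display-only conversion of 2011 CNY to US dollars (divide by 6.5)."""
    return cny / CNY_PER_USD


@dataclass(frozen=True)
class OddsRatio:
    """Point estimate with 95% CI bounds, treatment vs control odds."""

    base: float
    low: float
    high: float

    def validate(self, name: str) -> None:
        if not (self.base > 0 and self.low > 0 and self.high > 0):
            raise ValidationError(f"{name}: odds ratios must be positive")
        if not (self.low <= self.base <= self.high):
            raise ValidationError(f"{name}: require low <= base <= high")


@dataclass(frozen=True)
class TimeWindowProfile:
    """One onset-to-needle window: cohort share, 90-day tPA outcomes, ORs.

    ``p_mrs01 .. p_death`` is the observed 90-day distribution under tPA;
    ``p_sich`` the symptomatic intracerebral hemorrhage rate; the odds
    ratios convert treated to control probabilities (treated odds /
    control odds).
    """

    label: str
    share: float
    p_mrs01: float
    p_mrs23: float
    p_mrs45: float
    p_death: float
    p_sich: float
    or_mrs01: OddsRatio
    or_death: OddsRatio
    or_sich: OddsRatio

    @property
    def p(self) -> np.ndarray:
        return np.array([self.p_mrs01, self.p_mrs23, self.p_mrs45, self.p_death])

    def validate(self) -> None:
        for name in ("share", "p_mrs01", "p_mrs23", "p_mrs45", "p_death", "p_sich"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"window {self.label}: {name}={v} outside [0, 1]")
        if abs(self.p.sum() - 1.0) > 1e-6:
            raise ValidationError(
                f"window {self.label}: outcome probabilities sum to "
                f"{self.p.sum():.6f}, not 1"
            )
        for name in ("or_mrs01", "or_death", "or_sich"):
            getattr(self, name).validate(f"window {self.label}: {name}")


def normalize_distribution(p: Sequence[float]) -> np.ndarray:
    """Scale a non-negative probability vector to sum exactly to 1.

    Printed percentages are rounded to 2 dp, so column sums can miss 100%
    slightly; deviations beyond 0.5 percentage points raise instead of
    being silently absorbed.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("probability vector has negative entries")
    total = arr.sum()
    if total <= 0:
        raise ValidationError("probability vector sums to zero")
    if abs(total - 1.0) > _RENORM_TOL:
        raise ValidationError(
            f"probability vector sums to {total:.4f}; deviation exceeds "
            f"rounding tolerance {_RENORM_TOL}"
        )
    return arr / total


@dataclass(frozen=True)
class ParamSpec:
    """One scalar model input with its plausible range and PSA family."""

    name: str
    base: float
    low: float
    high: float
    dist_family: str  # beta | lognormal | fixed

    def validate(self) -> None:
        if self.dist_family not in ("beta", "lognormal", "fixed"):
            raise ValidationError(f"{self.name}: unknown dist_family {self.dist_family}")
        if not (self.low <= self.base <= self.high):
            raise ValidationError(
                f"{self.name}: base {self.base} outside range [{self.low}, {self.high}]"
            )
        if self.dist_family == "beta" and not (0 <= self.low and self.high <= 1):
            raise ValidationError(f"{self.name}: beta family requires range within [0, 1]")
        if self.dist_family == "lognormal" and self.low <= 0:
            raise ValidationError(f"{self.name}: lognormal family requires positive range")

    @property
    def degenerate(self) -> bool:
        return self.low == self.high


@dataclass(frozen=True)
class ModelParams:
    """Markov-cycle inputs: recurrence, mortality, costs, utilities, discounting.

    Costs are 2011 CNY. ``recur_rate`` is the annual stroke-recurrence
    probability, escalated ``recur_rr_per_year``-fold per life year.
    Non-stroke mortality is anchored at two printed ages and adjusted per
    state by hazard ratios on the hazard scale.
    """

    recur_rate: float = 0.1181
    recur_rr_per_year: float = 1.019
    recur_case_fatality: float = 0.2101
    hr_mrs01: float = 1.0
    hr_mrs23: float = 1.19
    hr_mrs45: float = 2.04
    mort_anchor_age_lo: float = 63.0
    mort_anchor_rate_lo: float = 0.0089
    mort_anchor_age_hi: float = 93.0
    mort_anchor_rate_hi: float = 0.1654
    cost_tpa_addon: float = 10830.0
    cost_sich_addon: float = 2300.0
    cost_hosp_mrs01: float = 9526.0
    cost_hosp_mrs25: float = 12595.0
    cost_hosp_mrs6: float = 10794.0
    cost_annual_mrs01: float = 6773.0
    cost_annual_mrs25: float = 10305.0
    utility_mrs01: float = 0.80
    utility_mrs23: float = 0.58
    utility_mrs45: float = 0.28
    utility_death: float = 0.0
    disc_cost: float = 0.03
    disc_outcome: float = 0.03
    start_age: float = 63.0
    horizon_years: int = 30

    @property
    def utilities(self) -> np.ndarray:
        return np.array(
            [self.utility_mrs01, self.utility_mrs23, self.utility_mrs45, self.utility_death]
        )

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.array([self.hr_mrs01, self.hr_mrs23, self.hr_mrs45])

    def validate(self) -> None:
        for name in ("utility_mrs01", "utility_mrs23", "utility_mrs45", "utility_death"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.utility_death != 0.0:
            raise ValidationError("utility_death must be exactly 0")
        for name in ("disc_cost", "disc_outcome"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in (
            "cost_tpa_addon", "cost_sich_addon", "cost_hosp_mrs01",
            "cost_hosp_mrs25", "cost_hosp_mrs6", "cost_annual_mrs01",
            "cost_annual_mrs25",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (1.0 <= self.hr_mrs01 <= self.hr_mrs23 <= self.hr_mrs45):
            raise ValidationError(
                "hazard ratios must satisfy 1 <= hr_mrs01 <= hr_mrs23 <= hr_mrs45"
            )
        for name in ("recur_rate", "recur_case_fatality"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} outside [0, 1]")
        if self.recur_rr_per_year <= 0:
            raise ValidationError("recur_rr_per_year must be positive")
        if not (0 < self.mort_anchor_rate_lo < self.mort_anchor_rate_hi < 1):
            raise ValidationError("mortality anchors must satisfy 0 < lo < hi < 1")
        if self.mort_anchor_age_hi <= self.mort_anchor_age_lo:
            raise ValidationError("mortality anchor ages must be increasing")
        if self.horizon_years < 1:
            raise ValidationError("horizon_years must be >= 1")


#: Upper-range utility set (Table-range highs); the published 1-year QALY
#: levels are consistent with these rather than the base utilities.
UPPER_UTILITIES = {"utility_mrs01": 0.95, "utility_mrs23": 0.78, "utility_mrs45": 0.36}


def with_utilities(params: ModelParams, which: str = "base") -> ModelParams:
    """Return params with the base or upper-range utility set installed."""
    if which == "base":
        return params
    if which == "upper":
        return dataclasses.replace(params, **UPPER_UTILITIES)
    raise ValueError(f"unknown utility set {which!r} (expected 'base' or 'upper')")


@dataclass(frozen=True)
class PSASettings:
    """Knobs of the probabilistic sensitivity analysis parameterization.

    Ranges are read as central 95% intervals (``ci_divisor`` = 3.92 turns a
    range width into an SD). Window outcome vectors are drawn either as
    independent beta margins renormalized to 1, or as a Dirichlet;
    ``window_sample_size`` sets the binomial precision of those draws to the
    size of the observed treated cohort.
    """

    ci_divisor: float = 3.92
    window_multivariate: str = "independent_beta"  # or "dirichlet" / "fixed"
    window_sample_size: int = 1128

    def validate(self) -> None:
        if self.ci_divisor <= 0:
            raise ValidationError("ci_divisor must be positive")
        if self.window_multivariate not in ("independent_beta", "dirichlet", "fixed"):
            raise ValidationError(
                f"unknown window_multivariate {self.window_multivariate!r}"
            )
        if self.window_sample_size < 2:
            raise ValidationError("window_sample_size must be >= 2")


def default_windows() -> list[TimeWindowProfile]:
    """The three printed onset-to-needle windows of the treated cohort.

    The sICH odds ratio for 0-1.5 h is assumed equal to the 1.5-3 h value
    (no pooled estimate exists for the earliest window); it is an ordinary
    default and can be overridden in config.
    """
    return [
        TimeWindowProfile(
            label="0-1.5h", share=0.0568,
            p_mrs01=0.5397, p_mrs23=0.2381, p_mrs45=0.0952, p_death=0.1270,
            p_sich=0.0469,
            or_mrs01=OddsRatio(2.55, 1.44, 4.52),
            or_death=OddsRatio(0.78, 0.41, 1.48),
            or_sich=OddsRatio(8.23, 2.39, 28.32),
        ),
        TimeWindowProfile(
            label="1.5-3h", share=0.6113,
            p_mrs01=0.4711, p_mrs23=0.2489, p_mrs45=0.1837, p_death=0.0963,
            p_sich=0.0305,
            or_mrs01=OddsRatio(1.64, 1.12, 2.40),
            or_death=OddsRatio(1.13, 0.70, 1.82),
            or_sich=OddsRatio(8.23, 2.39, 28.32),
        ),
        TimeWindowProfile(
            label="3-4.5h", share=0.3319,
            p_mrs01=0.4809, p_mrs23=0.2514, p_mrs45=0.1530, p_death=0.1147,
            p_sich=0.0535,
            or_mrs01=OddsRatio(1.34, 1.06, 1.68),
            or_death=OddsRatio(1.22, 0.87, 1.71),
            or_sich=OddsRatio(3.61, 1.76, 7.38),
        ),
    ]


def default_params() -> ModelParams:
    return ModelParams()


# (name, base, low, high, family) for every ranged scalar input.
_SPEC_TABLE: tuple[tuple[str, float, float, float, str], ...] = (
    ("recur_rate", 0.1181, 0.1123, 0.1241, "beta"),
    ("recur_rr_per_year", 1.019, 1.014, 1.024, "lognormal"),
    ("recur_case_fatality", 0.2101, 0.1887, 0.2316, "beta"),
    ("hr_mrs01", 1.0, 1.0, 1.2, "lognormal"),
    ("hr_mrs23", 1.19, 1.1, 1.3, "lognormal"),
    ("hr_mrs45", 2.04, 1.4, 3.0, "lognormal"),
    ("cost_tpa_addon", 10830.0, 8385.0, 12630.0, "lognormal"),
    ("cost_sich_addon", 2300.0, 500.0, 4800.0, "lognormal"),
    ("cost_hosp_mrs01", 9526.0, 5502.0, 11994.0, "lognormal"),
    ("cost_hosp_mrs25", 12595.0, 6922.0, 16516.0, "lognormal"),
    ("cost_hosp_mrs6", 10794.0, 5072.0, 14267.0, "lognormal"),
    ("cost_annual_mrs01", 6773.0, 2028.0, 8639.0, "lognormal"),
    ("cost_annual_mrs25", 10305.0, 2592.0, 12959.0, "lognormal"),
    ("utility_mrs01", 0.80, 0.80, 0.95, "beta"),
    ("utility_mrs23", 0.58, 0.56, 0.78, "beta"),
    ("utility_mrs45", 0.28, 0.05, 0.36, "beta"),
    ("utility_death", 0.0, 0.0, 0.0, "fixed"),
    # Discount-rate ranges feed the one-way analysis only; the PSA samples
    # probabilities/utilities (beta) and costs/ratios (lognormal), not
    # discount rates, hence family "fixed".
    ("disc_cost", 0.03, 0.03, 0.08, "fixed"),
    ("disc_outcome", 0.03, 0.024, 0.036, "fixed"),
)


def default_param_specs(windows: Iterable[TimeWindowProfile] | None = None) -> list[ParamSpec]:
    """Every ranged input as a ParamSpec, including per-window odds ratios.

    OR specs are named ``or_<endpoint>@<window label>`` so one-way analysis
    can perturb a single window's ratio.
    """
    specs = [ParamSpec(*row) for row in _SPEC_TABLE]
    for w in windows if windows is not None else default_windows():
        for endpoint in ("mrs01", "death", "sich"):
            o: OddsRatio = getattr(w, f"or_{endpoint}")
            specs.append(
                ParamSpec(f"or_{endpoint}@{w.label}", o.base, o.low, o.high, "lognormal")
            )
    return specs


@dataclass(frozen=True)
class ModelConfig:
    """A fully validated parameter set plus provenance (default vs user)."""

    windows: tuple[TimeWindowProfile, ...]
    params: ModelParams
    specs: tuple[ParamSpec, ...]
    psa: PSASettings
    provenance: Mapping[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        shares = sum(w.share for w in self.windows)
        if abs(shares - 1.0) > 1e-6:
            raise ValidationError(f"window shares sum to {shares:.6f}, not 1")
        for w in self.windows:
            w.validate()
        self.params.validate()
        for s in self.specs:
            s.validate()
        self.psa.validate()


# --- config file I/O -------------------------------------------------------

_PARAM_SECTIONS = {
    "markov": (
        "recur_rate", "recur_rr_per_year", "recur_case_fatality",
        "hr_mrs01", "hr_mrs23", "hr_mrs45",
        "mort_anchor_age_lo", "mort_anchor_rate_lo",
        "mort_anchor_age_hi", "mort_anchor_rate_hi",
        "start_age", "horizon_years",
    ),
    "costs": (
        "cost_tpa_addon", "cost_sich_addon", "cost_hosp_mrs01",
        "cost_hosp_mrs25", "cost_hosp_mrs6", "cost_annual_mrs01",
        "cost_annual_mrs25",
    ),
    "utilities": ("utility_mrs01", "utility_mrs23", "utility_mrs45", "utility_death"),
    "discounting": ("disc_cost", "disc_outcome"),
}

_WINDOW_SCALARS = ("share", "p_mrs01", "p_mrs23", "p_mrs45", "p_death", "p_sich")
_WINDOW_ORS = ("or_mrs01", "or_death", "or_sich")
_PSA_KEYS = ("ci_divisor", "window_multivariate", "window_sample_size")


def default_config() -> ModelConfig:
    """The full built-in parameter set (everything at its printed value)."""
    windows = tuple(default_windows())
    cfg = ModelConfig(
        windows=windows,
        params=default_params(),
        specs=tuple(default_param_specs(windows)),
        psa=PSASettings(),
        provenance={},
    )
    cfg.validate()
    return cfg


def _merge_windows(
    defaults: Sequence[TimeWindowProfile], overrides: object, provenance: dict[str, str]
) -> list[TimeWindowProfile]:
    if overrides is None:
        return list(defaults)
    if not isinstance(overrides, list):
        raise ConfigError("'windows' section must be a list of window mappings")
    by_label = {w.label: w for w in defaults}
    for entry in overrides:
        if not isinstance(entry, Mapping) or "label" not in entry:
            raise ConfigError("each windows entry must be a mapping with a 'label' key")
        label = str(entry["label"])
        if label not in by_label:
            raise ConfigError(
                f"unknown window label {label!r} (expected one of {sorted(by_label)})"
            )
        w = by_label[label]
        updates: dict[str, object] = {}
        for key, value in entry.items():
            if key == "label":
                continue
            if key in _WINDOW_SCALARS:
                updates[key] = float(value)
            elif key in _WINDOW_ORS:
                seq = list(value) if isinstance(value, (list, tuple)) else None
                if seq is None or len(seq) != 3:
                    raise ConfigError(f"window {label}: {key} must be [base, low, high]")
                updates[key] = OddsRatio(*(float(v) for v in seq))
            else:
                raise ConfigError(f"unknown key {key!r} in window {label}")
            provenance[f"{key}@{label}"] = "user"
        by_label[label] = dataclasses.replace(w, **updates)
    return [by_label[w.label] for w in defaults]


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load a YAML config, filling gaps with the built-in printed defaults.

    Sections: ``windows``, ``markov``, ``costs``, ``utilities``,
    ``discounting``, ``psa``. Unknown sections or keys raise
    :class:`ConfigError`; invariant violations raise
    :class:`ValidationError` naming the offending parameter.
    """
    if path is None:
        return default_config()
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # mark the line if the parser knows it
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"malformed config{where}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError("config root must be a mapping of sections")

    known_sections = set(_PARAM_SECTIONS) | {"windows", "psa"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")

    provenance: dict[str, str] = {}
    param_updates: dict[str, float] = {}
    for section, keys in _PARAM_SECTIONS.items():
        body = raw.get(section)
        if body is None:
            continue
        if not isinstance(body, Mapping):
            raise ConfigError(f"section {section!r} must be a mapping")
        bad = set(body) - set(keys)
        if bad:
            raise ConfigError(f"unknown key(s) in section {section!r}: {sorted(bad)}")
        for key, value in body.items():
            param_updates[key] = (
                int(value) if key == "horizon_years" else float(value)
            )
            provenance[key] = "user"

    psa_body = raw.get("psa") or {}
    if not isinstance(psa_body, Mapping):
        raise ConfigError("section 'psa' must be a mapping")
    bad = set(psa_body) - set(_PSA_KEYS)
    if bad:
        raise ConfigError(f"unknown key(s) in section 'psa': {sorted(bad)}")
    psa_kwargs: dict[str, object] = dict(psa_body)
    for k in psa_kwargs:
        provenance[f"psa.{k}"] = "user"

    windows = _merge_windows(default_windows(), raw.get("windows"), provenance)
    params = dataclasses.replace(default_params(), **param_updates)
    for name in _iter_param_names():
        provenance.setdefault(name, "default")

    cfg = ModelConfig(
        windows=tuple(windows),
        params=params,
        specs=tuple(default_param_specs(windows)),
        psa=PSASettings(**psa_kwargs),
        provenance=provenance,
    )
    cfg.validate()
    return cfg


def _iter_param_names():
    for keys in _PARAM_SECTIONS.values():
        yield from keys


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    """Serialize a full parameter set to YAML (round-trips via load_config)."""
    doc: dict[str, object] = {}
    for section, keys in _PARAM_SECTIONS.items():
        doc[section] = {k: getattr(cfg.params, k) for k in keys}
    doc["windows"] = [
        {
            "label": w.label,
            **{k: getattr(w, k) for k in _WINDOW_SCALARS},
            **{
                k: [getattr(w, k).base, getattr(w, k).low, getattr(w, k).high]
                for k in _WINDOW_ORS
            },
        }
        for w in cfg.windows
    ]
    doc["psa"] = {
        "ci_divisor": cfg.psa.ci_divisor,
        "window_multivariate": cfg.psa.window_multivariate,
        "window_sample_size": cfg.psa.window_sample_size,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
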