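import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from strokecea.cea import icer
from strokecea.model import apply_override, cea_at_horizons
from strokecea.params import ParamSpec, PSASettings, ValidationError
from strokecea.sensitivity import (
    WTP_3X_GDP,
    WTP_PER_CAPITA_GDP,
    ceac,
    default_wtp_grid,
    draw_psa_params,
    one_way,
    run_psa,
    tornado,
)


@pytest.fixture(scope="module")
def base_icer(cfg):
    return cea_at_horizons(cfg.windows, cfg.params, horizons=(30,))[0].icer


def test_apply_override_scalar_and_or(cfg):
    w2, p2 = apply_override(cfg.windows, cfg.params, "disc_cost", 0.05)
    assert p2.disc_cost == 0.05 and w2[0] == cfg.windows[0]
    w2, p2 = apply_override(cfg.windows, cfg.params, "or_mrs01@1.5-3h", 2.0)
    assert {w.label: w for w in w2}["1.5-3h"].or_mrs01.base == 2.0
    with pytest.raises(ValidationError):
        apply_override(cfg.windows, cfg.params, "or_mrs01@9h", 2.0)
    with pytest.raises(ValidationError):
        apply_override(cfg.windows, cfg.params, "bogus", 2.0)


def test_one_way_degenerate_returns_base(cfg, base_icer):
    spec = ParamSpec("recur_rate", 0.1181, 0.1181, 0.1181, "beta")
    entry = one_way(spec, cfg.windows, cfg.params)
    assert entry.icer_at_low == pytest.approx(base_icer, rel=1e-12)
    assert entry.icer_at_high == pytest.approx(base_icer, rel=1e-12)
    assert entry.spread == pytest.approx(0.0, abs=1e-9)


def test_one_way_direction_for_key_drivers(cfg, base_icer):
    """A stronger favorable-outcome OR or dearer disabled care lowers the ICER."""
    specs = {s.name: s for s in cfg.specs}
    e = one_way(specs["or_mrs01@1.5-3h"], cfg.windows, cfg.params)
    assert e.icer_at_high < base_icer < e.icer_at_low
    e = one_way(specs["cost_annual_mrs25"], cfg.windows, cfg.params)
    assert e.icer_at_high < base_icer < e.icer_at_low


def test_tornado_sorted_and_complete(cfg):
    df = tornado(cfg.specs, cfg.windows, cfg.params)
    ranged = [s for s in cfg.specs if not s.degenerate]
    assert len(df) == len(ranged)
    spreads = df["spread"].to_numpy()
    finite = spreads[np.isfinite(spreads)]
    assert np.all(np.diff(finite) <= 1e-9)
    assert not df["failed"].any()


# --- parameter sampling ---------------------------------------------------

def test_degenerate_spec_draws_base():
    rng = np.random.default_rng(0)
    spec = ParamSpec("x", 0.5, 0.5, 0.5, "beta")
    vals = {draw_psa_params([spec], rng)["x"] for _ in range(20)}
    assert vals == {0.5}


def test_beta_draw_moments():
    rng = np.random.default_rng(1)
    spec = ParamSpec("utility_mrs45", 0.28, 0.05, 0.36, "beta")
    draws = np.array([draw_psa_params([spec], rng)["utility_mrs45"] for _ in range(10_000)])
    assert np.all((draws >= 0) & (draws <= 1))
    sd = (0.36 - 0.05) / 3.92
    assert draws.mean() == pytest.approx(0.28, abs=3 * sd / math.sqrt(len(draws)))
    assert draws.std() == pytest.approx(sd, rel=0.1)


def test_lognormal_draw_moments():
    rng = np.random.default_rng(2)
    spec = ParamSpec("cost_tpa_addon", 10830, 8385, 12630, "lognormal")
    draws = np.array(
        [draw_psa_params([spec], rng)["cost_tpa_addon"] for _ in range(10_000)]
    )
    assert np.all(draws > 0)
    sigma = (math.log(12630) - math.log(8385)) / 3.92
    log_mean = np.log(draws).mean()
    assert log_mean == pytest.approx(
        math.log(10830), abs=3 * sigma / math.sqrt(len(draws))
    )
    assert np.log(draws).std() == pytest.approx(sigma, rel=0.1)


def test_boundary_base_lognormal_truncated_to_range():
    rng = np.random.default_rng(3)
    spec = ParamSpec("hr_mrs01", 1.0, 1.0, 1.2, "lognormal")
    draws = np.array([draw_psa_params([spec], rng)["hr_mrs01"] for _ in range(2000)])
    assert np.all((draws >= 1.0) & (draws <= 1.2))


def test_base_outside_range_rejected():
    with pytest.raises(ValidationError):
        draw_psa_params(
            [ParamSpec("x", 0.9, 0.1, 0.5, "beta")], np.random.default_rng(0)
        )


def test_infeasible_beta_falls_back_to_uniform():
    # a tiny CI divisor implies an SD beyond any beta's: uniform fallback
    rng = np.random.default_rng(4)
    spec = ParamSpec("wide", 0.5, 0.0, 1.0, "beta")
    vals = [draw_psa_params([spec], rng, ci_divisor=0.5)["wide"] for v in range(200)]
    assert all(0.0 <= v <= 1.0 for v in vals)
    assert np.std(vals) > 0.2  # spread consistent with uniform, not collapsed


# --- CEAC -----------------------------------------------------------------

def test_wtp_grid_contains_thresholds():
    grid = default_wtp_grid()
    assert WTP_PER_CAPITA_GDP in grid and WTP_3X_GDP in grid
    assert grid[0] == 0.0 and grid[-1] == 200_000.0


def test_ceac_closed_forms():
    points = pd.DataFrame(
        {"delta_cost": [-10.0, 5.0, 20.0], "delta_qaly": [0.1, 0.2, 0.4]}
    )
    curve = ceac(points, [0.0])
    assert curve["probability"].iloc[0] == pytest.approx(1 / 3)  # frac delta_cost < 0
    dominant = pd.DataFrame({"delta_cost": [-1.0, -2.0], "delta_qaly": [0.1, 0.2]})
    assert (ceac(dominant, [0, 1000, 1e6])["probability"] == 1.0).all()


def test_ceac_monotone_when_all_gain(cfg):
    res = run_psa(200, 7, cfg.windows, cfg.params, cfg.specs, cfg.psa)
    pts = res.points[res.points["delta_qaly"] > 0]
    curve = ceac(pts, np.arange(0, 200_001, 5000))
    assert np.all(np.diff(curve["probability"].to_numpy()) >= -1e-12)


def test_ceac_limit_is_fraction_gaining(cfg):
    res = run_psa(300, 11, cfg.windows, cfg.params, cfg.specs, cfg.psa)
    frac_gain = (res.points["delta_qaly"] > 0).mean()
    assert res.prob_cost_effective(1e12) == pytest.approx(frac_gain, abs=1e-12)
    for wtp in (1000.0, 35_100.0, 105_000.0):
        assert res.frac_dominant <= res.prob_cost_effective(wtp) + 1e-12


# --- PSA ------------------------------------------------------------------

def test_psa_deterministic_given_seed(cfg):
    a = run_psa(50, 123, cfg.windows, cfg.params, cfg.specs, cfg.psa)
    b = run_psa(50, 123, cfg.windows, cfg.params, cfg.specs, cfg.psa)
    pd.testing.assert_frame_equal(a.points, b.points)
    pd.testing.assert_frame_equal(a.ceac, b.ceac)
    c = run_psa(50, 124, cfg.windows, cfg.params, cfg.specs, cfg.psa)
    assert not a.points.equals(c.points)


def test_psa_degenerate_collapses_to_base_case(cfg):
    """All-degenerate distributions reproduce the deterministic base case."""
    degen = [dataclasses.replace(s, low=s.base, high=s.base) for s in cfg.specs]
    psa = PSASettings(window_multivariate="fixed")
    res = run_psa(20, 5, cfg.windows, cfg.params, degen, psa)
    base = cea_at_horizons(cfg.windows, cfg.params, horizons=(30,))[0]
    assert np.allclose(res.points["delta_cost"], base.delta_cost)
    assert np.allclose(res.points["delta_qaly"], base.delta_qaly)
    # CEAC is then a step function at the base-case ICER
    grid = np.array([base.icer * 0.5, base.icer * 2.0])
    curve = ceac(res.points, grid)
    assert list(curve["probability"]) == [0.0, 1.0]


def test_psa_invalid_draw_count(cfg):
    with pytest.raises(ValidationError):
        run_psa(0, 1, cfg.windows, cfg.params, cfg.specs, cfg.psa)
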