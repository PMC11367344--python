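"""Discounting, ICER/dominance, one-way SA mechanics, PSA and CEAC."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ohtsim import (CEResult, ConfigurationError, EconParams, PSASpec,
                    Scenario, discounted_accrual, icer, one_way_sa, run_psa,
                    run_strategy)
from ohtsim.config import default_params
from ohtsim.economics import (_beta_moment_match, _gamma_moment_match,
                              ceac_from_nmb, draw_second_order)
from ohtsim.engine import StrategyResult

RHO = math.log(1.035)


def _res(cost, qaly, strategy="sc"):
    return StrategyResult(strategy=strategy, n=1, mean_cost=cost,
                          mean_qaly=qaly, frac_treated=0, frac_converted=0,
                          end_state_dist=(1, 0, 0, 0, 0),
                          costs=np.array([cost]), qalys=np.array([qaly]))


def test_discounted_accrual_values():
    assert discounted_accrual(0.8015, 0, 1, 0.0) == pytest.approx(0.8015)
    got = discounted_accrual(0.8015, 0, 1, RHO)
    from scipy.integrate import quad
    ref, _ = quad(lambda t: 0.8015 * math.exp(-RHO * t), 0, 1)
    assert got == pytest.approx(ref, abs=1e-12)
    assert got == pytest.approx(0.7879, abs=2e-4)
    assert discounted_accrual(5.0, 2.0, 2.0, RHO) == 0.0
    with pytest.raises(ConfigurationError):
        discounted_accrual(1.0, 2.0, 1.0, RHO)


@given(st.floats(0, 30), st.floats(0, 30), st.floats(0, 30),
       st.floats(0.001, 0.2))
def test_discounted_accrual_additive_and_bounded(a, b, c, rho):
    t0, t1, t2 = sorted((a, b, c))
    whole = discounted_accrual(1.0, t0, t2, rho)
    split = (discounted_accrual(1.0, t0, t1, rho)
             + discounted_accrual(1.0, t1, t2, rho))
    assert whole == pytest.approx(split, abs=1e-9)
    assert whole <= (t2 - t0) + 1e-12


def test_icer_division_and_dominance_labels():
    ce = icer(_res(4662.0, 10.89), _res(4924.0, 10.913, "rp"))
    assert ce.icer == pytest.approx(262.0 / 0.023, rel=1e-6)
    assert ce.label == "icer"
    assert icer(_res(100, 10.0), _res(90, 10.01, "rp")).label == "rp_dominant"
    assert icer(_res(100, 10.0), _res(200, 9.99, "rp")).label == "rp_dominated"
    assert "compare costs" in icer(_res(100, 10.0), _res(90, 10.0, "rp")).label


def test_icer_against_itself_is_null(small_params, small_cohort):
    a = run_strategy(small_cohort, "sc", small_params, master_seed=1)
    b = run_strategy(small_cohort, "sc", small_params, master_seed=1)
    ce = icer(a, b)
    assert ce.delta_cost == 0.0 and ce.delta_qaly == 0.0


# --- CEAC -----------------------------------------------------------------

def test_ceac_definition_at_zero_threshold():
    dq = np.array([0.01, 0.02, -0.01, 0.03])
    dc = np.array([-5.0, 10.0, -1.0, 2.0])
    pts = ceac_from_nmb(dq, dc, [0.0])
    assert pts[0][1] == np.mean(dc < 0)


def test_ceac_monotone_when_all_replicates_gain_qalys():
    rng = np.random.default_rng(1)
    dq = rng.uniform(0.001, 0.05, 200)
    dc = rng.normal(200, 150, 200)
    grid = np.arange(0, 50001, 1000.0)
    pts = ceac_from_nmb(dq, dc, grid)
    vals = [p for _, p in pts]
    assert all(0.0 <= v <= 1.0 for v in vals)
    assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))


def test_ceac_nmb_agrees_with_icer_case_analysis():
    """Independent oracle: classify each replicate by quadrant and ICER
    position instead of via net monetary benefit."""
    rng = np.random.default_rng(7)
    dq = rng.normal(0.01, 0.02, 500)
    dc = rng.normal(100, 300, 500)
    for lam in (0.0, 10_000.0, 20_000.0, 40_000.0):
        nmb_frac = ceac_from_nmb(dq, dc, [lam])[0][1]
        ce = 0
        for q, c in zip(dq, dc):
            if q > 0:
                ce += (c <= 0) or (c / q < lam)
            elif q < 0:
                ce += (c < 0) and (c / q > lam)
            else:
                ce += c < 0
        assert nmb_frac == pytest.approx(ce / len(dq), abs=1e-12)


# --- second-order distributions ------------------------------------------

def test_moment_matched_beta_and_gamma_hit_targets():
    rng = np.random.default_rng(11)
    beta = np.array([_beta_moment_match(0.8015, 0.02, rng)
                     for _ in range(100_000)])
    assert beta.mean() == pytest.approx(0.8015, rel=0.01)
    assert beta.std() == pytest.approx(0.02, rel=0.01)
    gam = np.array([_gamma_moment_match(294.0, 0.2, rng)
                    for _ in range(100_000)])
    assert gam.mean() == pytest.approx(294.0, rel=0.01)
    assert gam.std() == pytest.approx(0.2 * 294.0, rel=0.01)


def test_second_order_draw_keeps_utility_ordering_and_means():
    params = default_params(n=100, seed=1)
    spec = PSASpec(n_patients=100, n_replicates=1, seed=1)
    rng = np.random.default_rng(3)
    tops, mods = [], []
    for _ in range(500):
        p = draw_second_order(params, spec, rng)
        us = p.econ.utilities_tuple()
        assert all(a >= b for a, b in zip(us, us[1:]))
        assert us[0] == us[1]           # OHT and mild stay tied
        tops.append(us[0])
        mods.append(us[0] - us[2])
    assert np.mean(tops) == pytest.approx(0.8015, abs=0.005)
    assert np.mean(mods) == pytest.approx(0.8015 - 0.7471, rel=0.1)


def test_medication_tariffs_not_perturbed_in_psa():
    from ohtsim.pathways import TreatmentLine
    params = default_params(n=100, seed=1)
    spec = PSASpec(n_patients=100, n_replicates=1, seed=1)
    p = draw_second_order(params, spec, np.random.default_rng(5))
    assert p.pathways.lines[TreatmentLine.PGA].annual_cost == 149.76
    assert p.pathways.lines[TreatmentLine.PGA_BB].annual_cost == 171.84
    assert p.pathways.lines[TreatmentLine.TRAB].oneoff_cost != 1694.0


# --- one-way SA -----------------------------------------------------------

def test_identity_scenario_reproduces_baseline_exactly(small_params):
    scen = [Scenario("baseline", "rp_threshold", 0.06),
            Scenario("same", "rp_threshold", 0.06)]
    rows = one_way_sa(small_params, scen, n=300, master_seed=9)
    assert rows[0]["icer"] == rows[1]["icer"]
    assert rows[0]["delta_qaly"] == rows[1]["delta_qaly"]


def test_scenario_paths_reach_nested_parameters(small_params):
    rows = one_way_sa(
        small_params,
        [Scenario("pga_cost", "pathways.lines.PGA.annual_cost", 149.76 * 1.5),
         Scenario("prim", "pathways.schedule.cost_primary_iop_vf", 30.0),
         Scenario("adh", "pathways.adherence", 0.75)],
        n=300, master_seed=9)
    assert len(rows) == 3
    assert all(math.isfinite(r["delta_cost"]) for r in rows)


def test_malformed_scenarios_rejected(small_params):
    with pytest.raises(ConfigurationError):
        one_way_sa(small_params, [("not", "a", "scenario")], n=50)
    with pytest.raises(ConfigurationError, match="unknown"):
        one_way_sa(small_params,
                   [Scenario("bad", "pathways.no_such_field", 1.0)], n=50)


# --- PSA ------------------------------------------------------------------

def test_small_psa_runs_and_is_reproducible():
    params = default_params(n=200, seed=2)
    spec = PSASpec(n_patients=200, n_replicates=4, seed=2)
    a = run_psa(spec, params)
    b = run_psa(PSASpec(n_patients=200, n_replicates=4, seed=2), params)
    assert np.array_equal(a.scatter, b.scatter)
    assert a.scatter.shape == (4, 2)
    assert all(0.0 <= p <= 1.0 for _, p in a.ceac)


def test_psa_spec_validation():
    with pytest.raises(ConfigurationError):
        run_psa(PSASpec(n_replicates=0), default_params(n=10, seed=1))


def test_econ_params_validation():
    with pytest.raises(ConfigurationError, match="utilit"):
        EconParams(utility_vi=1.2)
    with pytest.raises(ConfigurationError, match="non-increasing"):
        EconParams(utility_severe=0.9)
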