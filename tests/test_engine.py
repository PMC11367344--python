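"""DES engine: competing events, accrual, discounting, reproducibility."""

import dataclasses
import math
import random

import numpy as np
import pytest

from ohtsim import (ConfigurationError, GlaucomaStage, RiskCoefficients,
                    SimulationError, run_strategy, simulate_patient)
from ohtsim.config import default_params
from ohtsim.natural_history import NaturalHistoryParams
from .test_risk import make_profile

RHO = math.log(1.035)


def no_conversion_params(discount=0.0):
    """Conversion practically impossible; nobody treated."""
    p = default_params(n=10, seed=1)
    coef = RiskCoefficients(baseline_risk_5yr=1e-12)
    p.nh = NaturalHistoryParams(hazard_coef=coef)
    p.risk = coef
    p.rp_threshold = 1.0
    p.econ = dataclasses.replace(p.econ, discount_rate=discount)
    return p


def test_zero_hazard_undiscounted_qalys_closed_form():
    """With no conversion, no treatment and no discounting, lifetime QALYs
    are exactly utility x remaining life."""
    p = no_conversion_params(discount=0.0)
    prof = make_profile(age=62.0, death_age=85.25)
    rec = simulate_patient(prof, "rp", p, random.Random(4))
    assert rec.qaly == pytest.approx(0.8015 * 23.25, abs=1e-9)
    assert not rec.converted
    assert rec.final_stage == GlaucomaStage.OHT


def test_zero_hazard_discounted_qalys_closed_form_and_quadrature():
    p = no_conversion_params(discount=0.035)
    T = 23.25
    prof = make_profile(age=62.0, death_age=62.0 + T)
    rec = simulate_patient(prof, "rp", p, random.Random(4))
    closed = 0.8015 * (1.0 - 1.035 ** (-T)) / RHO
    assert rec.qaly == pytest.approx(closed, abs=1e-9)
    from scipy.integrate import quad
    numeric, _ = quad(lambda t: 0.8015 * math.exp(-RHO * t), 0, T)
    assert rec.qaly == pytest.approx(numeric, abs=1e-7)


def test_early_death_yields_single_event_beyond_allocation():
    p = no_conversion_params()
    prof = make_profile(age=62.0, death_age=62.2)
    rec = simulate_patient(prof, "rp", p, random.Random(1), trace=True)
    assert [e[1] for e in rec.log] == ["ALLOCATION", "DEATH"]


def test_untreated_annual_checkup_costs():
    """An untreated never-converting patient pays one primary sight test per
    year, discounted at the event time."""
    p = no_conversion_params(discount=0.035)
    prof = make_profile(age=62.0, death_age=65.5)   # check-ups at 1, 2, 3
    rec = simulate_patient(prof, "rp", p, random.Random(2))
    expected = sum(23.14 * math.exp(-RHO * t) for t in (1.0, 2.0, 3.0))
    assert rec.cost == pytest.approx(expected, abs=1e-9)
    assert rec.cost < rec.cost_undiscounted


def test_run_strategy_single_patient_equals_record(small_params):
    from ohtsim import sample_cohort
    cohort = sample_cohort(dataclasses.replace(small_params.cohort, n=1))
    res = run_strategy(cohort, "sc", small_params, master_seed=5)
    from ohtsim.engine import patient_seed
    rec = simulate_patient(cohort[0], "sc", small_params,
                           random.Random(patient_seed(5, cohort[0].id)))
    assert res.mean_cost == pytest.approx(rec.cost)
    assert res.mean_qaly == pytest.approx(rec.qaly)
    assert res.n == 1


def test_empty_cohort_rejected(small_params):
    with pytest.raises(ConfigurationError):
        run_strategy([], "sc", small_params)


def test_bitwise_reproducibility_and_seed_sensitivity(small_params,
                                                      small_cohort):
    a = run_strategy(small_cohort, "rp", small_params, master_seed=3)
    b = run_strategy(small_cohort, "rp", small_params, master_seed=3)
    assert np.array_equal(a.costs, b.costs)
    assert np.array_equal(a.qalys, b.qalys)
    c = run_strategy(small_cohort, "rp", small_params, master_seed=4)
    assert not np.array_equal(a.costs, c.costs)


def test_end_state_conservation_and_conversion_consistency(small_params,
                                                           small_cohort):
    res = run_strategy(small_cohort, "sc", small_params, master_seed=1)
    assert sum(res.end_state_dist) == pytest.approx(1.0, abs=1e-9)
    # a patient ends in a glaucoma state iff they converted
    assert sum(res.end_state_dist[1:]) == pytest.approx(res.frac_converted)


def test_zero_discount_qalys_match_trapezoid_oracle_on_log(small_params,
                                                           small_cohort):
    """With discounting off, engine QALYs equal a utility-weighted life-year
    integral reconstructed independently from the event log."""
    p = dataclasses.replace(small_params)
    p.econ = dataclasses.replace(p.econ, discount_rate=0.0)
    utilities = p.econ.utilities_tuple()
    for prof in small_cohort[:40]:
        from ohtsim.engine import patient_seed
        rec = simulate_patient(prof, "sc", p,
                               random.Random(patient_seed(1, prof.id)),
                               trace=True)
        total = 0.0
        for prev, cur in zip(rec.log, rec.log[1:]):
            total += utilities[prev[7]] * (cur[0] - prev[0])
        assert rec.qaly == pytest.approx(total, abs=1e-9)


def test_discounting_strictly_decreases_totals(small_params, small_cohort):
    prof = small_cohort[0]
    from ohtsim.engine import patient_seed
    recs = []
    for d in (0.0, 0.035, 0.07):
        p = dataclasses.replace(small_params)
        p.econ = dataclasses.replace(p.econ, discount_rate=d)
        recs.append(simulate_patient(prof, "sc", p,
                                     random.Random(patient_seed(1, prof.id))))
    assert recs[0].qaly > recs[1].qaly > recs[2].qaly
    assert recs[0].cost > recs[1].cost > recs[2].cost


def test_stage_monotone_and_vi_absorbing(small_params, small_cohort):
    from ohtsim.engine import patient_seed
    saw_vi = 0
    for prof in small_cohort[:150]:
        rec = simulate_patient(prof, "sc", small_params,
                               random.Random(patient_seed(1, prof.id)),
                               trace=True)
        stages = [e[7] for e in rec.log]
        assert all(a <= b for a, b in zip(stages, stages[1:]))
        if stages[-1] == int(GlaucomaStage.VISUAL_IMPAIRMENT):
            saw_vi += 1
            i = stages.index(int(GlaucomaStage.VISUAL_IMPAIRMENT))
            assert all(s == stages[i] for s in stages[i:])
    # lifetime escalations bounded by the length of the treatment sequence
    for prof in small_cohort[:150]:
        rec = simulate_patient(prof, "rp", small_params,
                               random.Random(patient_seed(1, prof.id)),
                               trace=True)
        lines = [e[3] for e in rec.log]
        changes = sum(a != b for a, b in zip(lines, lines[1:]))
        assert changes <= 4
        assert all(a <= b for a, b in zip(lines, lines[1:]))


def test_treat_all_dominates_treat_none_on_matched_seeds(small_params,
                                                         small_cohort):
    p_all = dataclasses.replace(small_params, rp_threshold=0.0)
    p_none = dataclasses.replace(small_params, rp_threshold=1.0)
    res_all = run_strategy(small_cohort, "rp", p_all, master_seed=2)
    res_none = run_strategy(small_cohort, "rp", p_none, master_seed=2)
    assert res_all.frac_treated == 1.0
    assert res_none.frac_treated == 0.0
    assert res_all.mean_qaly >= res_none.mean_qaly
    assert res_all.frac_converted < res_none.frac_converted


def test_adherence_drop_weakly_raises_iops_and_lowers_qalys(small_params,
                                                            small_cohort):
    from ohtsim.engine import patient_seed
    p_hi = dataclasses.replace(small_params)
    p_lo = dataclasses.replace(small_params)
    p_lo.pathways = dataclasses.replace(p_lo.pathways, adherence=0.75)
    hi = run_strategy(small_cohort, "rp", p_hi, master_seed=6)
    lo = run_strategy(small_cohort, "rp", p_lo, master_seed=6)
    assert lo.mean_qaly <= hi.mean_qaly
    for prof in small_cohort[:60]:
        rec_hi = simulate_patient(prof, "rp", p_hi,
                                  random.Random(patient_seed(6, prof.id)),
                                  trace=True)
        rec_lo = simulate_patient(prof, "rp", p_lo,
                                  random.Random(patient_seed(6, prof.id)),
                                  trace=True)
        # IOP right after allocation: lower adherence, weaker reduction
        assert rec_lo.log[0][6] >= rec_hi.log[0][6] - 1e-12


def test_runaway_event_loop_guard():
    p = no_conversion_params()
    p.pathways.schedule = dataclasses.replace(p.pathways.schedule,
                                              primary_interval=1e-4)
    prof = make_profile(age=62.0, death_age=85.0)
    with pytest.raises(SimulationError, match="events"):
        simulate_patient(prof, "rp", p, random.Random(1))
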