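"""Discrete event simulation core.

Each patient repeatedly faces three competing events — the next scheduled
check-up, the next natural-history event (conversion or stage progression),
and death — and the earliest clock fires.  Utilities accrue continuously at
the *true* disease stage between events and costs are charged at event times;
both are discounted continuously at rho = ln(1 + annual rate).  Death ages
are pre-sampled at cohort creation, and each patient owns a seeded random
substream derived from the master seed and patient id, so the same cohort can
be pushed through both strategies under common random numbers.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort import ConfigurationError, PatientProfile
from .natural_history import (GlaucomaStage, conversion_hazard,
                              md_decline_rate, next_stage_threshold,
                              sample_frailty, stage_from_md,
                              time_to_conversion, time_to_next_stage)
from .pathways import CareSetting, TreatmentLine, initial_allocation, \
    process_checkup

#: hard cap on events per patient; tripping it indicates an engine bug
MAX_EVENTS_PER_PATIENT = 10_000


class SimulationError(RuntimeError):
    pass


@dataclass
class PatientRecord:
    """Lifetime outcome of one simulated patient."""

    id: int
    cost: float              # discounted GBP
    qaly: float              # discounted QALYs
    cost_undiscounted: float
    qaly_undiscounted: float
    final_stage: GlaucomaStage
    converted: bool
    conversion_time: Optional[float]   # years from entry; None if never
    treated_initially: bool
    n_events: int
    log: Optional[list] = None   # (t, event, setting, line, cost, md, iop, stage)


@dataclass
class StrategyResult:
    """Cohort-level aggregate for one monitoring strategy."""

    strategy: str
    n: int
    mean_cost: float
    mean_qaly: float
    frac_treated: float
    frac_converted: float
    end_state_dist: tuple      # over the five stages, sums to 1
    costs: np.ndarray = field(repr=False)
    qalys: np.ndarray = field(repr=False)
    mean_cost_undiscounted: float = 0.0
    mean_qaly_undiscounted: float = 0.0


def patient_seed(master_seed: int, patient_id: int) -> int:
    """Deterministic per-patient substream seed (avalanched by the MT init)."""
    return (master_seed * 1_000_003 + patient_id * 7_919 + 17) % (2 ** 63)


def simulate_patient(profile: PatientProfile, strategy: str, params,
                     rng: random.Random, trace: bool = False) -> PatientRecord:
    """Run one patient from model entry to death under ``strategy``."""
    econ = params.econ
    nh = params.nh
    pw = params.pathways
    rho = math.log1p(econ.discount_rate)
    utilities = econ.utilities_tuple()
    annual_costs = tuple(pw.lines[TreatmentLine(i)].annual_cost
                         for i in range(5))
    thresholds = nh.stage_thresholds

    # patient-level frailty first, so all later draws stay aligned across
    # strategies under common random numbers
    frailty = sample_frailty(nh, rng)
    state, cost0 = initial_allocation(profile, strategy, params, rng)
    cost = cost0
    ucost = cost0
    qaly = 0.0
    uqaly = 0.0
    log = [(0.0, "ALLOCATION", int(state.setting), int(state.line), cost0,
            state.md, state.iop, int(state.stage))] if trace else None

    t = 0.0
    death_t = profile.death_age - profile.age
    if death_t <= 0:
        raise SimulationError(f"patient {profile.id}: death_age <= age")

    # natural-history clock and current MD slope
    rate = 0.0
    h = frailty * conversion_hazard(profile, state.iop, nh)
    t_nh = time_to_conversion(h, rng)
    converted = False
    conversion_time = None

    exp = math.exp
    n_events = 0
    while True:
        n_events += 1
        if n_events > MAX_EVENTS_PER_PATIENT:
            raise SimulationError(
                f"patient {profile.id}: exceeded {MAX_EVENTS_PER_PATIENT} events")
        t_next = min(death_t, t_nh, state.next_checkup)

        # continuous accrual over (t, t_next] at the *true* stage
        dt = t_next - t
        if rho > 0.0:
            w = (exp(-rho * t) - exp(-rho * t_next)) / rho
        else:
            w = dt
        u = utilities[state.stage]
        qaly += u * w
        uqaly += u * dt
        mc = annual_costs[state.line]
        if mc:
            cost += mc * w
            ucost += mc * dt
        if converted and rate < 0.0:
            state.md += rate * dt
        t = t_next

        if death_t <= t_nh and death_t <= state.next_checkup:
            if trace:
                log.append((t, "DEATH", int(state.setting), int(state.line),
                            0.0, state.md, state.iop, int(state.stage)))
            break

        if t_nh <= state.next_checkup:
            # natural-history event: conversion or stage progression
            if not converted:
                converted = True
                conversion_time = t
                state.md = state.md_at_conversion
                state.stage = stage_from_md(state.md, thresholds)
                rate = md_decline_rate(state.iop, nh)
            else:
                state.stage = GlaucomaStage(int(state.stage) + 1)
                # land exactly on the cutpoint to avoid float drift
                state.md = {
                    GlaucomaStage.MODERATE: thresholds[0],
                    GlaucomaStage.SEVERE: thresholds[1],
                    GlaucomaStage.VISUAL_IMPAIRMENT: thresholds[2],
                }[state.stage]
            if state.stage == GlaucomaStage.VISUAL_IMPAIRMENT or rate == 0.0:
                t_nh = math.inf
            else:
                t_nh = t + time_to_next_stage(state.md, rate, thresholds)
            if trace:
                log.append((t, "NATURAL_HISTORY", int(state.setting),
                            int(state.line), 0.0, state.md, state.iop,
                            int(state.stage)))
        else:
            # check-up
            iop_before = state.iop
            c = process_checkup(state, t, pw)
            if c:
                cost += c * (exp(-rho * t) if rho > 0.0 else 1.0)
                ucost += c
            if not converted:
                # resample the (memoryless) conversion clock at the hazard
                # implied by the current IOP and attained age
                h = frailty * conversion_hazard(profile, state.iop, nh, t)
                t_nh = time_to_conversion(h, rng)
                t_nh = t + t_nh if t_nh < math.inf else math.inf
            elif state.iop != iop_before:
                rate = md_decline_rate(state.iop, nh)
                if (state.stage == GlaucomaStage.VISUAL_IMPAIRMENT
                        or rate == 0.0):
                    t_nh = math.inf
                else:
                    t_nh = t + time_to_next_stage(state.md, rate, thresholds)
            if trace:
                log.append((t, "CHECKUP", int(state.setting), int(state.line),
                            c, state.md, state.iop, int(state.stage)))

    return PatientRecord(
        id=profile.id, cost=cost, qaly=qaly, cost_undiscounted=ucost,
        qaly_undiscounted=uqaly, final_stage=GlaucomaStage(int(state.stage)),
        converted=converted, conversion_time=conversion_time,
        treated_initially=state.treated_initially,
        n_events=n_events, log=log)


def run_strategy(cohort: Sequence[PatientProfile], strategy: str, params,
                 master_seed: int = 0) -> StrategyResult:
    """Simulate every patient in ``cohort`` under ``strategy``.

    Per-patient substreams are derived from (master seed, patient id), so
    running the SC and RP strategies with the same cohort and master seed is
    a matched (common-random-numbers) comparison.
    """
    if len(cohort) == 0:
        raise ConfigurationError("cohort must be non-empty")
    n = len(cohort)
    costs = np.empty(n)
    qalys = np.empty(n)
    treated = 0
    convert = 0
    ucost = 0.0
    uqaly = 0.0
    states = np.zeros(5, dtype=np.int64)
    for i, p in enumerate(cohort):
        rng = random.Random(patient_seed(master_seed, p.id))
        rec = simulate_patient(p, strategy, params, rng)
        costs[i] = rec.cost
        qalys[i] = rec.qaly
        treated += rec.treated_initially
        convert += rec.converted
        ucost += rec.cost_undiscounted
        uqaly += rec.qaly_undiscounted
        states[int(rec.final_stage)] += 1
    return StrategyResult(
        strategy=strategy, n=n,
        mean_cost=float(costs.mean()), mean_qaly=float(qalys.mean()),
        frac_treated=treated / n, frac_converted=convert / n,
        end_state_dist=tuple(states / n),
        costs=costs, qalys=qalys,
        mean_cost_undiscounted=ucost / n, mean_qaly_undiscounted=uqaly / n)
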