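"""Care pathways: treatment sequence, IOP targets, monitoring, referral.

Treatment escalates through a fixed sequence — prostaglandin analogue (PGA)
drops, PGA plus beta-blocker combination drops, selective laser
trabeculoplasty (SLT), trabeculectomy — with trabeculectomy terminal.  Each
line lowers the current IOP by a proportional reduction drawn once per
patient and line; medication effects scale with adherence, procedures do not.
A patient is "on target" when current IOP is at least 20% below the IOP at
model entry.  Monitoring alternates between primary care (cheap annual sight
tests) and secondary care (hospital reviews): untreated or stable patients
sit in primary care, off-target or newly converted patients are referred to
secondary care, and confirmed glaucoma is managed in secondary care for life.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum

from .cohort import ConfigurationError, PatientProfile
from .natural_history import GlaucomaStage
from . import risk as _risk


class TreatmentLine(IntEnum):
    NONE = 0
    PGA = 1
    PGA_BB = 2
    SLT = 3
    TRAB = 4


class CareSetting(IntEnum):
    PRIMARY = 0
    SECONDARY = 1


@dataclass(frozen=True)
class LineParams:
    """Effect and cost of one treatment line.

    ``effect_mean``/``effect_sd`` parameterise the proportional IOP reduction
    (drawn once per patient-line, clipped to [0, 0.9]).  Medication lines
    carry an annual cost accrued while active; procedures a one-off cost at
    escalation.  The combination line's effect is *additional* on top of the
    already PGA-reduced IOP, and its annual cost is the combination product's
    price (it replaces, not adds to, the PGA price).
    """

    effect_mean: float
    effect_sd: float
    annual_cost: float = 0.0
    oneoff_cost: float = 0.0
    uses_adherence: bool = True


def default_lines() -> dict[TreatmentLine, LineParams]:
    return {
        TreatmentLine.NONE: LineParams(0.0, 0.0, 0.0, 0.0, False),
        TreatmentLine.PGA: LineParams(0.29, 0.08, annual_cost=149.76),
        TreatmentLine.PGA_BB: LineParams(0.14, 0.08, annual_cost=171.84),
        TreatmentLine.SLT: LineParams(0.312, 0.08, oneoff_cost=151.0,
                                      uses_adherence=False),
        TreatmentLine.TRAB: LineParams(0.447, 0.189, oneoff_cost=1694.0,
                                       uses_adherence=False),
    }


@dataclass(frozen=True)
class MonitoringSchedule:
    """Visit intervals (years) and unit costs (GBP) per setting and state."""

    primary_interval: float = 1.0        # annual sight test, OHT in primary
    secondary_oht_interval: float = 0.5  # hospital OHT review
    glaucoma_interval: float = 1.0 / 3.0  # 4-monthly review, confirmed glaucoma
    cost_primary_iop: float = 11.57
    cost_primary_iop_vf: float = 23.14
    cost_secondary_iop: float = 147.0
    cost_secondary_iop_vf: float = 294.0

    def __post_init__(self):
        for f in ("primary_interval", "secondary_oht_interval",
                  "glaucoma_interval"):
            if getattr(self, f) <= 0:
                raise ConfigurationError(f"{f} must be > 0")
        for f in ("cost_primary_iop", "cost_primary_iop_vf",
                  "cost_secondary_iop", "cost_secondary_iop_vf"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"{f} must be >= 0")


@dataclass
class PathwayParams:
    lines: dict = field(default_factory=default_lines)
    schedule: MonitoringSchedule = field(default_factory=MonitoringSchedule)
    adherence: float = 1.0        # multiplies medication effects only
    pga_fraction: float = 0.8     # initial treated split PGA vs SLT
    on_target_reduction: float = 0.20

    def validate(self) -> None:
        if not 0.0 <= self.adherence <= 1.0:
            raise ConfigurationError(
                f"adherence must be in [0,1], got {self.adherence}")
        if not 0.0 <= self.pga_fraction <= 1.0:
            raise ConfigurationError(
                f"pga_fraction must be in [0,1], got {self.pga_fraction}")


class PatientState:
    """Mutable trajectory state for one simulated patient."""

    __slots__ = ("stage", "obs_stage", "md", "iop", "baseline_iop", "setting",
                 "line", "treated_initially", "sec_toggle", "next_checkup",
                 "escalations", "effects", "md_at_conversion")

    def __init__(self, baseline_iop: float, effects: tuple,
                 md_at_conversion: float):
        self.stage = GlaucomaStage.OHT
        self.obs_stage = GlaucomaStage.OHT
        self.md = math.nan
        self.iop = baseline_iop
        self.baseline_iop = baseline_iop
        self.setting = CareSetting.PRIMARY
        self.line = TreatmentLine.NONE
        self.treated_initially = False
        self.sec_toggle = False          # alternates hospital OHT bundles
        self.next_checkup = math.inf
        self.escalations = 0
        self.effects = effects           # pre-drawn reductions, lines 1..4
        self.md_at_conversion = md_at_conversion


def on_target(baseline_iop: float, current_iop: float,
              reduction: float = 0.20) -> bool:
    """True iff current IOP is reduced by >= ``reduction`` from baseline."""
    if baseline_iop <= 0 or current_iop <= 0:
        raise ConfigurationError("IOP values must be > 0")
    return current_iop <= (1.0 - reduction) * baseline_iop


def escalate(line: TreatmentLine) -> TreatmentLine:
    """Next line of the sequence; trabeculectomy is terminal."""
    if line == TreatmentLine.TRAB:
        return TreatmentLine.TRAB
    return TreatmentLine(int(line) + 1)


def draw_line_effect(line: TreatmentLine, params: PathwayParams, rng) -> float:
    """Proportional IOP reduction for a line, clipped into [0, 0.9]."""
    lp = params.lines[line]
    r = lp.effect_mean + lp.effect_sd * rng.gauss(0.0, 1.0)
    return min(max(r, 0.0), 0.9)


def apply_line_effect(current_iop: float, line: TreatmentLine, r: float,
                      adherence: float, params: PathwayParams) -> float:
    """New IOP after applying a line's (pre-drawn) reduction ``r``."""
    if params.lines[line].uses_adherence:
        r = adherence * r
    return current_iop * (1.0 - r)


def apply_treatment_effect(current_iop: float, line: TreatmentLine,
                           adherence: float, rng,
                           params: PathwayParams | None = None) -> float:
    """Draw a reduction for ``line`` and apply it to ``current_iop``."""
    if params is None:
        params = PathwayParams()
    if current_iop <= 0:
        raise ConfigurationError("current_iop must be > 0")
    if not 0.0 <= adherence <= 1.0:
        raise ConfigurationError("adherence must be in [0,1]")
    r = draw_line_effect(line, params, rng)
    return apply_line_effect(current_iop, line, r, adherence, params)


def _escalate_state(state: PatientState, params: PathwayParams) -> float:
    """Escalate once (if possible); returns the one-off cost incurred."""
    new_line = escalate(state.line)
    if new_line == state.line:
        return 0.0
    state.line = new_line
    state.escalations += 1
    r = state.effects[int(new_line) - 1]
    state.iop = apply_line_effect(state.iop, new_line, r, params.adherence,
                                  params)
    return params.lines[new_line].oneoff_cost


def initial_allocation(profile: PatientProfile, strategy: str, model_params,
                       rng) -> tuple[PatientState, float]:
    """Entry decision in secondary care; returns (state, cost at t=0).

    Treated patients start on PGA (with probability ``pga_fraction``) or SLT,
    have the effect applied immediately, and are placed per the on-target
    rule: on-target back to primary care, off-target retained in secondary
    care.  Untreated patients go to annual primary-care check-ups.  The
    entry assessment for treated patients is costed as one secondary-care
    full (IOP + visual field) visit.
    """
    pw: PathwayParams = model_params.pathways
    sched = pw.schedule
    # Pre-draw all stochastic patient-level quantities up front so that the
    # two strategies consume identical draws (common random numbers).
    u_alloc = rng.random()
    score_z = rng.gauss(0.0, 1.0)      # tool's scoring noise (RP arm only)
    effects = tuple(draw_line_effect(TreatmentLine(i), pw, rng)
                    for i in range(1, 5))
    from .cohort import sample_md_at_conversion
    md_conv = sample_md_at_conversion(
        model_params.cohort.md_at_conversion_mean,
        model_params.cohort.md_at_conversion_sd, rng)

    state = PatientState(profile.iop_baseline, effects, md_conv)

    if strategy == "rp":
        r5 = _risk.five_year_risk(profile, model_params.risk, score_z)
        treat = _risk.treat_decision_rp(r5, model_params.rp_threshold)
    elif strategy == "sc":
        treat = _risk.treat_decision_sc(profile, model_params.sc_table)
    else:
        raise ConfigurationError(f"unknown strategy {strategy!r}")

    cost = 0.0
    if treat:
        state.treated_initially = True
        cost += sched.cost_secondary_iop_vf
        line = (TreatmentLine.PGA if u_alloc < pw.pga_fraction
                else TreatmentLine.SLT)
        state.line = line
        state.escalations += 1
        r = state.effects[int(line) - 1]
        state.iop = apply_line_effect(state.iop, line, r, pw.adherence, pw)
        cost += pw.lines[line].oneoff_cost
        if on_target(state.baseline_iop, state.iop, pw.on_target_reduction):
            state.setting = CareSetting.PRIMARY
            state.next_checkup = sched.primary_interval
        else:
            state.setting = CareSetting.SECONDARY
            state.next_checkup = sched.secondary_oht_interval
    else:
        state.setting = CareSetting.PRIMARY
        state.next_checkup = sched.primary_interval
    return state, cost


def process_checkup(state: PatientState, t: float, params: PathwayParams
                    ) -> float:
    """One monitoring visit: charge it, observe, refer/escalate, reschedule.

    Returns the undiscounted cost incurred at the visit (test bundle plus any
    procedure charged on escalation).  At most one escalation happens per
    visit.  Confirmed glaucoma never returns to primary care.
    """
    sched = params.schedule
    cost = 0.0
    tgt = params.on_target_reduction
    if state.setting == CareSetting.PRIMARY:
        cost += sched.cost_primary_iop_vf
        if state.stage > state.obs_stage:
            # Conversion (or worse) newly observed: referral plus immediate
            # hospital assessment, then a first management review.
            state.obs_stage = state.stage
            state.setting = CareSetting.SECONDARY
            cost += sched.cost_secondary_iop_vf
            if not on_target(state.baseline_iop, state.iop, tgt):
                cost += _escalate_state(state, params)
        elif (state.line != TreatmentLine.NONE
              and not on_target(state.baseline_iop, state.iop, tgt)):
            state.setting = CareSetting.SECONDARY
            cost += _escalate_state(state, params)
    else:  # SECONDARY
        if state.obs_stage == GlaucomaStage.OHT:
            # Hospital OHT review, alternating cheap/full test bundles.
            cost += (sched.cost_secondary_iop if state.sec_toggle
                     else sched.cost_secondary_iop_vf)
            state.sec_toggle = not state.sec_toggle
            if state.stage > state.obs_stage:
                state.obs_stage = state.stage
                if not on_target(state.baseline_iop, state.iop, tgt):
                    cost += _escalate_state(state, params)
            elif state.line != TreatmentLine.NONE:
                if on_target(state.baseline_iop, state.iop, tgt):
                    state.setting = CareSetting.PRIMARY
                else:
                    cost += _escalate_state(state, params)
        else:
            # Confirmed glaucoma: full assessment every visit, for life.
            cost += sched.cost_secondary_iop_vf
            state.obs_stage = state.stage
            if not on_target(state.baseline_iop, state.iop, tgt):
                cost += _escalate_state(state, params)

    if state.setting == CareSetting.PRIMARY:
        state.next_checkup = t + sched.primary_interval
    elif state.obs_stage == GlaucomaStage.OHT:
        state.next_checkup = t + sched.secondary_oht_interval
    else:
        state.next_checkup = t + sched.glaucoma_interval
    return cost
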