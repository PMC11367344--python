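"""Natural history: conversion hazard, visual-field decline, and staging.

Conversion from ocular hypertension to open-angle glaucoma is modelled as a
proportional-hazards event whose rate is multiplicative in the patient's
current IOP and baseline risk factors; between events the hazard is constant,
so times-to-conversion are exponential and can be memorylessly resampled
whenever treatment changes the IOP.  After conversion, disease severity is
tracked through the visual-field mean deviation (MD, dB; more negative is
worse), which declines linearly in time at a rate that increases with IOP.
MD maps onto the conventional four-stage classification (mild > -6 dB,
moderate (-12, -6], severe (-20, -12], visual impairment <= -20 dB); visual
impairment is absorbing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

from .cohort import ConfigurationError, PatientProfile
from .risk import RiskCoefficients


class GlaucomaStage(IntEnum):
    OHT = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3
    VISUAL_IMPAIRMENT = 4


#: MD cutpoints (dB) between MILD/MODERATE, MODERATE/SEVERE, SEVERE/VI.
DEFAULT_STAGE_THRESHOLDS = (-6.0, -12.0, -20.0)


@dataclass(frozen=True)
class NaturalHistoryParams:
    """All natural-history constants.

    ``hazard_coef`` carries the covariate structure of the conversion hazard
    (shared shape with the risk tool); the annual baseline hazard at the
    reference profile is ``h0 = -ln(1 - baseline_risk_5yr) / 5``.  MD decline
    is ``-(a + b * (IOP - ref))`` dB/year, clamped so MD never improves.
    """

    hazard_coef: RiskCoefficients = field(default_factory=RiskCoefficients)
    frailty_sd: float = 0.0              # log-scale sd of unobserved frailty
    md_decline_intercept: float = 0.65   # a: dB/year at the reference IOP
    md_decline_slope: float = 0.03       # b: dB/year per mmHg above reference
    md_decline_ref_iop: float = 26.51    # mmHg
    stage_thresholds: Sequence[float] = DEFAULT_STAGE_THRESHOLDS

    def __post_init__(self):
        t = tuple(self.stage_thresholds)
        if len(t) != 3 or not (t[0] > t[1] > t[2]):
            raise ConfigurationError(
                f"stage thresholds must be 3 decreasing cutpoints, got {t}")
        object.__setattr__(self, "stage_thresholds", t)

    @property
    def h0(self) -> float:
        """Annual conversion hazard at the reference covariate profile."""
        return -math.log(1.0 - self.hazard_coef.baseline_risk_5yr) / 5.0


def sample_frailty(params: NaturalHistoryParams, rng) -> float:
    """Patient-level multiplicative frailty on the conversion hazard.

    Lognormal with unit mean (log-sd ``frailty_sd``), drawn once per patient.
    Frailty is *unobservable to the risk tool*: it is how the model
    represents the limited discrimination of real risk predictors — two
    patients with identical measured risk factors can differ in their true
    hazard.  ``frailty_sd = 0`` recovers a perfectly informative tool.
    """
    s = params.frailty_sd
    if s < 0:
        raise ConfigurationError(f"frailty_sd must be >= 0, got {s}")
    if s == 0:
        return 1.0
    return math.exp(s * rng.gauss(0.0, 1.0) - 0.5 * s * s)


def conversion_hazard(profile: PatientProfile, current_iop: float,
                      params: NaturalHistoryParams,
                      years_from_entry: float = 0.0) -> float:
    """Annual hazard of conversion at the patient's *current* IOP and age.

    Age is advanced continuously (baseline age + model time), so with a
    positive age coefficient the hazard rises over a patient's lifetime; the
    engine holds it piecewise-constant between events and resamples the
    conversion clock at every event, which is exact for a piecewise-constant
    hazard.
    """
    if current_iop <= 0:
        raise ConfigurationError(f"current_iop must be > 0, got {current_iop}")
    coef = params.hazard_coef
    lp = coef.profile_lp(profile, iop=current_iop)
    lp += coef.beta_age_per_decade * years_from_entry / 10.0
    return params.h0 * math.exp(lp)


def time_to_conversion(hazard: float, rng) -> float:
    """Exponential time-to-event; hazard 0 means 'never' (+inf).

    Memorylessness makes resampling after each event equivalent to
    conditioning on survival so far, which is what licenses the
    recalculate-on-every-event scheme of the simulation engine.
    """
    if hazard < 0:
        raise ConfigurationError(f"hazard must be >= 0, got {hazard}")
    if hazard == 0:
        return math.inf
    return rng.expovariate(hazard)


def md_decline_rate(current_iop: float, params: NaturalHistoryParams) -> float:
    """MD slope in dB/year, always <= 0 (the field never improves)."""
    raw = (params.md_decline_intercept
           + params.md_decline_slope * (current_iop - params.md_decline_ref_iop))
    return -max(0.0, raw)


def stage_from_md(md: float,
                  thresholds: Sequence[float] = DEFAULT_STAGE_THRESHOLDS
                  ) -> GlaucomaStage:
    """Stage of a *converted* eye; boundaries belong to the worse stage."""
    t_mild, t_mod, t_sev = thresholds
    if md > t_mild:
        return GlaucomaStage.MILD
    if md > t_mod:
        return GlaucomaStage.MODERATE
    if md > t_sev:
        return GlaucomaStage.SEVERE
    return GlaucomaStage.VISUAL_IMPAIRMENT


def next_stage_threshold(stage: GlaucomaStage,
                         thresholds: Sequence[float] = DEFAULT_STAGE_THRESHOLDS
                         ) -> float:
    """MD value at which the next (worse) stage begins; -inf at the end."""
    if stage == GlaucomaStage.MILD:
        return thresholds[0]
    if stage == GlaucomaStage.MODERATE:
        return thresholds[1]
    if stage == GlaucomaStage.SEVERE:
        return thresholds[2]
    return -math.inf


def time_to_next_stage(md: float, rate: float,
                       thresholds: Sequence[float] = DEFAULT_STAGE_THRESHOLDS
                       ) -> float:
    """Years until the linear MD trajectory crosses the next stage cutpoint.

    An MD sitting exactly on a boundary already belongs to the worse stage
    (consistent with :func:`stage_from_md`), so the crossing computed here is
    to the *following* cutpoint and is strictly positive for rate < 0.
    """
    if rate > 0:
        raise ConfigurationError(f"MD decline rate must be <= 0, got {rate}")
    stage = stage_from_md(md, thresholds)
    if stage == GlaucomaStage.VISUAL_IMPAIRMENT or rate == 0:
        return math.inf
    target = next_stage_threshold(stage, thresholds)
    return (md - target) / (-rate)
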