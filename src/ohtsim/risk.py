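"""Five-year glaucoma-conversion risk and the two treatment-initiation rules.

The risk-prediction (RP) rule scores each patient with a proportional-hazards
style predictor — 5-year risk = 1 - (1 - p0)^exp(LP), where p0 is the risk at
the reference covariate profile and LP a linear predictor over centred
covariates (age, IOP, CCT, PSD, vCD, plus optional binary risk factors) — and
treats everyone at or above a risk threshold (6% by default).  The standard
care (SC) rule is a clinician-style decision table over IOP, age, and CCT
bands.  Coefficients and table cells are configuration: the defaults are
calibrated so the scored risks agree with the simulation's own conversion
hazard (see natural_history), i.e. the default RP tool is perfectly
calibrated to the modelled natural history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import pandas as pd

from .cohort import ConfigurationError, PatientProfile


@dataclass(frozen=True)
class RiskCoefficients:
    """Log-hazard-ratio coefficients on conventional clinical scales.

    ``baseline_risk_5yr`` is the 5-year conversion probability at the
    reference profile.  Continuous coefficients are per decade of age, per
    mmHg of IOP, per 40 um of corneal *thinning*, per 0.2 dB of PSD and per
    0.1 of vCD, so their magnitudes are comparable across predictors.  Binary
    coefficients default to 0 (hooks retained).
    """

    baseline_risk_5yr: float = 0.15
    ref_age: float = 62.01
    ref_iop: float = 26.51
    ref_cct: float = 558.66
    ref_psd: float = 1.63
    ref_vcd: float = 0.46
    beta_age_per_decade: float = 0.0
    beta_iop_per_mmhg: float = 0.0
    beta_cct_per_40um_thinner: float = 0.0
    beta_psd_per_02db: float = 0.0
    beta_vcd_per_01: float = 0.0
    beta_hypertension: float = 0.0
    beta_family_history: float = 0.0
    beta_diabetes: float = 0.0
    beta_male: float = 0.0
    #: log-scale sd of per-patient scoring noise (measurement error in the
    #: tool's inputs); 0 = a perfectly reliable score.  Noise degrades the
    #: tool's discrimination without touching the underlying natural history.
    score_noise_sd: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.baseline_risk_5yr < 1.0:
            raise ConfigurationError(
                f"baseline_risk_5yr must be in (0,1), got {self.baseline_risk_5yr}")

    def linear_predictor(self, *, age: float, iop: float, cct: float,
                         psd: float, vcd: float, hypertension: bool = False,
                         family_history: bool = False, diabetes: bool = False,
                         male: bool = False) -> float:
        return (
            self.beta_age_per_decade * (age - self.ref_age) / 10.0
            + self.beta_iop_per_mmhg * (iop - self.ref_iop)
            + self.beta_cct_per_40um_thinner * (self.ref_cct - cct) / 40.0
            + self.beta_psd_per_02db * (psd - self.ref_psd) / 0.2
            + self.beta_vcd_per_01 * (vcd - self.ref_vcd) / 0.1
            + self.beta_hypertension * hypertension
            + self.beta_family_history * family_history
            + self.beta_diabetes * diabetes
            + self.beta_male * male
        )

    def profile_lp(self, profile: PatientProfile,
                   iop: float | None = None) -> float:
        """LP of a patient, optionally overriding IOP (e.g. post-treatment)."""
        return self.linear_predictor(
            age=profile.age,
            iop=profile.iop_baseline if iop is None else iop,
            cct=profile.cct, psd=profile.psd, vcd=profile.vcd,
            hypertension=profile.hypertension,
            family_history=profile.family_history,
            diabetes=profile.diabetes, male=profile.male)


def five_year_risk(profile: PatientProfile, coef: RiskCoefficients,
                   noise_z: float = 0.0) -> float:
    """Probability of conversion to glaucoma within 5 years, in (0, 1).

    ``noise_z`` is a standard-normal draw injecting the tool's per-patient
    scoring noise (scaled by ``coef.score_noise_sd``); the default 0 gives
    the noise-free score.
    """
    lp = coef.profile_lp(profile) + coef.score_noise_sd * noise_z
    return 1.0 - (1.0 - coef.baseline_risk_5yr) ** math.exp(lp)


def treat_decision_rp(risk: float, threshold: float) -> bool:
    """Treat iff risk >= threshold (the threshold is inclusive)."""
    if not 0.0 <= risk <= 1.0:
        raise ConfigurationError(f"risk must be in [0,1], got {risk}")
    if not 0.0 <= threshold <= 1.0 + 1e-12:
        # threshold > 1 is allowed only as the explicit 'treat nobody' limit
        if threshold > 1.0:
            return False
        raise ConfigurationError(f"threshold must be in [0,1], got {threshold}")
    return risk >= threshold


@dataclass(frozen=True)
class DecisionRule:
    """Half-open covariate box [lo, hi) -> treat flag; inf bounds allowed."""

    iop_lo: float
    iop_hi: float
    age_lo: float
    age_hi: float
    cct_lo: float
    cct_hi: float
    treat: bool

    def matches(self, iop: float, age: float, cct: float) -> bool:
        return (self.iop_lo <= iop < self.iop_hi
                and self.age_lo <= age < self.age_hi
                and self.cct_lo <= cct < self.cct_hi)


@dataclass
class SCDecisionTable:
    """Ordered treat/defer rules over (IOP, age, CCT); first match wins."""

    rules: Sequence[DecisionRule] = field(default_factory=list)

    def decide(self, iop: float, age: float, cct: float) -> bool:
        for rule in self.rules:
            if rule.matches(iop, age, cct):
                return rule.treat
        raise ConfigurationError(
            f"standard-care decision table has no rule covering "
            f"IOP={iop}, age={age}, CCT={cct}")

    @classmethod
    def from_csv(cls, path) -> "SCDecisionTable":
        df = pd.read_csv(path)
        need = ["iop_lo", "iop_hi", "age_lo", "age_hi", "cct_lo", "cct_hi",
                "treat"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise ConfigurationError(
                f"decision table {path} missing columns: {missing}")
        rules = [DecisionRule(float(r.iop_lo), float(r.iop_hi),
                              float(r.age_lo), float(r.age_hi),
                              float(r.cct_lo), float(r.cct_hi),
                              bool(int(r.treat)))
                 for r in df.itertuples(index=False)]
        return cls(rules)

    def to_csv(self, path) -> None:
        pd.DataFrame([r.__dict__ for r in self.rules]).to_csv(path, index=False)

    @classmethod
    def load_default(cls) -> "SCDecisionTable":
        """Bundled default table, calibrated to treat ~47% of the cohort."""
        with resources.as_file(
            resources.files("ohtsim.data") / "sc_decision_table.csv"
        ) as p:
            return cls.from_csv(p)


def treat_decision_sc(profile: PatientProfile, table: SCDecisionTable) -> bool:
    return table.decide(profile.iop_baseline, profile.age, profile.cct)
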