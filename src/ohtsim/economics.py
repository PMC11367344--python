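"""Health-economic layer: discounting, ICER, one-way SA, PSA and CEAC.

Strategies are compared from the payer perspective: incremental cost and
incremental QALYs over matched cohorts, the incremental cost-effectiveness
ratio (ICER) with dominance labelling, deterministic one-way sensitivity
analyses over single parameters, and a probabilistic sensitivity analysis
(PSA) that re-draws second-order parameter uncertainty per replicate and
summarises decision uncertainty as a cost-effectiveness acceptability curve
(CEAC) via net monetary benefit (NMB).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .cohort import STREAM_PSA, ConfigurationError, sample_cohort
from .engine import StrategyResult
from .natural_history import GlaucomaStage
from .pathways import TreatmentLine


@dataclass(frozen=True)
class EconParams:
    """Utilities by stage, discounting and the decision threshold.

    Stage utilities are EQ-5D style weights: ocular hypertension and mild
    glaucoma are indistinguishable to the patient (0.8015); moderate and
    severe glaucoma and visual impairment carry progressively lower weights.
    """

    utility_oht: float = 0.8015
    utility_mild: float = 0.8015
    utility_moderate: float = 0.7471
    utility_severe: float = 0.7133
    utility_vi: float = 0.535
    discount_rate: float = 0.035      # annual, applied as rho = ln(1 + rate)
    wtp_threshold: float = 20_000.0   # GBP per QALY

    def __post_init__(self):
        us = self.utilities_tuple()
        if any(not 0.0 <= u <= 1.0 for u in us):
            raise ConfigurationError(f"utilities must be in [0,1], got {us}")
        if any(us[i] < us[i + 1] for i in range(4)):
            raise ConfigurationError(
                "utilities must be non-increasing with stage severity")
        if self.discount_rate < 0:
            raise ConfigurationError("discount_rate must be >= 0")

    def utilities_tuple(self) -> tuple:
        return (self.utility_oht, self.utility_mild, self.utility_moderate,
                self.utility_severe, self.utility_vi)


def discounted_accrual(value: float, t0: float, t1: float, rho: float) -> float:
    """Integral of ``value * e^(-rho s)`` over [t0, t1]; exact event accrual."""
    if t1 < t0:
        raise ConfigurationError(f"t1 < t0 ({t1} < {t0})")
    if rho == 0.0:
        return value * (t1 - t0)
    return value * (math.exp(-rho * t0) - math.exp(-rho * t1)) / rho


@dataclass
class CEResult:
    """Incremental comparison of the RP strategy against standard care."""

    delta_cost: float
    delta_qaly: float
    icer: Optional[float]      # GBP/QALY when both increments are positive
    label: str                 # "icer", "rp_dominant", "rp_dominated", ...
    ceac: Optional[list] = None       # [(lambda, P(cost-effective)), ...]
    scatter: Optional[np.ndarray] = None   # PSA replicates, columns dQ, dC

    def nmb(self, wtp: float) -> float:
        return wtp * self.delta_qaly - self.delta_cost


def icer(sc: StrategyResult, rp: StrategyResult) -> CEResult:
    """Incremental cost, QALYs and ICER/dominance of RP versus SC."""
    dc = rp.mean_cost - sc.mean_cost
    dq = rp.mean_qaly - sc.mean_qaly
    if dq == 0.0:
        return CEResult(dc, dq, None, "undefined, compare costs")
    if dc <= 0.0 and dq > 0.0:
        return CEResult(dc, dq, None, "rp_dominant")
    if dc >= 0.0 and dq < 0.0:
        return CEResult(dc, dq, None, "rp_dominated")
    return CEResult(dc, dq, dc / dq, "icer")


# ---------------------------------------------------------------------------
# one-way sensitivity analysis


@dataclass(frozen=True)
class Scenario:
    """A single-parameter perturbation, addressed by dotted path.

    Paths traverse the model-parameter dataclasses, e.g.
    ``rp_threshold``, ``pathways.adherence``,
    ``pathways.lines.PGA.annual_cost`` or
    ``pathways.schedule.cost_primary_iop_vf``.
    """

    name: str
    param: str
    value: float


def _set_by_path(obj, path: str, value):
    parts = path.split(".")
    for key in parts[:-1]:
        if isinstance(obj, dict):
            obj = obj[_dict_key(obj, key)]
        else:
            if not hasattr(obj, key):
                raise ConfigurationError(f"unknown parameter path element {key!r}")
            obj = getattr(obj, key)
    leaf = parts[-1]
    if isinstance(obj, dict):
        obj[_dict_key(obj, leaf)] = value
    else:
        if not hasattr(obj, leaf):
            raise ConfigurationError(f"unknown parameter {leaf!r} in {path!r}")
        current = getattr(obj, leaf)
        try:
            object.__setattr__(obj, leaf, value)  # works for frozen dataclasses
        except Exception as exc:   # pragma: no cover
            raise ConfigurationError(f"cannot set {path}: {exc}")
        if isinstance(current, float) and not isinstance(value, (int, float)):
            raise ConfigurationError(f"{path}: expected a number")


def _dict_key(d: dict, key: str):
    for k in d:
        if k == key or getattr(k, "name", None) == key or str(k) == key:
            return k
    raise ConfigurationError(f"unknown key {key!r}")


def _frozen_replace_by_path(params, path: str, value):
    """Deep-copy ``params`` and set one dotted-path leaf on the copy."""
    out = copy.deepcopy(params)
    _set_by_path(out, path, value)
    return out


def one_way_sa(base_params, scenarios: Sequence[Scenario], n: int,
               master_seed: int = 0, cohort=None) -> list[dict]:
    """Run each single-parameter scenario on the same matched cohort.

    Returns one row per scenario (the unperturbed baseline should be included
    by the caller as a ``Scenario`` pointing at any parameter with its default
    value, or simply via the first scenario).  Every row re-runs both
    strategies with the same cohort and master seed, so differences between
    rows are attributable to the perturbed parameter alone.
    """
    from .engine import run_strategy
    if cohort is None:
        spec = replace(copy.deepcopy(base_params.cohort), n=n)
        cohort = sample_cohort(spec)
    rows = []
    for sc_def in scenarios:
        if not isinstance(sc_def, Scenario):
            raise ConfigurationError(
                "each scenario must be a single-parameter Scenario")
        params = _frozen_replace_by_path(base_params, sc_def.param,
                                         sc_def.value)
        res_sc = run_strategy(cohort, "sc", params, master_seed)
        res_rp = run_strategy(cohort, "rp", params, master_seed)
        ce = icer(res_sc, res_rp)
        rows.append({
            "scenario": sc_def.name,
            "param": sc_def.param,
            "value": sc_def.value,
            "cost_sc": res_sc.mean_cost, "cost_rp": res_rp.mean_cost,
            "qaly_sc": res_sc.mean_qaly, "qaly_rp": res_rp.mean_qaly,
            "delta_cost": ce.delta_cost, "delta_qaly": ce.delta_qaly,
            "icer": ce.icer if ce.icer is not None else math.nan,
            "label": ce.label,
        })
    return rows


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PSASpec:
    """Second-order uncertainty plan.

    Per replicate: treatment-effect means are drawn Normal (Table-style sd,
    truncated at 0), utilities Beta (moment-matched around the base values
    with absolute sd ``utility_sd``, re-ordered to preserve severity
    monotonicity), and unit costs Gamma (moment-matched, sd equal to
    ``cost_cv`` times the mean).  Each replicate simulates a fresh matched
    cohort of ``n_patients`` under both strategies.
    """

    n_patients: int = 10_000
    n_replicates: int = 1_000
    seed: int = 0
    utility_sd: float = 0.02
    utility_decrement_cv: float = 0.15
    cost_cv: float = 0.20
    lambda_grid: Sequence[float] = field(
        default_factory=lambda: tuple(np.arange(0.0, 50_001.0, 2_500.0)))

    def validate(self):
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not 0 <= self.utility_sd < 0.5:
            raise ConfigurationError("utility_sd out of range")
        if self.cost_cv < 0:
            raise ConfigurationError("cost_cv must be >= 0")


def _beta_moment_match(mean: float, sd: float, rng) -> float:
    """One Beta draw with the target mean/sd (sd shrunk if infeasible)."""
    if sd <= 0:
        return mean
    var = min(sd * sd, 0.95 * mean * (1 - mean))
    if var <= 0:
        return mean
    k = mean * (1 - mean) / var - 1.0
    return float(rng.beta(mean * k, (1 - mean) * k))


def _gamma_moment_match(mean: float, cv: float, rng) -> float:
    if mean <= 0 or cv <= 0:
        return mean
    shape = 1.0 / (cv * cv)
    return float(rng.gamma(shape, mean / shape))


def draw_second_order(base_params, spec: PSASpec, rng) -> object:
    """One replicate's parameter set (deep copy of the base configuration)."""
    p = copy.deepcopy(base_params)
    # treatment-effect means: truncated-normal around the base means
    for line in (TreatmentLine.PGA, TreatmentLine.PGA_BB, TreatmentLine.SLT,
                 TreatmentLine.TRAB):
        lp = p.pathways.lines[line]
        m = max(0.0, float(rng.normal(lp.effect_mean, lp.effect_sd)))
        p.pathways.lines[line] = replace(lp, effect_mean=min(m, 0.9))
    # utilities: Beta on the top (OHT = mild) utility plus gamma-distributed
    # decrements per severity step.  Drawing each state's utility separately
    # and re-sorting would inflate the mean stage gaps (order-statistic
    # bias) and with them the incremental QALYs; decrements keep every
    # stage-gap mean at its base value and severity ordering by construction.
    base_u = p.econ.utilities_tuple()
    top = _beta_moment_match(base_u[0], spec.utility_sd, rng)
    cv = spec.utility_decrement_cv
    gaps = [base_u[1] - base_u[2], base_u[2] - base_u[3], base_u[3] - base_u[4]]
    d = [_gamma_moment_match(g, cv, rng) for g in gaps]
    u_mod = max(0.0, top - d[0])
    u_sev = max(0.0, u_mod - d[1])
    u_vi = max(0.0, u_sev - d[2])
    p.econ = replace(
        p.econ, utility_oht=top, utility_mild=top,
        utility_moderate=u_mod, utility_severe=u_sev, utility_vi=u_vi)
    # unit costs: Gamma with cv
    sched = p.pathways.schedule
    p.pathways.schedule = replace(
        sched,
        cost_primary_iop=_gamma_moment_match(sched.cost_primary_iop,
                                             spec.cost_cv, rng),
        cost_primary_iop_vf=_gamma_moment_match(sched.cost_primary_iop_vf,
                                                spec.cost_cv, rng),
        cost_secondary_iop=_gamma_moment_match(sched.cost_secondary_iop,
                                               spec.cost_cv, rng),
        cost_secondary_iop_vf=_gamma_moment_match(sched.cost_secondary_iop_vf,
                                                  spec.cost_cv, rng),
    )
    # Procedure costs are estimates (trial / reference-cost based) and are
    # drawn; annual medication costs are administered BNF tariff prices —
    # set by policy, known exactly — and so carry no estimation uncertainty.
    for line in (TreatmentLine.SLT, TreatmentLine.TRAB):
        lp = p.pathways.lines[line]
        p.pathways.lines[line] = replace(
            lp,
            oneoff_cost=_gamma_moment_match(lp.oneoff_cost, spec.cost_cv, rng))
    return p


def ceac_from_nmb(delta_qalys: np.ndarray, delta_costs: np.ndarray,
                  lambda_grid: Sequence[float]) -> list[tuple[float, float]]:
    """P(cost-effective) = fraction of replicates with positive NMB."""
    out = []
    for lam in lambda_grid:
        nmb = lam * delta_qalys - delta_costs
        out.append((float(lam), float(np.mean(nmb > 0))))
    return out


def run_psa(spec: PSASpec, base_params) -> CEResult:
    """Probabilistic sensitivity analysis with CEAC construction.

    Per replicate a second-order parameter set is drawn, a fresh cohort of
    ``spec.n_patients`` is generated, and both strategies are simulated on it
    under common random numbers; the replicate contributes one (dQALY, dCost)
    point.  The CEAC reports, per willingness-to-pay, the fraction of
    replicates in which the RP strategy has positive net monetary benefit.
    """
    from .engine import run_strategy
    spec.validate()
    dqs = np.empty(spec.n_replicates)
    dcs = np.empty(spec.n_replicates)
    for r in range(spec.n_replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, STREAM_PSA, r]))
        params = draw_second_order(base_params, spec, rng)
        cohort_seed = int(rng.integers(0, 2 ** 31 - 1))
        master = int(rng.integers(0, 2 ** 31 - 1))
        cspec = replace(copy.deepcopy(base_params.cohort),
                        n=spec.n_patients, seed=cohort_seed)
        cohort = sample_cohort(cspec)
        res_sc = run_strategy(cohort, "sc", params, master)
        res_rp = run_strategy(cohort, "rp", params, master)
        dqs[r] = res_rp.mean_qaly - res_sc.mean_qaly
        dcs[r] = res_rp.mean_cost - res_sc.mean_cost
    dq = float(dqs.mean())
    dc = float(dcs.mean())
    ic = dc / dq if dq > 0 and dc > 0 else None
    label = "icer" if ic is not None else (
        "rp_dominant" if dq > 0 else "rp_dominated")
    return CEResult(dc, dq, ic, label,
                    ceac=ceac_from_nmb(dqs, dcs, spec.lambda_grid),
                    scatter=np.column_stack([dqs, dcs]))
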