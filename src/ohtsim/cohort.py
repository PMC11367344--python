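"""Synthetic ocular-hypertension cohort generation.

The simulation needs a population of newly diagnosed ocular hypertension (OHT)
patients — raised intraocular pressure (IOP >= 24 mmHg) without glaucomatous
damage — each carrying the risk factors that drive conversion to open-angle
glaucoma: age, IOP, central corneal thickness (CCT), pattern standard deviation
(PSD) of the visual field, vertical cup-to-disc ratio (vCD), and four binary
comorbidity/demography flags.  Real electronic medical records are not
available, so cohorts are synthesised from published marginal summaries:
continuous variables are truncated normals, binary variables are Bernoulli,
and (optionally) a Gaussian copula imposes a correlation structure on the
continuous block.  Each patient's age at death is pre-sampled once from an
annual life table, because background mortality is independent of ocular
disease in this model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class ConfigurationError(ValueError):
    """Invalid model configuration (bad spec field, missing rule, ...)."""


# Named RNG sub-streams: adding draws in one purpose never perturbs another.
STREAM_COHORT = 11
STREAM_MORTALITY = 12
STREAM_NATURAL_HISTORY = 13
STREAM_TREATMENT = 14
STREAM_PSA = 15


@dataclass(frozen=True)
class Marginal:
    """Truncated-normal marginal for one continuous baseline variable.

    ``mean``/``sd`` are the moments of the *truncated* distribution — the
    published summaries describe the population after inclusion criteria and
    plausibility limits were applied — so sampling moment-matches a parent
    normal whose truncation to [lower, upper] reproduces them.  (Sampling the
    stated moments as the parent's would, e.g., inflate the IOP mean well
    above its target because of the 24 mmHg inclusion floor.)
    """

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def validate(self, name: str) -> None:
        if self.sd < 0:
            raise ConfigurationError(f"{name}: sd must be >= 0, got {self.sd}")
        if not self.lower < self.upper:
            raise ConfigurationError(f"{name}: empty truncation interval")
        if self.sd == 0 and not (self.lower <= self.mean <= self.upper):
            raise ConfigurationError(f"{name}: point mass outside bounds")


@dataclass(frozen=True)
class PatientProfile:
    """One simulated patient's baseline risk factors and pre-sampled death age."""

    id: int
    age: float            # years
    iop_baseline: float   # mmHg, >= 24 by inclusion criterion
    cct: float            # micrometres
    psd: float            # dB
    vcd: float            # ratio in [0, 1]
    hypertension: bool
    family_history: bool
    diabetes: bool
    male: bool
    previously_treated: bool
    death_age: float      # years, > age


# Order of continuous variables in the copula / correlation matrix.
CONTINUOUS_VARS = ("age", "cct", "iop", "psd", "vcd")
BINARY_VARS = ("hypertension", "family_history", "diabetes", "male",
               "previously_treated")


@dataclass
class CohortSpec:
    """Sampling plan for a synthetic cohort.

    Defaults reproduce the marginal statistics of the source EMR population:
    mean age 62.01 (SD 10.56), CCT 558.66 (35.83) um, IOP 26.51 (2.13) mmHg
    floored at the 24 mmHg inclusion criterion, PSD 1.63 (0.34) dB, vCD 0.46
    (0.17), and the five binary prevalences.  Truncation bounds are
    physiologic-plausibility limits.  ``correlation`` (optional, 5x5 over the
    continuous block in :data:`CONTINUOUS_VARS` order) enables a Gaussian
    copula; the default is independence, which is the honest choice when only
    marginals are published.
    """

    n: int
    seed: int = 0
    age: Marginal = field(default_factory=lambda: Marginal(62.01, 10.56, 35.0, 95.0))
    cct: Marginal = field(default_factory=lambda: Marginal(558.66, 35.83, 400.0, 700.0))
    iop: Marginal = field(default_factory=lambda: Marginal(26.51, 2.13, 24.0, 40.0))
    psd: Marginal = field(default_factory=lambda: Marginal(1.63, 0.34, 0.3, 4.0))
    vcd: Marginal = field(default_factory=lambda: Marginal(0.46, 0.17, 0.05, 0.95))
    prevalence: dict = field(default_factory=lambda: {
        "hypertension": 0.12,
        "family_history": 0.26,
        "diabetes": 0.14,
        "male": 0.43,
        "previously_treated": 0.36,
    })
    md_at_conversion_mean: float = -2.94   # dB, negative by convention
    md_at_conversion_sd: float = 2.67      # dB
    correlation: Optional[np.ndarray] = None

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigurationError(f"n must be >= 0, got {self.n}")
        for name in CONTINUOUS_VARS:
            getattr(self, name).validate(name)
        for name in BINARY_VARS:
            if name not in self.prevalence:
                raise ConfigurationError(f"prevalence missing for {name}")
            p = self.prevalence[name]
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"prevalence[{name}] must be in [0,1], got {p}")
        if self.md_at_conversion_mean >= 0:
            raise ConfigurationError("md_at_conversion_mean must be negative")
        if self.md_at_conversion_sd < 0:
            raise ConfigurationError("md_at_conversion_sd must be >= 0")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            k = len(CONTINUOUS_VARS)
            if c.shape != (k, k):
                raise ConfigurationError(f"correlation must be {k}x{k}")
            if not np.allclose(c, c.T) or np.any(np.linalg.eigvalsh(c) < -1e-9):
                raise ConfigurationError("correlation must be symmetric PSD")


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities q(x) by integer age, gender-averaged.

    ``ages`` is contiguous and increasing; the final q is forced to 1 so every
    sampled lifetime terminates inside the table.
    """

    ages: np.ndarray   # int years
    qx: np.ndarray     # annual probability of death in [0, 1]

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        if ages.ndim != 1 or ages.size == 0 or qx.shape != ages.shape:
            raise ConfigurationError("life table: ages/qx shape mismatch")
        if np.any(np.diff(ages) != 1):
            raise ConfigurationError("life table: ages must be contiguous")
        if np.any((qx < 0) | (qx > 1)):
            raise ConfigurationError("life table: qx outside [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)

    @property
    def start_age(self) -> int:
        return int(self.ages[0])

    @property
    def end_age(self) -> int:
        return int(self.ages[-1])

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ConfigurationError(f"life table {path}: need 2 columns (age, qx)")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    @classmethod
    def load_default(cls) -> "LifeTable":
        """Bundled synthetic UK-like table (see data/uk_life_table_synthetic.csv)."""
        with resources.as_file(
            resources.files("ohtsim.data") / "uk_life_table_synthetic.csv"
        ) as p:
            return cls.from_csv(p)

    def survival_curve(self, from_age: int) -> np.ndarray:
        """S(k) = P(alive k whole years after ``from_age``), k = 0, 1, ..."""
        i0 = max(0, min(from_age - self.start_age, len(self.qx) - 1))
        return np.concatenate([[1.0], np.cumprod(1.0 - self.qx[i0:])])


def sample_death_age(age: float, life_table: LifeTable, rng) -> float:
    """Draw an age at death > ``age`` by inverse transform on the table.

    The death year is found on the cumulative survival curve from the integer
    age floor(``age``); the moment of death is uniform within that year.
    ``rng`` needs ``.random()`` (``random.Random`` or ``numpy`` Generator).
    """
    k0 = int(math.floor(age))
    if k0 > life_table.end_age:
        warnings.warn(
            f"age {age} beyond life-table range; clamping to final band")
        k0 = life_table.end_age
    surv = life_table.survival_curve(k0)   # S[0]=1 .. S[-1]=0 (last q forced 1)
    u = rng.random()                       # P(death in year k) = S[k] - S[k+1]
    s = 1.0 - u                            # find k with S[k+1] <= s < S[k]
    k = int(np.searchsorted(-surv, -s, side="right")) - 1
    k = min(max(k, 0), len(surv) - 2)
    lo = max(age, float(k0 + k))
    hi = float(k0 + k + 1)
    if hi <= lo:          # start age clamped into the final band
        hi = lo + 1.0
    frac = rng.random()
    return lo + frac * (hi - lo)


def _sample_death_ages(ages: np.ndarray, life_table: LifeTable,
                       rng: np.random.Generator) -> np.ndarray:
    """Vectorised counterpart of :func:`sample_death_age` (same distribution)."""
    ages = np.asarray(ages, dtype=float)
    out = np.empty_like(ages)
    floors = np.floor(ages).astype(int)
    floors = np.clip(floors, None, life_table.end_age)
    u = rng.random(len(ages))
    frac = rng.random(len(ages))
    for k0 in np.unique(floors):
        idx = np.where(floors == k0)[0]
        surv = life_table.survival_curve(int(k0))
        s = 1.0 - u[idx]
        k = np.searchsorted(-surv, -s, side="right") - 1
        k = np.clip(k, 0, len(surv) - 2)
        lo = np.maximum(ages[idx], k0 + k.astype(float))
        hi = k0 + k + 1.0
        out[idx] = lo + frac[idx] * (hi - lo)
    return out


_PARENT_CACHE: dict = {}


def _parent_params(m: Marginal) -> tuple[float, float]:
    """Parent-normal (mu, sigma) whose [lower, upper] truncation has the
    marginal's target mean and sd.  Cached; solved by root finding."""
    key = (m.mean, m.sd, m.lower, m.upper)
    if key in _PARENT_CACHE:
        return _PARENT_CACHE[key]
    if not (m.lower < m.mean < m.upper):
        raise ConfigurationError(
            f"marginal mean {m.mean} outside bounds ({m.lower}, {m.upper})")

    def moments(x):
        mu, logsd = x
        sd = math.exp(logsd)
        a, b = (m.lower - mu) / sd, (m.upper - mu) / sd
        mean, var = stats.truncnorm.stats(a, b, loc=mu, scale=sd,
                                          moments="mv")
        return [float(mean) - m.mean, math.sqrt(float(var)) - m.sd]

    from scipy.optimize import fsolve
    sol, info, ok, msg = fsolve(moments, [m.mean, math.log(m.sd)],
                                full_output=True)
    if ok != 1 or max(abs(r) for r in info["fvec"]) > 1e-6 * max(1.0, m.sd):
        raise ConfigurationError(
            f"cannot moment-match truncated normal for {m}: {msg}")
    out = (float(sol[0]), float(math.exp(sol[1])))
    _PARENT_CACHE[key] = out
    return out


def _truncnorm_ppf(u: np.ndarray, m: Marginal) -> np.ndarray:
    if m.sd == 0:
        return np.full_like(u, m.mean)
    mu, sd = _parent_params(m)
    a = (m.lower - mu) / sd
    b = (m.upper - mu) / sd
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sd)


def sample_cohort(spec: CohortSpec,
                  life_table: Optional[LifeTable] = None) -> list[PatientProfile]:
    """Synthesise ``spec.n`` patients; identical spec -> identical cohort.

    Continuous variables come from truncated normals (via uniform draws pushed
    through the ppf, so a copula can supply correlated uniforms), binary
    variables from independent Bernoullis, and death ages from the life table
    on a separate named stream.
    """
    spec.validate()
    if life_table is None:
        life_table = LifeTable.load_default()
    n = spec.n
    if n == 0:
        return []

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, STREAM_COHORT]))
    k = len(CONTINUOUS_VARS)
    if spec.correlation is None:
        u = rng.random((n, k))
    else:
        c = np.asarray(spec.correlation, dtype=float)
        z = rng.multivariate_normal(np.zeros(k), c, size=n,
                                    method="eigh")
        u = stats.norm.cdf(z)
        u = np.clip(u, 1e-12, 1 - 1e-12)

    cols = {}
    for j, name in enumerate(CONTINUOUS_VARS):
        cols[name] = _truncnorm_ppf(u[:, j], getattr(spec, name))
    for name in BINARY_VARS:
        cols[name] = rng.random(n) < spec.prevalence[name]

    mort_rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, STREAM_MORTALITY]))
    death = _sample_death_ages(cols["age"], life_table, mort_rng)

    return [
        PatientProfile(
            id=i,
            age=float(cols["age"][i]),
            iop_baseline=float(cols["iop"][i]),
            cct=float(cols["cct"][i]),
            psd=float(cols["psd"][i]),
            vcd=float(cols["vcd"][i]),
            hypertension=bool(cols["hypertension"][i]),
            family_history=bool(cols["family_history"][i]),
            diabetes=bool(cols["diabetes"][i]),
            male=bool(cols["male"][i]),
            previously_treated=bool(cols["previously_treated"][i]),
            death_age=float(death[i]),
        )
        for i in range(n)
    ]


def sample_md_at_conversion(mean: float, sd: float, rng) -> float:
    """Visual-field mean deviation (dB, < 0) at the moment of conversion.

    The magnitude is gamma-distributed with method-of-moments parameters
    shape k = (|mean|/sd)^2, scale theta = sd^2/|mean|; the sign convention
    (loss is negative) is applied on return.  ``rng`` is ``random.Random``.
    """
    if mean >= 0:
        raise ConfigurationError("MD at conversion must have negative mean")
    if sd < 0:
        raise ConfigurationError("sd must be >= 0")
    m = -mean
    if sd == 0:
        return mean
    shape = (m / sd) ** 2
    scale = sd * sd / m
    return -rng.gammavariate(shape, scale)


def cohort_to_frame(cohort: Sequence[PatientProfile]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in cohort])


def save_cohort(cohort: Sequence[PatientProfile], path) -> None:
    """Write one row per patient; round-trips losslessly via full float repr."""
    cohort_to_frame(cohort).to_csv(path, index=False)


def load_cohort(path) -> list[PatientProfile]:
    df = pd.read_csv(path, float_precision="round_trip")
    want = list(PatientProfile.__dataclass_fields__)
    missing = [c for c in want if c not in df.columns]
    if missing:
        raise ConfigurationError(f"cohort file missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(PatientProfile(
            id=int(d["id"]),
            age=float(d["age"]),
            iop_baseline=float(d["iop_baseline"]),
            cct=float(d["cct"]),
            psd=float(d["psd"]),
            vcd=float(d["vcd"]),
            hypertension=bool(d["hypertension"]),
            family_history=bool(d["family_history"]),
            diabetes=bool(d["diabetes"]),
            male=bool(d["male"]),
            previously_treated=bool(d["previously_treated"]),
            death_age=float(d["death_age"]),
        ))
    return out


def make_synthetic_life_table(makeham_a: float = 3.0e-4,
                              gompertz_b: float = 2.6e-5,
                              gompertz_theta: float = 0.093,
                              start_age: int = 35,
                              end_age: int = 109) -> LifeTable:
    """Gompertz–Makeham annual death probabilities, q(x) = 1 - exp(-mu(x)).

    Defaults are calibrated so that remaining life expectancy at 62 is ~23
    years, matching a UK-like gender-averaged period table.  The last band is
    forced to q = 1.
    """
    ages = np.arange(start_age, end_age + 1)
    mu = makeham_a + gompertz_b * np.exp(gompertz_theta * ages)
    qx = 1.0 - np.exp(-mu)
    qx[-1] = 1.0
    return LifeTable(ages, np.clip(qx, 0.0, 1.0))
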