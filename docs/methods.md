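# Methods

`ohtsim` is a patient-level discrete event simulation (DES) of ocular
hypertension (OHT) monitoring in the UK NHS. It compares two rules for
deciding, at a single secondary-care entry assessment, which newly diagnosed
OHT patients (intraocular pressure, IOP ≥ 24 mmHg) receive IOP-lowering
treatment:

* **Standard care (SC)** — a clinician-style decision table over IOP, age and
  central corneal thickness (CCT) bands;
* **Risk prediction (RP)** — treat every patient whose scored 5-year risk of
  conversion to open-angle glaucoma (OAG) is ≥ 6%.

Outcomes are lifetime discounted NHS costs and QALYs per patient, their
increments, the ICER, one-way sensitivity analyses, and a probabilistic
sensitivity analysis (PSA) summarised as a cost-effectiveness acceptability
curve (CEAC).

## Model structure

Each patient carries baseline risk factors (age, IOP, CCT, visual-field
pattern standard deviation PSD, vertical cup-to-disc ratio vCD, four binary
factors) and a pre-sampled age at death. From entry, the patient repeatedly
faces three competing clocks — next scheduled check-up, next natural-history
event (conversion, or progression to a worse glaucoma stage), and death —
and the earliest fires. All clocks are recomputed whenever an event changes
the state.

**Conversion.** The annual hazard of OHT → OAG conversion is proportional:

    h(t) = h0 · exp( β_age·(age(t) − 62.01)/10 + β_iop·(IOP(t) − 26.51)
                     + β_cct·(558.66 − CCT)/40 + β_psd·(PSD − 1.63)/0.2
                     + β_vcd·(vCD − 0.46)/0.1 )

with age advancing continuously (age(t) = entry age + t) and IOP equal to the
current, treatment-modified pressure. Between events the hazard is held
constant, so times-to-conversion are exponential draws that are memorylessly
resampled at every check-up; this makes the piecewise-constant approximation
of the rising hazard exact at event resolution (untreated patients are seen
at least annually). An optional lognormal, unit-mean patient frailty
(`nh.frailty_sd`, default 0) multiplies the hazard to represent risk
heterogeneity invisible to any scoring tool.

**Progression.** At conversion the visual-field mean deviation (MD, dB) is
drawn as the negative of a gamma variate (method-of-moments fit to mean
−2.94, SD 2.67 dB); MD then declines linearly at

    dMD/dt = −max(0, a + b·(IOP − 26.51))   dB/year,

and the four-stage classification (mild > −6; moderate (−12, −6]; severe
(−20, −12]; visual impairment ≤ −20 dB) follows MD deterministically, with
visual impairment absorbing. A gamma tail worse than −6 dB means a patient
can enter directly at a worse stage; the sampled distribution is respected
rather than clamped.

**Risk tool.** The RP score is `1 − (1 − p0)^exp(LP)` with the same covariate
structure as the hazard. Two deliberate differences keep the tool a
*predictor* rather than a copy of the generator: its age coefficient is the
flatter cross-sectional gradient between patients (0.20/decade) rather than
the within-person ageing trend (0.45/decade), and its baseline `p0` is
calibrated so the cohort's mean scored risk equals the untreated 5-year
conversion fraction (17%). Optional per-patient scoring noise
(`risk.score_noise_sd`, default 0) degrades the tool's discrimination
without touching the natural history.

**Pathways.** Treated patients start on prostaglandin analogue (PGA) drops
(80%) or selective laser trabeculoplasty (SLT) (20%). Each line lowers the
current IOP by a proportional reduction drawn once per patient and line
(Normal, clipped to [0, 0.9]); medication effects scale with adherence
(base 1.0), procedures do not. "On-target" means IOP ≥ 20% below the IOP at
model entry (boundary inclusive). Off-target patients escalate one line per
visit along PGA → PGA+beta-blocker → SLT → trabeculectomy (terminal).
Untreated patients are reviewed annually in primary care (£23.14 full sight
test); off-target treated OHT patients and newly observed converters are
referred to secondary care (conversion triggers an immediate £294
assessment); on-target treated OHT patients return to primary care after one
hospital visit. Hospital OHT reviews are 6-monthly, alternating IOP-only
(£147) and IOP+VF (£294) bundles. Confirmed glaucoma is managed in secondary
care for life with 4-monthly full assessments — the review interval NICE
recommends for progressing disease; this intensity is also what the
lifetime-cost calibration (below) supports. Conversion and progression are
*observed* only at visits: true state and observed state are tracked
separately, and utilities attach to the true stage (vision loss affects
quality of life whether or not it has been measured yet).

**Economics.** Utilities by stage: OHT/mild 0.8015, moderate 0.7471, severe
0.7133, visual impairment 0.535. Costs: PGA £149.76/yr, PGA+BB combination
£171.84/yr (the combination product's price, replacing the PGA price),
SLT £151 and trabeculectomy £1694 one-off at escalation, plus the monitoring
bundles above. Costs and QALYs are discounted continuously at
ρ = ln(1.035); interval accrual uses the exact closed form
`v·(e^(−ρt0) − e^(−ρt1))/ρ`, so zero-discount results reduce to
utility-weighted life-years to machine precision.

## Synthetic cohort

No patient-level records are available, so cohorts are synthesised from
published marginal summaries: truncated normals for the five continuous
variables and Bernoulli for the binary ones. The published moments describe
the *already-truncated* population (the 24 mmHg floor is an inclusion
criterion), so the generator moment-matches the parent normal such that the
truncated distribution reproduces the target mean/SD — naively sampling
truncnorm(26.51, 2.13, lo=24) would inflate the IOP mean to ~27.0.
Truncation bounds are plausibility limits: age [35, 95], CCT [400, 700] µm,
IOP [24, 40] mmHg, PSD [0.3, 4] dB, vCD [0.05, 0.95]. Marginals are
independent by default; a Gaussian copula over the continuous block is
available for sensitivity exploration, because the joint structure of the
real population is unknown. Death ages come from a bundled synthetic
Gompertz–Makeham life table (`uk_life_table_synthetic.csv`, μ(x) = 3.0e−4 +
2.6e−5·e^(0.093x), final band forced to q = 1) calibrated to a UK-like
gender-averaged remaining life expectancy of ~23.0 years at age 62; any
two-column (age, qx) CSV can replace it.

What the generator does **not** emulate: correlations between risk factors,
measurement error and visit-to-visit IOP fluctuation, bilateral eyes,
treatment intolerance and discontinuation, and secular trends. Passing tests
therefore demonstrate internal consistency of the model and reproduction of
the calibrated aggregate behaviour, not fidelity to any real patient
population.

## Calibration

The functional skeleton above has constants that are not identifiable from
published aggregates alone. They were calibrated, in this order, against the
reference outcomes the model is built to reproduce:

1. `h0` (via the baseline 5-year probability, default 0.1446): solved so the
   expected untreated 5-year conversion fraction of the default cohort is
   17% (closed form per patient, with death truncation and ageing integrated
   analytically; `config.calibrate_baseline_risk` re-solves it for any
   configuration).
2. `β_age = 0.45/decade`: without ageing, a 17% 5-year rate caps lifetime
   untreated conversion near 50%, which is incompatible with 57% of the
   SC arm converting when 47% of it is treated; 0.45/decade reconciles the
   two.
3. The SC decision table: treat IOP ≥ 28; treat IOP 26–28 with thin cornea
   (< 555 µm) or age ≥ 65; treat IOP 24–26 only with thin cornea at age
   65–79 (the very elderly in the lowest band gain too little lifetime
   benefit). This treats 47.7% of the default cohort.
4. `β_iop = 0.055/mmHg` (hazard ratio ≈ 1.06 per mmHg) and the MD decline
   parameters `a = 0.65` dB/yr at reference IOP, `b = 0.03` dB/yr per mmHg:
   chosen jointly so the SC arm's lifetime conversion (58%), end-state
   distribution, the strategies' mean discounted costs, the incremental
   QALYs (≈ 0.024) and the ICER (≈ £10–11k/QALY) all land at the reference
   base case. The glaucoma review interval (4-monthly) is part of the same
   joint calibration.

The remaining coefficients (CCT 0.10 per 40 µm, PSD 0.10 per 0.2 dB, vCD
0.15 per 0.1; binary factors 0) are fixed at conventional moderate values
and act only through cohort heterogeneity.

## Sensitivity analyses

One-way scenarios perturb exactly one dotted-path parameter each and re-run
both strategies on the same 10,000-patient cohort with identical seeds, so
scenario differences are attributable to the parameter alone.

The PSA draws, per replicate: treatment-effect means ~ Normal(mean, SD)
truncated at 0 (the published effect SDs); the top (OHT = mild) utility
~ Beta moment-matched with SD 0.02 and the three severity *decrements*
~ Gamma with CV 0.15 — decrements rather than per-state draws, because
independently drawn state utilities re-sorted for monotonicity inflate the
mean stage gaps (order-statistic bias; measured to double the incremental
QALYs); estimated unit costs (monitoring bundles, SLT, trabeculectomy)
~ Gamma with CV 0.20, while BNF tariff medication prices are policy-set
exact prices and carry no estimation uncertainty. Each replicate simulates
a fresh matched cohort under both strategies; the CEAC is the fraction of
replicates with positive net monetary benefit λ·ΔQ − ΔC.

## Numerical choices

* Tie-breaking of simultaneous clocks: death > natural history > check-up
  (ties have probability zero in continuous time; the order only matters in
  constructed tests).
* MD is advanced to the exact stage cutpoint at progression events to avoid
  float drift; a boundary MD belongs to the worse stage, and the next
  crossing targets the following cutpoint (never a zero-time event).
* Per-patient random substreams are derived deterministically from
  (master seed, patient id); the patient-level draws that both strategies
  need (allocation branch, score noise, the four line effects, MD at
  conversion, frailty) are all drawn up front in a fixed order, so the two
  arms are compared under common random numbers even when their event paths
  diverge.
* An event-count guard (10,000 per patient) turns any non-terminating
  configuration into an explicit simulation error.
* Degenerate inputs: zero SDs give point masses; zero hazard gives an
  infinite conversion time; zero MD slope freezes progression; a zero
  discount rate switches accrual to its exact undiscounted limit.

## Known limitations

* With the default, fully informative risk score, raising the RP threshold
  sheds the lowest-benefit patients first, so the ICER *falls* with the
  threshold and the RP strategy eventually dominates. Decision tools with
  weak discrimination (concordance ~0.7) show the opposite, rising-ICER
  pattern; `risk.score_noise_sd ≈ 0.8` reproduces it, but also spreads the
  score distribution so that only ~88% of this high-risk cohort clears the
  6% threshold. The two regimes cannot be combined under this model
  skeleton, and the defaults keep the informative score.
* Medication, once started, is accrued for life (no discontinuation
  process; adherence scales the effect, not the duration). This makes the
  ICER roughly twice as sensitive to the PGA price (+50% price → ~+90%
  ICER) as it would be in a model where medication exposure is shorter.
* Treatment effects are permanent single draws: no IOP drift, waning, or
  repeat off-target excursions after the initial titration sequence.
* Glaucoma management costs are stage-independent; severe disease and
  visual impairment likely cost more in reality, which would favour the
  treat-more strategy.
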