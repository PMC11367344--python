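# ohtsim

Discrete event simulation of ocular hypertension (OHT) monitoring and
treatment in the UK NHS, comparing two rules for initiating IOP-lowering
therapy at the secondary-care entry assessment:

* **standard care (SC)** — a clinician decision table over IOP, age and
  corneal thickness bands, and
* **risk prediction (RP)** — treat everyone whose scored 5-year risk of
  conversion to open-angle glaucoma is ≥ 6%,

and evaluating their lifetime cost-effectiveness (discounted NHS costs,
QALYs, ICER, one-way and probabilistic sensitivity analyses). It is aimed at
health-economic modellers and glaucoma researchers who want a transparent,
scriptable re-implementation of this class of monitoring model.

## The model in brief

Each simulated patient (age, IOP, CCT, PSD, vCD and comorbidity flags drawn
from published marginal summaries; death age from a life table) repeatedly
faces three competing events — check-up, natural-history event, death — and
the earliest clock fires. Conversion OHT → glaucoma follows a proportional
hazard

&nbsp;&nbsp;&nbsp;&nbsp;h(t) = h₀ · exp(β·x(t)),&nbsp;&nbsp;
x(t) = current age, IOP and baseline risk factors,

with exponential, memorylessly-resampled event times; after conversion the
visual-field mean deviation declines linearly in time (rate increasing in
IOP) through the mild / moderate / severe / visual-impairment stages.
Treatment escalates PGA → PGA+BB → SLT → trabeculectomy until IOP is
reduced ≥ 20% from baseline. QALYs accrue continuously at the true stage's
utility and, like costs, are discounted at ρ = ln(1.035). The incremental
comparison is run under common random numbers, and the PSA summarises
second-order uncertainty as a CEAC via net monetary benefit. Full model
description, calibration account and limitations: [docs/methods.md](docs/methods.md).

## Worked example

```python
from ohtsim import icer, run_strategy, sample_cohort
from ohtsim.config import default_params

params = default_params(n=20_000, seed=1)
cohort = sample_cohort(params.cohort)           # synthetic OHT cohort
sc = run_strategy(cohort, "sc", params, master_seed=1)
rp = run_strategy(cohort, "rp", params, master_seed=1)
print(icer(sc, rp))
```

or, as a script, `python analysis/02_base_case.py --n 20000`, which prints

```
  SC  treated  47%  end states [OHT mild mod sev VI]:  42%   19%   24%   13%    2%
  RP  treated 100%  end states [OHT mild mod sev VI]:  49%   18%   21%   11%    2%

mean discounted cost : SC    5,174  RP    5,428  (delta +253)
mean discounted QALY : SC   11.653  RP   11.677  (delta +0.0242)
ICER                 : 10,470 GBP/QALY
```

Reading: the decision table treats 47% of the cohort, the 6% risk threshold
effectively everyone; treating more delays conversion (49% vs 42% still
conversion-free at death) and shifts the end-state mix towards milder
disease. The RP strategy costs ~£253 more per patient (medication for the
extra half of the cohort, partly offset by deferred glaucoma monitoring) and
gains ~0.024 discounted QALYs, i.e. ~£10,500 per QALY — cost-effective
against the usual £20,000/QALY willingness-to-pay.

The numbered drivers under `analysis/` reproduce each stage: `01_make_cohort`
(cohort marginals), `02_base_case`, `03_one_way_sa` (risk-threshold sweep,
price and adherence scenarios), `04_psa` (CEAC and cost-effectiveness
plane); outputs land under `results/`.

## Configuration

All parameters (cohort marginals, risk coefficients, decision table,
natural history, treatment lines, monitoring schedule, economics) live in
dataclasses with calibrated defaults; `ohtsim.load_config` applies a YAML
override file with strict unknown-key checking, and the standard-care
decision table and life table are replaceable CSV files.
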