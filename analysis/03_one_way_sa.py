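"""One-way sensitivity analyses on the matched 10,000-patient cohort.

Sweeps the risk-prediction treatment threshold (2-16%), scales the PGA
medication price and the monitoring unit costs by up to 1.5x, and lowers
medication adherence to 75%; each scenario perturbs exactly one parameter
and re-runs both strategies with identical seeds.  Results land in
results/one_way_sa.csv.

Note on the threshold sweep: with the default (fully informative) risk
score, raising the threshold drops the lowest-benefit patients from
treatment first, so the ICER *falls* and the risk strategy eventually
dominates — the opposite of what a poorly discriminating score produces.
See docs/methods.md for the discussion and the `risk.score_noise_sd` /
`nh.frailty_sd` knobs that degrade the score's discrimination.
"""

import argparse
from pathlib import Path

import pandas as pd

from ohtsim import Scenario, one_way_sa
from ohtsim.config import default_params


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=10_000)
    ap.add_argument("--seed", type=int, default=2)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    params = default_params(n=args.n, seed=args.seed)
    scenarios = [Scenario("baseline", "rp_threshold", 0.06)]
    for thr in (0.02, 0.04, 0.08, 0.10, 0.12, 0.14, 0.16):
        scenarios.append(Scenario(f"threshold_{thr:.2f}", "rp_threshold", thr))
    for m in (1.1, 1.3, 1.5):
        scenarios.append(Scenario(f"pga_cost_x{m}",
                                  "pathways.lines.PGA.annual_cost",
                                  149.76 * m))
    for m in (1.1, 1.5):
        scenarios.append(Scenario(f"primary_test_x{m}",
                                  "pathways.schedule.cost_primary_iop_vf",
                                  23.14 * m))
        scenarios.append(Scenario(f"secondary_test_x{m}",
                                  "pathways.schedule.cost_secondary_iop_vf",
                                  294.0 * m))
    scenarios.append(Scenario("adherence_0.75", "pathways.adherence", 0.75))

    print(f"running {len(scenarios)} scenarios x 2 strategies "
          f"x {args.n} patients ...")
    rows = one_way_sa(params, scenarios, n=args.n, master_seed=args.seed)
    df = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "one_way_sa.csv", index=False)
    with pd.option_context("display.width", 120):
        print(df[["scenario", "delta_cost", "delta_qaly", "icer", "label"]]
              .to_string(index=False))
    base = df.loc[df.scenario == "baseline", "icer"].iloc[0]
    print(f"\nSA baseline ICER: {base:,.0f} GBP/QALY")
    print(f"wrote {args.out / 'one_way_sa.csv'}")


if __name__ == "__main__":
    main()
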