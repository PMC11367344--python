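"""Run reports: a base-case summary table plus machine-readable JSON.

The human-readable report mirrors the conventional presentation of a
cost-effectiveness base case — initially-treated percentage, end-of-run state
distribution, mean discounted cost and QALYs per strategy, the increments and
the ICER — with percentages rounded to integers; the JSON keeps full
precision and a provenance block (master seed, config digest).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .economics import CEResult
from .engine import StrategyResult

STAGE_NAMES = ("OHT", "mild", "moderate", "severe", "visual_impairment")


def result_dict(res: StrategyResult) -> dict:
    return {
        "strategy": res.strategy,
        "n": res.n,
        "mean_cost": res.mean_cost,
        "mean_qaly": res.mean_qaly,
        "mean_cost_undiscounted": res.mean_cost_undiscounted,
        "mean_qaly_undiscounted": res.mean_qaly_undiscounted,
        "frac_treated": res.frac_treated,
        "frac_converted": res.frac_converted,
        "end_state_dist": {k: float(v) for k, v in
                           zip(STAGE_NAMES, res.end_state_dist)},
    }


def write_report(res_sc: StrategyResult, res_rp: StrategyResult,
                 ce: CEResult, out_dir, seed: int,
                 digest: str = "") -> dict:
    """Write report.txt / report.json under ``out_dir``; returns the dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    payload = {
        "provenance": {"master_seed": seed, "config_digest": digest},
        "standard_care": result_dict(res_sc),
        "risk_prediction": result_dict(res_rp),
        "incremental": {
            "delta_cost": ce.delta_cost,
            "delta_qaly": ce.delta_qaly,
            "icer": ce.icer,
            "label": ce.label,
        },
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2))

    def pct_row(res: StrategyResult) -> str:
        states = "  ".join(f"{100 * v:3.0f}%" for v in res.end_state_dist)
        return (f"{res.strategy.upper():>4}  treated {100 * res.frac_treated:3.0f}%  "
                f"end states [OHT mild mod sev VI]: {states}")

    icer_txt = (f"{ce.icer:,.0f} GBP/QALY" if ce.icer is not None
                else ce.label)
    txt = "\n".join([
        "Base-case cost-effectiveness summary",
        f"(n = {res_sc.n} per strategy, master seed {seed}, "
        f"config {digest or 'default'})",
        "",
        pct_row(res_sc),
        pct_row(res_rp),
        "",
        f"mean discounted cost : SC {res_sc.mean_cost:8,.0f}  "
        f"RP {res_rp.mean_cost:8,.0f}  (delta {ce.delta_cost:+,.0f})",
        f"mean discounted QALY : SC {res_sc.mean_qaly:8.3f}  "
        f"RP {res_rp.mean_qaly:8.3f}  (delta {ce.delta_qaly:+.4f})",
        f"ICER                 : {icer_txt}",
        "",
    ])
    (out / "report.txt").write_text(txt)
    return payload


def write_ceac(ce: CEResult, out_dir) -> None:
    """Export CEAC points and the PSA scatter as delimited text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if ce.ceac is not None:
        lines = ["wtp,prob_cost_effective"]
        lines += [f"{lam:.0f},{p:.6f}" for lam, p in ce.ceac]
        (out / "ceac.csv").write_text("\n".join(lines) + "\n")
    if ce.scatter is not None:
        arr = np.asarray(ce.scatter)
        lines = ["delta_qaly,delta_cost"]
        lines += [f"{q:.8f},{c:.4f}" for q, c in arr]
        (out / "psa_scatter.csv").write_text("\n".join(lines) + "\n")
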