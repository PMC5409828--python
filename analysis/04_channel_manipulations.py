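#!/usr/bin/env python
"""Virtual channel pharmacology on the somatodendritic-H reference model.

Three manipulations of the calibrated control model (run 02 and 03 first):

* H + Kdrs block, with the excitatory conductance re-tuned at fixed
  inhibition to restore the ~2.5 Hz baseline;
* H block alone (same re-tuning rule);
* cAMP modulation: the H activation midpoint depolarized by +5 mV (−84 →
  −79 mV) with no synaptic recalibration.

Writes results/sweep_manipulations.csv and the qualitative pass/fail report
to results/qualitative_checks.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from olmtheta.calibration import CalibrationResult, OperatingPoint, retune_excitation
from olmtheta.channels import apply_block, with_camp
from olmtheta.reference import load_reference, modulated_summaries, spawn_seeds

SEED = 1
FREQS = (2.0, 3.0, 4.0, 5.0, 8.0, 10.0, 12.0)
N_SEEDS = 3
OUT = Path("results")


def sweep_rows(params, morph, sites, cal, condition):
    rows = []
    for f in FREQS:
        seeds = spawn_seeds(SEED, f"manip-{condition}-{f}", N_SEEDS)
        for seed, s in zip(seeds, modulated_summaries(
                params, morph, sites, cal, f, seeds)):
            rows.append({
                "condition": condition, "f_mod": f, "seed": seed,
                "power_ratio": s.power_ratio,
                "rotation_number": s.rotation_number,
                "vector_strength": s.vector_strength,
                "mean_phase_deg": s.mean_phase_deg,
            })
    return rows


def main() -> None:
    with open(OUT / "calibration.json") as fh:
        c = json.load(fh)["HSD"]
    params, morph, sites = load_reference("HSD")
    cal = CalibrationResult(
        g_exc=c["g_exc_nS"], g_inh=c["g_inh_nS"],
        achieved_rate=c["held_out_rate_hz"], achieved_sd=c["subthreshold_sd_mv"],
        achieved_mean_vm=c["subthreshold_mean_mv"],
    )
    op = OperatingPoint(measure_duration=8000.0, n_seeds=2)

    rows = sweep_rows(params, morph, sites, cal, "control")
    rows += sweep_rows(with_camp(params), morph, sites, cal, "camp")
    for blocked_set, name in (({"H"}, "minusH"), ({"H", "Kdrs"}, "minusH_minusKdrs")):
        blocked = apply_block(params, blocked_set)
        recal = retune_excitation(morph, blocked, sites, cal.g_inh, op,
                                  g_exc_hint=cal.g_exc, base_seed=SEED)
        print(f"{name}: g_exc {cal.g_exc:.4f} -> {recal.g_exc:.4f} nS "
              f"(baseline {recal.achieved_rate:.2f} Hz, g_inh fixed)")
        rows += sweep_rows(blocked, morph, sites, recal, name)

    table = pd.DataFrame(rows)
    table.to_csv(OUT / "sweep_manipulations.csv", index=False)

    med = table.groupby(["condition", "f_mod"]).median(numeric_only=True)
    checks = []
    peaks = {c: float(g.power_ratio.idxmax()[1])
             for c, g in med.groupby(level=0)}
    phase8 = med.loc[("control", 8.0), "mean_phase_deg"]
    checks.append({
        "check": "hsd_8hz_phase_near_180",
        "passed": bool(abs(phase8 - 180.0) <= 45.0),
        "value": float(phase8),
    })
    checks.append({
        "check": "hsd_minus_h_kdrs_peak_low_theta",
        "passed": bool(2.0 <= peaks["minusH_minusKdrs"] <= 4.0),
        "value": peaks["minusH_minusKdrs"],
    })
    checks.append({
        "check": "hsd_camp_peak_8_10hz",
        "passed": bool(8.0 <= peaks["camp"] <= 10.0),
        "value": peaks["camp"],
    })
    with open(OUT / "qualitative_checks.json", "w") as fh:
        json.dump(checks, fh, indent=2)
    for rec in checks:
        print(f"{rec['check']}: {'PASS' if rec['passed'] else 'FAIL'} "
              f"(value {rec['value']:.1f})")


if __name__ == "__main__":
    main()
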