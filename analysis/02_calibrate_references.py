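#!/usr/bin/env python
"""Calibrate the reference models to the high-conductance operating point.

For each reference model (rank 6, somatodendritic H; rank 26, somatic H) the
script searches per-site peak synaptic conductances that yield ~2.5 Hz
baseline firing under unmodulated 500/1000 Hz Poisson bombardment while
maximizing the subthreshold fluctuation SD, then validates the rate on fresh
seeds and writes results/calibration.json.
"""

import json
from pathlib import Path

from olmtheta.calibration import OperatingPoint, measure_operating_point
from olmtheta.reference import calibrate_reference, spawn_seeds

SEED = 1
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    op = OperatingPoint()
    out = {}
    for h_dist in ("HSD", "HS"):
        params, morph, sites, cal = calibrate_reference(h_dist, SEED, op)
        held_out = spawn_seeds(SEED, f"validate-{h_dist}", 5)
        rate, sd, mean_vm = measure_operating_point(
            morph, params, sites, cal.g_exc, cal.g_inh, op, held_out
        )
        out[h_dist] = {
            "rank": params.rank,
            "g_exc_nS": cal.g_exc,
            "g_inh_nS": cal.g_inh,
            "calibration_rate_hz": cal.achieved_rate,
            "held_out_rate_hz": rate,
            "subthreshold_sd_mv": sd,
            "subthreshold_mean_mv": mean_vm,
        }
        print(
            f"{h_dist} (rank {params.rank}): g_exc={cal.g_exc:.4f} nS, "
            f"g_inh={cal.g_inh:.4f} nS -> {rate:.2f} Hz held-out "
            f"(SD {sd:.2f} mV, mean {mean_vm:.1f} mV)"
        )
    with open(OUT / "calibration.json", "w") as fh:
        json.dump(out, fh, indent=2)


if __name__ == "__main__":
    main()
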