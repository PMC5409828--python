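#!/usr/bin/env python
"""Statistical layer applied to the sweep tables (run 03 and 04 first).

Desk-scale demonstration of the statistical protocol on the reduced
ensembles: drive realizations (seeds) stand in for the per-model subjects
that a full-scale design would use.

* Normality-gated two-sample comparison (Anderson–Darling, then Wilcoxon
  rank-sum or a t test) of somatic-H vs somatodendritic-H vector strength at
  3 Hz and at 8 Hz.
* Two-way repeated-measures ANOVA (frequency × condition) with Huynh–Feldt
  correction on the manipulation table's power ratios (control vs H+Kdrs
  block).

Writes results/statistics.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from olmtheta.stats import compare_two_samples, rm_anova_hf

OUT = Path("results")


def main() -> None:
    sweep = pd.read_csv(OUT / "sweep_control.csv")
    manip = pd.read_csv(OUT / "sweep_manipulations.csv")
    out = {}

    for f in (3.0, 8.0):
        hs = sweep[(sweep.h_dist == "HS") & (sweep.f_mod == f)].vector_strength.values
        hsd = sweep[(sweep.h_dist == "HSD") & (sweep.f_mod == f)].vector_strength.values
        res = compare_two_samples(hs, hsd)
        out[f"vs_HS_vs_HSD_at_{f:g}Hz"] = {
            "test": res.test_used, "statistic": res.statistic, "p": res.p,
            "median_HS": float(np.median(hs)), "median_HSD": float(np.median(hsd)),
        }
        print(f"VS at {f:g} Hz, HS vs HSD: {res.test_used}, p = {res.p:.4g} "
              f"(medians {np.median(hs):.2f} vs {np.median(hsd):.2f})")

    # rmANOVA: seeds x frequency x condition on power ratios
    conds = ["control", "minusH_minusKdrs"]
    sub = manip[manip.condition.isin(conds)]
    freqs = sorted(sub.f_mod.unique())
    n_seeds = sub.groupby(["condition", "f_mod"]).size().min()
    data = np.empty((n_seeds, len(freqs), len(conds)))
    for j, f in enumerate(freqs):
        for k, c in enumerate(conds):
            vals = sub[(sub.f_mod == f) & (sub.condition == c)].power_ratio.values
            data[:, j, k] = vals[:n_seeds]
    res = rm_anova_hf(data)
    out["rm_anova_power_ratio"] = {
        eff: {
            "F": r.F, "df": r.df, "epsilon_hf": r.epsilon_hf,
            "df_corrected": r.df_corrected, "p_corrected": r.p_corrected,
        }
        for eff, r in res.items()
    }
    for eff, r in res.items():
        print(f"rmANOVA {eff}: F({r.df_corrected[0]:.2f},{r.df_corrected[1]:.2f}) "
              f"= {r.F:.2f}, HF-corrected p = {r.p_corrected:.4g}")

    with open(OUT / "statistics.json", "w") as fh:
        json.dump(out, fh, indent=2)


if __name__ == "__main__":
    main()
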