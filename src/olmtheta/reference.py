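"""Reference-model protocol shared by the analysis scripts and acceptance runs.

One representative model per H-distribution group anchors the headline
measurements: rank 6 for somatodendritic H and rank 26 for somatic H (the
best-behaved variant of each group under the package's reference kinetics;
all 32 printed parameter sets load and run).  The protocol is: calibrate the
baseline operating point (~2.5 Hz under unmodulated bombardment), then drive
the model with square-wave-modulated inhibition on held-out seeds and score
the spike train.
"""

from __future__ import annotations

import numpy as np

from .calibration import CalibrationResult, OperatingPoint, calibrate_baseline
from .channels import ModelParameters, load_model_parameters
from .drive import ModulationSpec, build_drive
from .metrics import ResonanceSummary, summarize
from .morphology import Morphology, SynapseSite, place_synapse_sites, standard_morphology
from .simulator import SimulationConfig, detect_spikes, simulate

__all__ = [
    "REFERENCE_HSD_RANK",
    "REFERENCE_HS_RANK",
    "load_reference",
    "calibrate_reference",
    "modulated_summaries",
    "spawn_seeds",
]

REFERENCE_HSD_RANK = 6
REFERENCE_HS_RANK = 26


def spawn_seeds(master_seed: int, label: str, n: int) -> list[int]:
    """n reproducible 31-bit seeds derived from a master seed and a label."""
    ss = np.random.SeedSequence(entropy=int(master_seed) % (2**31),
                                spawn_key=tuple(label.encode()))
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def load_reference(h_dist: str) -> tuple[ModelParameters, Morphology, list[SynapseSite]]:
    rank = REFERENCE_HSD_RANK if h_dist == "HSD" else REFERENCE_HS_RANK
    params = load_model_parameters(rank, h_dist)
    morph = standard_morphology(params.cell, seed=params.cell)
    sites = place_synapse_sites(morph, "every_fourth_segment")
    return params, morph, sites


def calibrate_reference(
    h_dist: str, master_seed: int, op: OperatingPoint | None = None
) -> tuple[ModelParameters, Morphology, list[SynapseSite], CalibrationResult]:
    params, morph, sites = load_reference(h_dist)
    op = op or OperatingPoint()
    cal = calibrate_baseline(morph, params, sites, op, base_seed=master_seed)
    return params, morph, sites, cal


def modulated_summaries(
    params: ModelParameters,
    morph: Morphology,
    sites: list[SynapseSite],
    cal: CalibrationResult,
    f_mod: float,
    seeds,
    duration_ms: float = 10_000.0,
    dt: float = 0.025,
) -> list[ResonanceSummary]:
    """One resonance summary per seed for f_mod-modulated inhibitory drive."""
    out = []
    for seed in seeds:
        mod = ModulationSpec(frequency=f_mod, duration=duration_ms)
        drv = build_drive(sites, cal.g_exc, cal.g_inh, mod, int(seed),
                          duration_ms=duration_ms)
        cfg = SimulationConfig(dt=dt, duration=duration_ms)
        trace = simulate(morph, params, drv, None, cfg)
        spikes = detect_spikes(trace)
        if spikes.n == 0:
            continue
        out.append(summarize(spikes.spike_times, duration_ms, drv.release_times, f_mod))
    return out
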