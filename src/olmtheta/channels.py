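"""Hodgkin–Huxley channel kinetics and the 32 reference parameter sets.

The model database this work builds on prescribes, for every model variant,
the maximum conductance densities of nine voltage-gated currents plus
re-fitted passive properties; those printed values ship with the package as
``data/model_parameters.csv`` and are loaded by rank.  The kinetic equations
themselves are not part of that table, so the package carries a fully
parameterized "reference O-LM channel set": Boltzmann steady states and
bell/sigmoid voltage-dependent time constants, every parameter overridable.
The H (HCN) activation gate is anchored at its printed control half-activation
of −84 mV; cAMP modulation is a +5 mV depolarizing shift of that value.

Sign conventions
----------------
``x_inf(V) = 1 / (1 + exp((V - v_half)/slope))`` — a *negative* slope gives a
gate that opens with depolarization (activation), a positive slope one that
opens with hyperpolarization (H activation, inactivation gates).
Current is ohmic, positive outward: ``I = gbar * area * open * (V - e_rev)``.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "TauSpec",
    "GateSpec",
    "ChannelSpec",
    "ModelParameters",
    "load_model_parameters",
    "available_ranks",
    "gate_inf",
    "gate_tau",
    "channel_current",
    "apply_camp_shift",
    "apply_block",
    "fit_h_leak",
    "reference_channel_set",
    "REGIONS",
    "CHANNEL_NAMES",
]

REGIONS = ("soma", "dendrite", "axon")
CHANNEL_NAMES = ("Nas", "Nad", "Kdrf", "Kdrs", "KA", "CaT", "CaL", "AHP", "H", "M", "Hleak")

# default reversal potentials (mV); config-overridable
E_NA = 50.0
E_K = -90.0
E_CA = 120.0
E_H = -20.0
E_LEAK = -68.0


@dataclass(frozen=True)
class TauSpec:
    """Voltage-dependent time constant (ms):

    ``tau(V) = tau_min + tau_amp / (exp((V - v1)/k1) + exp(-(V - v2)/k2))``

    With both exponentials active this is bell-shaped; sending one ``k`` to a
    large value flattens that wing, giving a sigmoid.  ``tau_min > 0`` keeps
    tau positive over the physiological range.
    """

    tau_min: float
    tau_amp: float
    v1: float
    k1: float
    v2: float
    k2: float

    def __call__(self, v: float | np.ndarray) -> float | np.ndarray:
        return self.tau_min + self.tau_amp / (
            np.exp((v - self.v1) / self.k1) + np.exp(-(v - self.v2) / self.k2)
        )


@dataclass(frozen=True)
class GateSpec:
    """One gating variable: Boltzmann steady state and its time constant."""

    v_half: float  # mV
    slope: float  # mV, signed (see module docstring)
    tau: TauSpec
    exponent: int = 1
    ca_dependent: bool = False  # AHP proxy gate: steady state driven by the Ca pool

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("gate slope must be nonzero")
        if self.exponent < 1:
            raise ValueError("gate exponent must be a positive integer")


def gate_inf(v: float | np.ndarray, gate: GateSpec) -> float | np.ndarray:
    """Steady-state open fraction of a gate at voltage ``v`` (mV)."""
    return 1.0 / (1.0 + np.exp((v - gate.v_half) / gate.slope))


def gate_tau(v: float | np.ndarray, gate: GateSpec) -> float | np.ndarray:
    """Time constant of a gate at voltage ``v`` (ms)."""
    return gate.tau(v)


@dataclass(frozen=True)
class ChannelSpec:
    name: str
    gates: tuple[GateSpec, ...]
    e_rev: float  # mV

    def open_fraction(self, state) -> float:
        out = 1.0
        for g, x in zip(self.gates, state):
            out *= x ** g.exponent
        return out


def channel_current(
    v: float, state, spec: ChannelSpec, gbar: float, area: float
) -> float:
    """Ohmic channel current in pA (positive outward).

    ``gbar`` in pS/µm², ``area`` in µm²; pS·mV = 1e-3 pA.
    """
    for x in state:
        if not 0.0 <= x <= 1.0:
            raise ValueError("gate values must lie in [0, 1]")
    g_ps = gbar * area * spec.open_fraction(state)
    return 1e-3 * g_ps * (v - spec.e_rev)


# ---------------------------------------------------------------------------
# reference channel set
# ---------------------------------------------------------------------------


def _sigmoid_tau(tau_min, tau_amp, v_mid, k, rising=True) -> TauSpec:
    # one wing carries the sigmoid; the other is pushed flat
    if rising:  # tau grows with depolarization
        return TauSpec(tau_min, tau_amp, v_mid, -k, v_mid, 1e6)
    return TauSpec(tau_min, tau_amp, v_mid, k, v_mid, 1e6)


def reference_channel_set() -> dict[str, ChannelSpec]:
    """The package's default O-LM channel kinetics.

    Transient Na and the fast delayed rectifier give the spike itself
    (somatic Nas, dendritic Nad share kinetics); Kdrs is a slow,
    incompletely-deactivating K current that builds a long post-spike
    hyperpolarized shoulder; KA a transient A-type current; CaT/CaL carry the
    Ca influx that drives the first-order Ca-pool AHP proxy; H is the
    hyperpolarization-activated inward current with its printed −84 mV
    half-activation and a slow sigmoidal tau (~100–700 ms between −120 and
    −60 mV); M a small slow K current.  All numbers here are package design
    choices, exposed so published kinetics can be dropped in.
    """
    na_gates = (
        GateSpec(-48.0, -5.5, TauSpec(0.05, 0.4, -40.0, 12.0, -40.0, 12.0), exponent=3),
        GateSpec(-60.0, 7.0, TauSpec(0.5, 10.0, -55.0, 12.0, -62.0, 12.0), exponent=1),
    )
    chans = {
        "Nas": ChannelSpec("Nas", na_gates, E_NA),
        "Nad": ChannelSpec("Nad", na_gates, E_NA),
        "Kdrf": ChannelSpec(
            "Kdrf",
            (GateSpec(-34.0, -9.0, TauSpec(0.6, 5.0, -32.0, 18.0, -32.0, 18.0), exponent=4),),
            E_K,
        ),
        "Kdrs": ChannelSpec(
            "Kdrs",
            (GateSpec(-35.0, -6.5, _sigmoid_tau(6.0, 190.0, -50.0, 12.0, rising=False), exponent=2),),
            E_K,
        ),
        "KA": ChannelSpec(
            "KA",
            (
                GateSpec(-52.0, -5.5, TauSpec(0.8, 4.0, -40.0, 20.0, -40.0, 20.0), exponent=1),
                GateSpec(-74.0, 6.0, _sigmoid_tau(12.0, 55.0, -65.0, 12.0, rising=True), exponent=1),
            ),
            E_K,
        ),
        "CaT": ChannelSpec(
            "CaT",
            (
                GateSpec(-52.0, -5.5, TauSpec(10.0, 60.0, -60.0, 10.0, -60.0, 10.0), exponent=2),
                GateSpec(-70.0, 5.0, _sigmoid_tau(20.0, 80.0, -65.0, 10.0, rising=True), exponent=1),
            ),
            E_CA,
        ),
        "CaL": ChannelSpec(
            "CaL",
            (GateSpec(-25.0, -6.0, TauSpec(1.0, 2.5, -25.0, 15.0, -25.0, 15.0), exponent=2),),
            E_CA,
        ),
        # AHP: Ca-pool-driven first-order gate; v_half/slope unused for the
        # steady state (the simulator substitutes ca/(ca + kd)), tau fixed.
        "AHP": ChannelSpec(
            "AHP",
            (GateSpec(0.0, -1.0, TauSpec(40.0, 0.0, 0.0, 1e6, 0.0, 1e6), exponent=1, ca_dependent=True),),
            E_K,
        ),
        "H": ChannelSpec(
            "H",
            (GateSpec(-84.0, 10.2, _sigmoid_tau(50.0, 650.0, -55.0, 4.0, rising=True), exponent=1),),
            E_H,
        ),
        "M": ChannelSpec(
            "M",
            (GateSpec(-27.0, -7.0, _sigmoid_tau(30.0, 70.0, -40.0, 10.0, rising=True), exponent=1),),
            E_K,
        ),
        "Hleak": ChannelSpec("Hleak", (), E_H),
    }
    return chans


# ---------------------------------------------------------------------------
# model parameter sets
# ---------------------------------------------------------------------------


@dataclass
class ModelParameters:
    """The full biophysical identity of one O-LM model variant.

    ``densities`` maps channel name -> {region: pS/µm²}.  ``i_bias`` (pA) is
    the holding current of the parameter table; it is stored for completeness
    but never injected in high-conductance simulations.
    """

    rank: int
    cell: int
    h_dist: str  # "HS" (somatic H) or "HSD" (somatodendritic H)
    densities: dict[str, dict[str, float]]
    r_m: float  # Ω·cm²
    c_m: float  # µF/cm²
    i_bias: float  # pA
    r_a: float = 300.0  # Ω·cm, axial resistivity (not printed; default)
    e_leak: float = E_LEAK
    channels: dict[str, ChannelSpec] = field(default_factory=reference_channel_set)

    def density(self, channel: str, region: str) -> float:
        return self.densities.get(channel, {}).get(region, 0.0)

    def copy(self) -> "ModelParameters":
        return replace(
            self,
            densities=copy.deepcopy(self.densities),
            channels=dict(self.channels),
        )


def _table() -> pd.DataFrame:
    with resources.files("olmtheta.data").joinpath("model_parameters.csv").open() as fh:
        return pd.read_csv(fh)


def available_ranks(h_dist: str | None = None) -> list[int]:
    t = _table()
    if h_dist is not None:
        t = t[t.h_dist == h_dist]
    return t["rank"].tolist()


def load_model_parameters(rank: int, h_dist: str) -> ModelParameters:
    """Load one printed parameter row (by rank and H distribution).

    Region assignment: Nas is somatic, Nad dendritic; H is somatic for HS
    rows and uniform somatodendritic for HSD rows; every other channel is
    uniform over soma and dendrites.  The truncated axon is passive.
    """
    if h_dist not in ("HS", "HSD"):
        raise ValueError("h_dist must be 'HS' or 'HSD'")
    t = _table()
    row = t[(t["rank"] == rank) & (t.h_dist == h_dist)]
    if row.empty:
        valid = t[t.h_dist == h_dist]["rank"].tolist()
        raise KeyError(
            f"no model with rank {rank} and h_dist {h_dist}; valid ranks: {valid}"
        )
    r = row.iloc[0]
    densities: dict[str, dict[str, float]] = {
        "Nas": {"soma": float(r.Nas)},
        "Nad": {"dendrite": float(r.Nad)},
    }
    for ch in ("Kdrf", "Kdrs", "KA", "CaT", "CaL", "AHP", "M"):
        densities[ch] = {"soma": float(r[ch]), "dendrite": float(r[ch])}
    if h_dist == "HS":
        densities["H"] = {"soma": float(r.H)}
    else:
        densities["H"] = {"soma": float(r.H), "dendrite": float(r.H)}
    return ModelParameters(
        rank=int(r["rank"]),
        cell=int(r.cell),
        h_dist=h_dist,
        densities=densities,
        r_m=float(r.Rm),
        c_m=float(r.Cm),
        i_bias=float(r.Ibias),
    )


# ---------------------------------------------------------------------------
# manipulations
# ---------------------------------------------------------------------------


def apply_camp_shift(spec: ChannelSpec, delta: float = 5.0) -> ChannelSpec:
    """Depolarizing shift of the H activation half-voltage (cAMP modulation)."""
    if spec.name != "H":
        raise ValueError("cAMP modulation applies to the H channel only")
    shifted = tuple(replace(g, v_half=g.v_half + delta) for g in spec.gates)
    return replace(spec, gates=shifted)


def apply_block(params: ModelParameters, channels) -> ModelParameters:
    """Zero the densities of the given channels (⊆ {H, Kdrs, KA}) everywhere."""
    channels = set(channels)
    allowed = {"H", "Kdrs", "KA"}
    if not channels <= allowed:
        raise ValueError(f"blockable channels are {sorted(allowed)}")
    out = params.copy()
    for ch in channels:
        out.densities[ch] = {k: 0.0 for k in out.densities.get(ch, {})}
    return out


def fit_h_leak(params: ModelParameters, mean_subthreshold_vm: float) -> float:
    """Initial H-leak density: gbar_H scaled by H activation at the mean Vm.

    The H-leak control replaces the voltage-gated H current with an ohmic
    conductance of the same reversal; this returns the *starting* density,
    which the calibration layer may subsequently reduce to restore the
    baseline firing rate.
    """
    if not -120.0 <= mean_subthreshold_vm <= 0.0:
        raise ValueError("mean subthreshold Vm outside the physiological range")
    dens = params.densities.get("H", {})
    gbar = max(dens.values()) if dens else 0.0
    if gbar <= 0:
        raise ValueError("model has no H conductance to convert to a leak")
    h_gate = params.channels["H"].gates[0]
    return float(gbar * gate_inf(mean_subthreshold_vm, h_gate))


def with_h_leak(params: ModelParameters, density: float) -> ModelParameters:
    """Return a copy with H blocked and an Hleak of the given density inserted
    in the regions H originally occupied."""
    regions = list(params.densities.get("H", {}))
    out = apply_block(params, {"H"})
    out.densities["Hleak"] = {reg: density for reg in regions}
    return out


def with_camp(params: ModelParameters, delta: float = 5.0) -> ModelParameters:
    """Return a copy whose H channel spec has the cAMP V1/2 shift applied."""
    out = params.copy()
    out.channels = dict(out.channels)
    out.channels["H"] = apply_camp_shift(out.channels["H"], delta)
    return out
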