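"""High-conductance-state synaptic bombardment.

Each synapse site carries one excitatory (500 Hz) and one inhibitory
(1000 Hz) Poisson event stream, statistically independent across sites and
classes.  Conductances are double exponentials (tau_rise 0.5 ms, tau_decay
6.8 ms for both classes, matching GABA_A/kainate-like kinetics) normalized so
the single-event peak equals ``g_peak``.  Theta-band modulation switches the
inhibitory rate square-wave fashion by ±``depth`` around its base: the first
half of each cycle is the high-rate "peak" of inhibition, the second half the
"trough"; the peak→trough transitions ("release from peak inhibition") define
phase 0 for all spike-phase statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphology import SynapseSite

__all__ = [
    "SynapseKinetics",
    "ModulationSpec",
    "SynapticDrive",
    "EXC_RATE_HZ",
    "INH_RATE_HZ",
    "DEFAULT_KINETICS",
    "generate_poisson_events",
    "generate_modulated_events",
    "conductance_waveform",
    "build_drive",
    "MODULATION_FREQUENCIES_HZ",
]

EXC_RATE_HZ = 500.0
INH_RATE_HZ = 1000.0

#: The modulation frequency sweep (Hz), denser through theta (4–12 Hz).
MODULATION_FREQUENCIES_HZ = (
    0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 8.0, 9.0, 10.0, 12.0, 15.0, 16.0, 20.0, 25.0, 30.0,
)


@dataclass(frozen=True)
class SynapseKinetics:
    tau_rise: float = 0.5  # ms
    tau_decay: float = 6.8  # ms
    e_rev: float = 0.0  # mV
    g_peak: float = 0.001  # nS

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("require 0 < tau_rise < tau_decay")
        if self.g_peak < 0:
            raise ValueError("g_peak must be nonnegative")

    @property
    def t_peak(self) -> float:
        """Time of the waveform maximum (ms)."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * np.log(td / tr)

    @property
    def norm(self) -> float:
        """Value of ``exp(-t/tau_d) - exp(-t/tau_r)`` at its maximum."""
        tp = self.t_peak
        return float(np.exp(-tp / self.tau_decay) - np.exp(-tp / self.tau_rise))


DEFAULT_KINETICS = {
    "exc": SynapseKinetics(e_rev=0.0),
    "inh": SynapseKinetics(e_rev=-80.0),
}


def conductance_waveform(t_since_event, kin: SynapseKinetics):
    """Single-event conductance g(t) in nS for t >= 0 (0 for t < 0)."""
    t = np.asarray(t_since_event, dtype=float)
    g = kin.g_peak * (np.exp(-t / kin.tau_decay) - np.exp(-t / kin.tau_rise)) / kin.norm
    return np.where(t >= 0, g, 0.0)


@dataclass(frozen=True)
class ModulationSpec:
    """Square-wave modulation of the inhibitory rate."""

    frequency: float  # Hz
    base_rate: float = INH_RATE_HZ
    depth: float = 0.4
    duration: float = 10_000.0  # ms

    def __post_init__(self) -> None:
        if not 0 <= self.depth < 1:
            raise ValueError("depth must lie in [0, 1)")
        if not 0 < self.frequency <= 30.0:
            raise ValueError("modulation frequency must lie in (0, 30] Hz")

    @property
    def period(self) -> float:
        """Cycle period T in ms."""
        return 1000.0 / self.frequency

    def release_times(self) -> np.ndarray:
        """Peak→trough transition times (ms): T/2, 3T/2, ... within duration."""
        t = np.arange(self.period / 2.0, self.duration, self.period)
        return t


def generate_poisson_events(rate_hz: float, duration_ms: float, seed) -> np.ndarray:
    """Homogeneous Poisson event times (ms), sorted, deterministic per seed."""
    if rate_hz < 0:
        raise ValueError("rate must be nonnegative")
    if rate_hz == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    rate_per_ms = rate_hz / 1000.0
    # draw a safe surplus of exponential gaps, extend in the rare shortfall
    n_guess = int(rate_per_ms * duration_ms * 1.2 + 10 * np.sqrt(rate_per_ms * duration_ms + 1))
    gaps = rng.exponential(1.0 / rate_per_ms, size=n_guess)
    times = np.cumsum(gaps)
    while times.size and times[-1] < duration_ms:
        extra = rng.exponential(1.0 / rate_per_ms, size=max(16, n_guess // 4))
        times = np.concatenate([times, times[-1] + np.cumsum(extra)])
    return times[times < duration_ms]


def generate_modulated_events(spec: ModulationSpec, seed) -> tuple[np.ndarray, np.ndarray]:
    """Square-wave-modulated Poisson events and the release times.

    The first half of each cycle runs at ``base*(1+depth)`` (peak of
    inhibition), the second half at ``base*(1-depth)`` (trough); cycle phase 0
    is t = 0.  Implemented by thinning a homogeneous process at the peak rate,
    which keeps the event stream exactly piecewise-Poisson.
    """
    rng = np.random.default_rng(seed)
    hi = spec.base_rate * (1.0 + spec.depth)
    lo = spec.base_rate * (1.0 - spec.depth)
    base = generate_poisson_events(hi, spec.duration, rng)
    if hi > 0:
        phase = np.mod(base, spec.period) / spec.period
        in_peak = phase < 0.5
        keep = in_peak | (rng.random(base.size) < lo / hi)
        events = base[keep]
    else:
        events = base
    return events, spec.release_times()


@dataclass
class SynapticDrive:
    """Per-site excitatory/inhibitory event trains plus kinetics and phase refs."""

    sites: list[SynapseSite]
    exc_events: list[np.ndarray]
    inh_events: list[np.ndarray]
    kinetics: dict[str, SynapseKinetics]
    modulation: ModulationSpec | None = None
    release_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not (len(self.sites) == len(self.exc_events) == len(self.inh_events)):
            raise ValueError("per-site event lists must match the site list")


def _substream_seed(master_seed: int, site_index: int, klass: int) -> np.random.SeedSequence:
    # counter-style derivation: one master entropy, per-(site, class) spawn key
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(site_index, klass))


def build_drive(
    sites: list[SynapseSite],
    g_exc: float,
    g_inh: float,
    modulation: ModulationSpec | None,
    master_seed: int,
    duration_ms: float | None = None,
    exc_rate_hz: float = EXC_RATE_HZ,
    inh_rate_hz: float = INH_RATE_HZ,
) -> SynapticDrive:
    """Independent excitatory + inhibitory streams for every site.

    Seeds are derived deterministically from ``master_seed`` and the site
    index (class 0 = excitatory, 1 = inhibitory), so the full drive is
    reproducible bit-exactly while streams stay independent.
    """
    if not sites:
        raise ValueError("no synapse sites")
    if duration_ms is None:
        duration_ms = modulation.duration if modulation is not None else 10_000.0
    exc_events, inh_events = [], []
    release = np.empty(0)
    for i in range(len(sites)):
        exc_events.append(
            generate_poisson_events(exc_rate_hz, duration_ms, _substream_seed(master_seed, i, 0))
        )
        if modulation is None:
            inh_events.append(
                generate_poisson_events(inh_rate_hz, duration_ms, _substream_seed(master_seed, i, 1))
            )
        else:
            spec = ModulationSpec(
                frequency=modulation.frequency,
                base_rate=inh_rate_hz,
                depth=modulation.depth,
                duration=duration_ms,
            )
            ev, release = generate_modulated_events(spec, _substream_seed(master_seed, i, 1))
            inh_events.append(ev)
    kin = {
        "exc": SynapseKinetics(e_rev=DEFAULT_KINETICS["exc"].e_rev, g_peak=g_exc),
        "inh": SynapseKinetics(e_rev=DEFAULT_KINETICS["inh"].e_rev, g_peak=g_inh),
    }
    return SynapticDrive(
        sites=list(sites),
        exc_events=exc_events,
        inh_events=inh_events,
        kinetics=kin,
        modulation=modulation,
        release_times=release,
    )
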