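"""Spiking-output measures: power ratio, rotation number, vector strength.

All three operate on somatic spike times against the square-wave modulation
schedule.  The power ratio is spectral: the spike train is binned into a
1 ms binary sequence, a Welch PSD is taken *without* mean subtraction, and
the value at the grid frequency nearest the modulation frequency is divided
by the DC (0 Hz) value.  The rotation number is the average number of spikes
per complete input cycle.  Vector strength is the circular resultant length
of spike phases measured from the most recent release-from-peak-inhibition
event; phase 0° is that release.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "BinnedTrain",
    "PhaseSet",
    "ResonanceSummary",
    "bin_spike_train",
    "power_ratio",
    "rotation_number",
    "spike_phases",
    "vector_strength",
    "phase_histogram",
    "summarize",
]

VS_PHASE_THRESHOLD = 0.6  # below this, a mean phase is not reported


@dataclass
class BinnedTrain:
    bins: np.ndarray  # binary
    bin_width: float  # ms
    collisions: int = 0  # spikes sharing a bin with an earlier spike

    @property
    def fs(self) -> float:
        """Sampling rate of the binary sequence in Hz."""
        return 1000.0 / self.bin_width


@dataclass
class PhaseSet:
    phases: np.ndarray  # radians in [0, 2π)
    period: float  # ms
    n_dropped: int = 0  # spikes preceding the first release event

    @property
    def n(self) -> int:
        return int(self.phases.size)


@dataclass
class ResonanceSummary:
    f_mod: float
    power_ratio: float
    rotation_number: float
    vector_strength: float
    mean_phase_deg: float | None  # None when VS < threshold
    n_spikes: int


def bin_spike_train(spike_times, duration_ms: float, bin_width: float = 1.0) -> BinnedTrain:
    """Binary train: bin b is 1 iff at least one spike falls in [b·w, (b+1)·w)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    spikes = np.asarray(spike_times, dtype=float)
    n_bins = int(np.ceil(duration_ms / bin_width))
    bins = np.zeros(n_bins)
    idx = np.floor(spikes / bin_width).astype(int)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    uniq = np.unique(idx)
    bins[uniq] = 1.0
    return BinnedTrain(bins=bins, bin_width=bin_width, collisions=int(idx.size - uniq.size))


def power_ratio(binned: BinnedTrain, f_mod: float, nperseg: int = 2 ** 14) -> float:
    """PSD at the modulation frequency over PSD at 0 Hz (Welch, DC retained)."""
    fs = binned.fs
    if not 0 < f_mod < fs / 2:
        raise ValueError("f_mod must lie below the Nyquist frequency")
    if not binned.bins.any():
        raise ValueError("empty spike train: PSD(0) is zero, power ratio undefined")
    nps = min(nperseg, binned.bins.size)
    # two-sided spectrum: no one-sided doubling, so a perfectly locked
    # periodic train carries equal mass at 0 Hz and f_mod (ratio 1)
    freqs, psd = signal.welch(
        binned.bins,
        fs=fs,
        window="hann",
        nperseg=nps,
        noverlap=nps // 2,
        detrend=False,
        return_onesided=False,
    )
    pos = freqs >= 0
    freqs, psd = freqs[pos], psd[pos]
    i = int(np.argmin(np.abs(freqs - f_mod)))
    return float(psd[i] / psd[0])


def rotation_number(spike_times, duration_ms: float, f_mod: float) -> float:
    """Average spikes per complete input cycle."""
    period = 1000.0 / f_mod
    n_cycles = int(np.floor(duration_ms / period))
    if n_cycles < 1:
        raise ValueError("fewer than one complete modulation cycle")
    spikes = np.asarray(spike_times, dtype=float)
    return float(np.sum(spikes < n_cycles * period) / n_cycles)


def spike_phases(spike_times, release_times, period: float) -> PhaseSet:
    """Phases of spikes relative to the most recent release event.

    θ_i = 2π (t_diff mod T) / T where t_diff is the time since the most
    recent release; spikes before the first release have no defined t_diff
    and are dropped (their count is reported).
    """
    spikes = np.asarray(spike_times, dtype=float)
    release = np.sort(np.asarray(release_times, dtype=float))
    if release.size == 0:
        raise ValueError("no release events")
    k = np.searchsorted(release, spikes, side="right") - 1
    valid = k >= 0
    tdiff = spikes[valid] - release[k[valid]]
    phases = 2.0 * np.pi * np.mod(tdiff, period) / period
    return PhaseSet(phases=phases, period=period, n_dropped=int(np.sum(~valid)))


def vector_strength(phases: PhaseSet) -> tuple[float, float]:
    """(VS, mean phase in degrees).

    VS = sqrt((Σcosθ)² + (Σsinθ)²) / N; 1 means perfectly synchronized
    spikes.  The mean phase is atan2 of the resultant, mapped to [0, 360).
    """
    if phases.n == 0:
        raise ValueError("vector strength undefined for zero spikes")
    c = float(np.sum(np.cos(phases.phases)))
    s = float(np.sum(np.sin(phases.phases)))
    vs = np.sqrt(c * c + s * s) / phases.n
    mean_deg = float(np.degrees(np.arctan2(s, c)) % 360.0)
    return float(vs), mean_deg


def phase_histogram(phases: PhaseSet, n_bins: int = 18) -> tuple[np.ndarray, np.ndarray]:
    """(counts, bin edges in degrees) over uniform bins of [0°, 360°)."""
    if n_bins < 2:
        raise ValueError("need at least two bins")
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(np.degrees(phases.phases), bins=edges)
    return counts, edges


def summarize(spike_times, duration_ms: float, release_times, f_mod: float,
              bin_width: float = 1.0) -> ResonanceSummary:
    """Bundle the three measures for one simulation.

    The mean phase is reported only when VS ≥ 0.6 — with poor
    synchronization a circular mean is not informative.
    """
    spikes = np.asarray(spike_times, dtype=float)
    if spikes.size == 0:
        raise ValueError("no spikes: resonance summary undefined")
    period = 1000.0 / f_mod
    binned = bin_spike_train(spikes, duration_ms, bin_width)
    pr = power_ratio(binned, f_mod)
    rot = rotation_number(spikes, duration_ms, f_mod)
    ph = spike_phases(spikes, release_times, period)
    vs, mean_deg = vector_strength(ph)
    return ResonanceSummary(
        f_mod=f_mod,
        power_ratio=pr,
        rotation_number=rot,
        vector_strength=vs,
        mean_phase_deg=mean_deg if vs >= VS_PHASE_THRESHOLD else None,
        n_spikes=int(spikes.size),
    )
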