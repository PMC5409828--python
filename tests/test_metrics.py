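import numpy as np
import pytest

from olmtheta.metrics import (
    PhaseSet,
    bin_spike_train,
    phase_histogram,
    power_ratio,
    rotation_number,
    spike_phases,
    summarize,
    vector_strength,
)


def locked_train(f_mod=8.0, duration=20_000.0, offset=30.0):
    """One spike at a fixed offset after every release; returns (spikes, releases, T)."""
    T = 1000.0 / f_mod
    releases = np.arange(T / 2, duration, T)
    spikes = releases + offset
    return spikes[spikes < duration], releases, T


class TestBinning:
    def test_empty_train_all_zeros(self):
        b = bin_spike_train([], 1000.0)
        assert b.bins.sum() == 0

    def test_known_bin_placement(self):
        b = bin_spike_train([0.5, 10.2], 20.0, bin_width=1.0)
        assert b.bins[0] == 1 and b.bins[10] == 1
        assert b.bins.sum() == 2

    def test_collision_logged(self):
        b = bin_spike_train([5.1, 5.9], 10.0, bin_width=1.0)
        assert b.bins.sum() == 1
        assert b.collisions == 1


class TestPowerRatio:
    def test_periodic_locked_train_ratio_near_one(self):
        spikes, _, _ = locked_train(8.0, 20_000.0)
        b = bin_spike_train(spikes, 20_000.0)
        assert power_ratio(b, 8.0) == pytest.approx(1.0, rel=0.05)

    def test_periodic_matches_direct_dft_oracle(self):
        spikes, _, _ = locked_train(8.0, 16_384.0)
        b = bin_spike_train(spikes, 16_384.0)
        # direct periodogram (rectangular window) as an independent oracle
        x = b.bins
        X = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(x.size, d=1e-3)
        k = int(np.argmin(np.abs(freqs - 8.0)))
        direct = np.abs(X[k]) ** 2 / np.abs(X[0]) ** 2
        assert power_ratio(b, 8.0) == pytest.approx(direct, rel=0.1)

    def test_poisson_train_ratio_below_0p3(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            spikes = np.sort(rng.uniform(0, 20_000.0, size=50))  # ~2.5 Hz
            b = bin_spike_train(spikes, 20_000.0)
            for f in (3.0, 8.0):
                assert power_ratio(b, f) < 0.3

    def test_jitter_monotonically_degrades_ratio(self):
        ratios = []
        for sd in (0.0, 8.0, 30.0):
            vals = []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                spikes, _, _ = locked_train(8.0, 20_000.0)
                jittered = np.sort(spikes + rng.normal(0, sd, spikes.size))
                jittered = jittered[(jittered >= 0) & (jittered < 20_000.0)]
                vals.append(power_ratio(bin_spike_train(jittered, 20_000.0), 8.0))
            ratios.append(np.mean(vals))
        assert ratios[0] > ratios[1] > ratios[2]

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            power_ratio(bin_spike_train([], 1000.0), 8.0)


class TestRotationNumber:
    @pytest.mark.parametrize(
        "n_spikes,duration,f,expected",
        [(10, 10_000.0, 1.0, 1.0), (0, 5000.0, 4.0, 0.0), (20, 2000.0, 4.0, 2.5)],
    )
    def test_arithmetic(self, n_spikes, duration, f, expected):
        spikes = np.linspace(1.0, duration - 1.0, n_spikes) if n_spikes else []
        assert rotation_number(spikes, duration, f) == pytest.approx(expected)

    def test_invariant_to_within_cycle_timing(self, rng):
        T = 250.0
        base = np.arange(10) * T
        a = rotation_number(base + 10.0, 2500.0, 4.0)
        b = rotation_number(base + rng.uniform(0, T, 10), 2500.0, 4.0)
        assert a == b

    def test_zero_complete_cycles_rejected(self):
        with pytest.raises(ValueError):
            rotation_number([10.0], 100.0, 1.0)  # period 1000 ms > duration


class TestVectorStrength:
    def test_perfectly_synchronized_is_one(self):
        spikes, releases, T = locked_train(8.0)
        vs, _ = vector_strength(spike_phases(spikes, releases, T))
        assert vs == pytest.approx(1.0, abs=1e-12)

    def test_four_symmetric_phases_cancel(self):
        ph = PhaseSet(phases=np.deg2rad([0.0, 90.0, 180.0, 270.0]), period=125.0)
        vs, _ = vector_strength(ph)
        assert vs == pytest.approx(0.0, abs=1e-12)

    def test_two_spikes_at_0_and_90_degrees(self):
        ph = PhaseSet(phases=np.deg2rad([0.0, 90.0]), period=125.0)
        vs, mean_deg = vector_strength(ph)
        assert vs == pytest.approx(np.sqrt(2) / 2, rel=1e-12)
        assert mean_deg == pytest.approx(45.0)

    def test_time_shift_by_whole_periods_invariant(self):
        spikes, releases, T = locked_train(4.0, 10_000.0, offset=40.0)
        vs1, m1 = vector_strength(spike_phases(spikes, releases, T))
        shifted = spikes[:-8] + 2 * T  # still inside the release schedule
        vs2, m2 = vector_strength(spike_phases(shifted, releases, T))
        assert vs2 == pytest.approx(vs1, abs=1e-9)
        assert m2 == pytest.approx(m1, abs=1e-6)

    def test_uniform_phase_null_scaling(self, rng):
        # E[VS] under uniform phases ~ sqrt(pi)/(2 sqrt(N))
        n = 1000
        vals = []
        for _ in range(40):
            ph = PhaseSet(phases=rng.uniform(0, 2 * np.pi, n), period=125.0)
            vals.append(vector_strength(ph)[0])
        expected = np.sqrt(np.pi) / (2 * np.sqrt(n))
        assert np.mean(vals) == pytest.approx(expected, rel=0.2)

    def test_spikes_before_first_release_dropped_and_counted(self):
        releases = np.array([100.0, 200.0])
        ph = spike_phases([50.0, 150.0, 250.0], releases, 100.0)
        assert ph.n == 2
        assert ph.n_dropped == 1

    def test_empty_phase_set_rejected(self):
        with pytest.raises(ValueError):
            vector_strength(PhaseSet(phases=np.empty(0), period=100.0))


class TestPhaseHistogram:
    def test_single_phase_single_bin(self):
        ph = PhaseSet(phases=np.full(10, np.deg2rad(45.0)), period=125.0)
        counts, _ = phase_histogram(ph, 8)
        assert counts.sum() == 10
        assert np.count_nonzero(counts) == 1

    def test_counts_conserved_under_refinement(self, rng):
        ph = PhaseSet(phases=rng.uniform(0, 2 * np.pi, 500), period=125.0)
        for nb in (6, 12, 24):
            counts, _ = phase_histogram(ph, nb)
            assert counts.sum() == 500

    def test_uniform_phases_roughly_flat(self, rng):
        ph = PhaseSet(phases=rng.uniform(0, 2 * np.pi, 20_000), period=125.0)
        counts, _ = phase_histogram(ph, 8)
        assert counts.max() / counts.min() < 1.5


class TestSummarize:
    def test_locked_train_composition(self):
        spikes, releases, _ = locked_train(8.0, 20_000.0)
        s = summarize(spikes, 20_000.0, releases, 8.0)
        assert s.power_ratio == pytest.approx(1.0, rel=0.05)
        assert s.rotation_number == pytest.approx(1.0, rel=0.01)
        assert s.vector_strength == pytest.approx(1.0, abs=1e-9)
        assert s.mean_phase_deg is not None

    def test_poisson_train_phase_flagged_absent(self, rng):
        releases = np.arange(62.5, 20_000.0, 125.0)
        flagged = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            spikes = np.sort(r.uniform(0, 20_000.0, 60))
            s = summarize(spikes, 20_000.0, releases, 8.0)
            flagged += s.mean_phase_deg is None
        assert flagged == 10  # VS null ~ 1/sqrt(60) << 0.6

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            summarize([], 1000.0, [62.5], 8.0)
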