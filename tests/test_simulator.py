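import numpy as np
import pytest

from olmtheta.channels import ModelParameters, load_model_parameters
from olmtheta.drive import build_drive
from olmtheta.morphology import Morphology, Section, place_synapse_sites, standard_morphology
from olmtheta.simulator import (
    SimulationConfig,
    SpikeTrain,
    VoltageTrace,
    detect_spikes,
    input_resistance,
    post_spike_trajectory,
    simulate,
    subthreshold_stats,
)


class TestPassiveAnalytics:
    def test_no_input_rests_at_leak_reversal(self, passive_sphere):
        morph, params = passive_sphere
        cfg = SimulationConfig(duration=500.0, v_init=params.e_leak)
        trace = simulate(morph, params, None, None, cfg)
        assert np.allclose(trace.vm, params.e_leak, atol=1e-9)

    def test_minus_25pA_step_gives_minus_15mV(self, passive_sphere):
        # R_in = R_m/A = 600 MOhm, so -25 pA -> -15 mV
        morph, params = passive_sphere
        cfg = SimulationConfig(duration=1500.0, v_init=params.e_leak)
        trace = simulate(morph, params, None, (-25.0, 500.0, 1500.0), cfg)
        dv = trace.vm[-1] - params.e_leak
        assert dv == pytest.approx(-15.0, rel=0.02)

    def test_input_resistance_600_mohm(self, passive_sphere):
        morph, params = passive_sphere
        rin = input_resistance(morph, params, None, i_step=-25.0,
                               settle=1000.0, step_dur=1500.0)
        assert rin == pytest.approx(600.0, rel=0.02)

    def test_halving_rm_halves_rin(self, passive_sphere):
        morph, params = passive_sphere
        rin1 = input_resistance(morph, params, None, settle=800.0, step_dur=1200.0)
        params2 = ModelParameters(
            rank=0, cell=1, h_dist="HS", densities={},
            r_m=params.r_m / 2, c_m=params.c_m, i_bias=0.0,
        )
        rin2 = input_resistance(morph, params2, None, settle=800.0, step_dur=1200.0)
        assert rin2 == pytest.approx(rin1 / 2, rel=0.02)

    def test_membrane_time_constant_rm_cm(self, passive_sphere):
        # tau = R_m * C_m = 60 ms, from an exponential fit to the step response
        morph, params = passive_sphere
        cfg = SimulationConfig(duration=1200.0, v_init=params.e_leak)
        trace = simulate(morph, params, None, (-25.0, 200.0, 1200.0), cfg)
        i0 = int(200.0 / trace.dt)
        v = trace.vm[i0:]
        frac = (v - v[0]) / (v[-1] - v[0])
        # independent oracle: log-linear fit of the relaxation
        t = np.arange(frac.size) * trace.dt
        mask = (frac > 0.05) & (frac < 0.95)
        slope = np.polyfit(t[mask], np.log1p(-frac[mask]), 1)[0]
        tau = -1.0 / slope
        assert tau == pytest.approx(60.0, rel=0.02)

    def test_charge_balance_single_compartment(self):
        # with a near-infinite R_m the membrane is a pure integrator:
        # dV = I * T / C
        soma = Section(id=0, parent_id=None, kind="soma", length=159.154943, diameter=20.0)
        morph = Morphology(sections=[soma])
        params = ModelParameters(rank=0, cell=1, h_dist="HS", densities={},
                                 r_m=1e12, c_m=1.0, i_bias=0.0)
        area = soma.area  # ~10,000 um^2 -> C = 100 pF
        c_pf = params.c_m * area * 1e-2
        cfg = SimulationConfig(duration=1000.0, v_init=-70.0)
        trace = simulate(morph, params, None, (20.0, 0.0, 1000.0), cfg)
        expected_dv = 20.0 * 1000.0 / c_pf
        assert trace.vm[-1] - (-70.0) == pytest.approx(expected_dv, rel=1e-6)


class TestSpikeDetection:
    def _trace(self, vm, dt=0.1):
        vm = np.asarray(vm, dtype=float)
        return VoltageTrace(times=np.arange(vm.size) * dt, vm=vm)

    def test_constant_trace_no_spikes(self):
        trace = self._trace(np.full(1000, -70.0))
        assert detect_spikes(trace).n == 0

    def test_two_separated_transients(self):
        vm = np.full(2000, -70.0)
        vm[300:310] = 40.0
        vm[1500:1510] = 40.0
        trace = self._trace(vm, dt=0.1)
        st = detect_spikes(trace, threshold=-10.0, refractory=2.0)
        assert st.n == 2
        assert st.spike_times[0] == pytest.approx(30.0, abs=0.2)
        assert st.spike_times[1] == pytest.approx(150.0, abs=0.2)

    def test_doublet_within_refractory_collapses(self):
        vm = np.full(1000, -70.0)
        vm[100:105] = 40.0  # t = 10.0 ms
        vm[110:115] = 40.0  # t = 11.0 ms, inside the 2 ms window
        trace = self._trace(vm, dt=0.1)
        assert detect_spikes(trace, refractory=2.0).n == 1


class TestSubthresholdStats:
    def test_constant_trace(self):
        trace = VoltageTrace(times=np.arange(1000) * 0.1, vm=np.full(1000, -64.0))
        m, sd = subthreshold_stats(trace, SpikeTrain(np.empty(0), 100.0))
        assert m == -64.0 and sd == 0.0

    def test_sinusoid_sd_a_over_sqrt2(self):
        t = np.arange(0, 1000.0, 0.1)
        a = 3.0
        trace = VoltageTrace(times=t, vm=-65.0 + a * np.sin(2 * np.pi * t / 50.0))
        m, sd = subthreshold_stats(trace, SpikeTrain(np.empty(0), 1000.0))
        assert sd == pytest.approx(a / np.sqrt(2), rel=0.01)

    def test_spike_cut_recovers_baseline(self, rng):
        t = np.arange(0, 2000.0, 0.1)
        base = -65.0 + rng.normal(0, 1.0, t.size)
        vm = base.copy()
        spike_times = np.array([300.0, 900.0, 1500.0])
        for ts in spike_times:
            i = int(ts / 0.1)
            vm[i : i + 30] = 30.0  # 3 ms transients
        trace = VoltageTrace(times=t, vm=vm)
        m, sd = subthreshold_stats(trace, SpikeTrain(spike_times, 2000.0))
        assert m == pytest.approx(base.mean(), abs=0.3)
        assert sd == pytest.approx(base.std(), rel=0.05)

    def test_everything_cut_rejected(self):
        trace = VoltageTrace(times=np.arange(100) * 0.1, vm=np.full(100, -64.0))
        with pytest.raises(ValueError):
            subthreshold_stats(trace, SpikeTrain(np.array([5.0]), 10.0),
                               cut_before=10.0, cut_after=10.0)


class TestPostSpikeTrajectory:
    def test_single_spike_equals_raw_segment(self):
        t = np.arange(0, 500.0, 0.025)
        vm = np.full(t.size, -65.0)
        i0 = int(100.0 / 0.025)
        vm[i0] = 20.0  # spike peak at exactly 100 ms
        vm[i0 + 1 :] = -70.0 + 5 * np.exp(-(t[i0 + 1 :] - 100.0) / 30.0)
        trace = VoltageTrace(times=t, vm=vm)
        st = SpikeTrain(np.array([100.0]), 500.0)
        t_rel, traj, terminal = post_spike_trajectory([trace], [st], horizon=62.5)
        i_peak = i0  # aligned at the peak sample
        np.testing.assert_allclose(traj, vm[i_peak : i_peak + traj.size])
        assert terminal == traj[-1]
        assert t_rel[-1] == pytest.approx(62.5)

    def test_identical_periodic_spikes_average_to_one_segment(self):
        dt = 0.025
        t = np.arange(0, 2000.0, dt)
        period = 250.0
        vm = -65.0 + 10 * np.cos(2 * np.pi * t / period)
        spike_times = np.arange(0, 1800.0, period)
        trace = VoltageTrace(times=t, vm=vm)
        st = SpikeTrain(spike_times, 2000.0)
        _, traj, _ = post_spike_trajectory([trace], [st], horizon=62.5)
        one = vm[: traj.size]
        np.testing.assert_allclose(traj, one, atol=1e-9)

    def test_no_spikes_rejected(self):
        trace = VoltageTrace(times=np.arange(100) * 0.025, vm=np.full(100, -65.0))
        with pytest.raises(ValueError):
            post_spike_trajectory([trace], [SpikeTrain(np.empty(0), 2.5)])


class TestActiveIntegration:
    def test_convergence_halving_dt(self):
        """Halving dt from the 0.025 ms default changes the somatic trace
        by well under 0.5 mV RMS on a driven active model."""
        params = load_model_parameters(109, "HSD")
        morph = standard_morphology(params.cell, seed=params.cell)
        sites = place_synapse_sites(morph)
        drv = build_drive(sites, 0.03, 0.03, None, 5, duration_ms=1000.0)
        traces = {}
        for dt in (0.025, 0.0125):
            cfg = SimulationConfig(dt=dt, duration=1000.0)
            traces[dt] = simulate(morph, params, drv, None, cfg)
        coarse = traces[0.025].vm
        fine = traces[0.0125].vm[::2]
        rms = np.sqrt(np.mean((coarse - fine) ** 2))
        assert rms < 0.5

    def test_determinism_bitwise(self):
        params = load_model_parameters(26, "HS")
        morph = standard_morphology(params.cell, seed=params.cell)
        sites = place_synapse_sites(morph)
        drv = build_drive(sites, 0.03, 0.03, None, 9, duration_ms=400.0)
        cfg = SimulationConfig(duration=400.0)
        a = simulate(morph, params, drv, None, cfg)
        b = simulate(morph, params, drv, None, cfg)
        assert np.array_equal(a.vm, b.vm)

    def test_uniform_passive_tree_stays_spatially_uniform(self):
        # identical leak everywhere and a uniform start: axial currents must
        # vanish, so the soma trace is flat at the leak reversal
        morph = standard_morphology(1)
        params = ModelParameters(rank=0, cell=1, h_dist="HS", densities={},
                                 r_m=60_000.0, c_m=1.0, i_bias=0.0)
        cfg = SimulationConfig(duration=300.0, v_init=params.e_leak)
        trace = simulate(morph, params, None, None, cfg)
        assert np.allclose(trace.vm, params.e_leak, atol=1e-9)
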