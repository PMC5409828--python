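import math

import numpy as np
import pytest

from olmtheta.channels import (
    available_ranks,
    apply_block,
    apply_camp_shift,
    channel_current,
    fit_h_leak,
    gate_inf,
    gate_tau,
    load_model_parameters,
    reference_channel_set,
)


class TestParameterTable:
    def test_all_32_rows_load(self):
        ranks_hs = available_ranks("HS")
        ranks_hsd = available_ranks("HSD")
        assert len(ranks_hs) == len(ranks_hsd) == 16
        for h_dist, ranks in (("HS", ranks_hs), ("HSD", ranks_hsd)):
            for rank in ranks:
                p = load_model_parameters(rank, h_dist)
                assert p.rank == rank

    def test_h_density_invariant_per_distribution(self):
        for rank in available_ranks("HS"):
            p = load_model_parameters(rank, "HS")
            assert p.density("H", "soma") == 0.5
            assert p.density("H", "dendrite") == 0.0
        for rank in available_ranks("HSD"):
            p = load_model_parameters(rank, "HSD")
            assert p.density("H", "soma") == 0.1
            assert p.density("H", "dendrite") == 0.1

    def test_rank_109_row_values(self):
        p = load_model_parameters(109, "HSD")
        assert p.density("H", "dendrite") == 0.1
        assert p.density("Kdrs", "soma") == 42.0
        assert p.density("Nad", "dendrite") == 230.0
        assert p.density("KA", "soma") == 32.0
        assert p.c_m == pytest.approx(1.061)

    def test_rank_26_row_values(self):
        p = load_model_parameters(26, "HS")
        assert p.density("H", "soma") == 0.5
        assert p.density("Kdrs", "soma") == 2.3
        assert p.density("Nad", "dendrite") == 117.0
        assert p.c_m == pytest.approx(1.046)

    def test_unknown_rank_lists_valid_ones(self):
        with pytest.raises(KeyError, match="valid ranks"):
            load_model_parameters(9999, "HS")

    def test_bias_current_stored_but_documented_unused(self):
        p = load_model_parameters(109, "HSD")
        assert p.i_bias == pytest.approx(-2.18)


class TestGates:
    def test_boltzmann_midpoint(self):
        g = reference_channel_set()["H"].gates[0]
        assert gate_inf(g.v_half, g) == pytest.approx(0.5)

    def test_saturation_hyperpolarized(self):
        g = reference_channel_set()["H"].gates[0]  # positive slope
        assert gate_inf(-1e3, g) == pytest.approx(1.0)
        assert gate_inf(1e3, g) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_boltzmann_value(self):
        g = reference_channel_set()["H"].gates[0]
        # independent scalar arithmetic: 1/(1+exp((-74 - (-84))/10.2))
        expected = 1.0 / (1.0 + math.exp(10.0 / 10.2))
        assert gate_inf(-74.0, g) == pytest.approx(expected, rel=1e-12)

    def test_tau_positive_over_physiological_range(self):
        v = np.linspace(-120.0, 60.0, 361)
        for name, spec in reference_channel_set().items():
            for g in spec.gates:
                assert np.all(gate_tau(v, g) > 0), name

    def test_gating_ode_relaxes_monotonically_to_xinf(self):
        # voltage clamp at -70 mV from a displaced start, explicit integration
        g = reference_channel_set()["H"].gates[0]
        v = -70.0
        xinf, tau = float(gate_inf(v, g)), float(gate_tau(v, g))
        x, dt = 0.0, 0.01
        gap_prev = abs(xinf - x)
        for _ in range(int(15 * tau / dt)):
            x += dt * (xinf - x) / tau
            gap = abs(xinf - x)
            assert gap <= gap_prev + 1e-15
            gap_prev = gap
        assert gap_prev < 1e-6


class TestChannelCurrent:
    def test_zero_density_zero_current(self):
        spec = reference_channel_set()["Kdrf"]
        assert channel_current(-50.0, [0.5], spec, 0.0, 1000.0) == 0.0

    def test_reversal_potential_nulls_current(self):
        spec = reference_channel_set()["Kdrf"]
        assert channel_current(spec.e_rev, [0.7], spec, 100.0, 1000.0) == 0.0

    def test_area_linearity_vs_bruteforce(self):
        spec = reference_channel_set()["KA"]
        state = [0.4, 0.6]
        i1 = channel_current(-40.0, state, spec, 32.0, 500.0)
        i2 = channel_current(-40.0, state, spec, 32.0, 1000.0)
        brute = 1e-3 * 32.0 * 1000.0 * (0.4 ** spec.gates[0].exponent) * (
            0.6 ** spec.gates[1].exponent
        ) * (-40.0 - spec.e_rev)
        assert i2 == pytest.approx(2.0 * i1)
        assert i2 == pytest.approx(brute)

    def test_gate_values_outside_unit_interval_rejected(self):
        spec = reference_channel_set()["Kdrf"]
        with pytest.raises(ValueError):
            channel_current(-50.0, [1.5], spec, 10.0, 100.0)


class TestCampShift:
    def test_control_minus84_shifts_to_minus79(self):
        h = reference_channel_set()["H"]
        assert h.gates[0].v_half == -84.0
        shifted = apply_camp_shift(h)
        assert shifted.gates[0].v_half == -79.0

    def test_two_shifts_compose(self):
        h = reference_channel_set()["H"]
        twice = apply_camp_shift(apply_camp_shift(h))
        assert twice.gates[0].v_half == -74.0

    def test_activation_strictly_increases_at_fixed_voltage(self):
        h = reference_channel_set()["H"]
        shifted = apply_camp_shift(h)
        assert gate_inf(-80.0, shifted.gates[0]) > gate_inf(-80.0, h.gates[0])

    def test_non_h_channel_rejected(self):
        with pytest.raises(ValueError):
            apply_camp_shift(reference_channel_set()["Kdrs"])

    def test_other_fields_untouched(self):
        h = reference_channel_set()["H"]
        shifted = apply_camp_shift(h)
        assert shifted.e_rev == h.e_rev
        assert shifted.gates[0].slope == h.gates[0].slope
        assert shifted.gates[0].tau == h.gates[0].tau


class TestBlock:
    def test_h_block_zeroes_h_only(self):
        p = load_model_parameters(109, "HSD")
        b = apply_block(p, {"H"})
        assert b.density("H", "dendrite") == 0.0
        assert b.density("Kdrs", "soma") == 42.0
        assert p.density("H", "dendrite") == 0.1  # original untouched

    def test_empty_block_is_identity(self):
        p = load_model_parameters(26, "HS")
        b = apply_block(p, set())
        assert b.densities == p.densities

    def test_blocks_compose_as_union(self):
        p = load_model_parameters(109, "HSD")
        ab = apply_block(apply_block(p, {"H", "Kdrs"}), {"KA"})
        direct = apply_block(p, {"H", "Kdrs", "KA"})
        assert ab.densities == direct.densities

    def test_unblockable_channel_rejected(self):
        p = load_model_parameters(109, "HSD")
        with pytest.raises(ValueError):
            apply_block(p, {"Nad"})


class TestHLeak:
    def test_density_is_product_of_gbar_and_activation(self):
        p = load_model_parameters(26, "HS")  # gbar_H = 0.5
        h = p.channels["H"].gates[0]
        vm = -70.0
        assert fit_h_leak(p, vm) == pytest.approx(0.5 * float(gate_inf(vm, h)))

    def test_midpoint_gives_half_gbar(self):
        p = load_model_parameters(26, "HS")
        assert fit_h_leak(p, -84.0) == pytest.approx(0.25)  # 0.5 * 0.5

    def test_monotone_increase_with_hyperpolarization(self):
        p = load_model_parameters(109, "HSD")
        densities = [fit_h_leak(p, vm) for vm in np.linspace(-60.0, -100.0, 9)]
        assert all(b > a for a, b in zip(densities, densities[1:]))

    def test_model_without_h_rejected(self):
        p = apply_block(load_model_parameters(109, "HSD"), {"H"})
        with pytest.raises(ValueError):
            fit_h_leak(p, -70.0)
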