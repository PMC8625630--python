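"""Tunneling probability, kinetic-energy models and quantum conductances."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ionqt.constants import get_constants
from ionqt.tunneling import (
    BarrierProfile,
    ChannelPopulation,
    GateBarrier,
    KineticEnergy,
    PlausibilityWarning,
    exponent_integral_oracle,
    extracellular_kinetic_energy,
    get_ion,
    intracellular_kinetic_energy,
    membrane_conductance,
    single_channel_conductance,
    tunneling_exponent,
    tunneling_probability,
)

PAPER = get_constants("paper")
CODATA = get_constants("codata")

LI7 = get_ion("Li-7")
LI6 = get_ion("Li-6")


def _extra(Vm=0.087):
    return extracellular_kinetic_energy(Vm, LI7, PAPER)


class TestKineticEnergy:
    def test_extracellular_value(self):
        # q*Vm + thermal term = 1.6e-19*0.087 + 0.64e-20
        assert _extra().value == pytest.approx(2.032e-20, rel=1e-6)

    def test_zero_voltage_degenerates_to_intracellular(self):
        assert _extra(0.0).value == intracellular_kinetic_energy(PAPER).value

    def test_voltage_part_linear(self):
        thermal = intracellular_kinetic_energy(PAPER).value
        v1 = _extra(0.05).value - thermal
        v2 = _extra(0.10).value - thermal
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_signed_voltage_rejected(self):
        with pytest.raises(ValueError, match="magnitude"):
            extracellular_kinetic_energy(-0.087, LI7, PAPER)

    def test_negative_kinetic_energy_rejected(self):
        with pytest.raises(ValueError):
            KineticEnergy(-1.0, "intracellular")


class TestTunnelingProbability:
    @pytest.mark.parametrize(
        "ion,G,side,expected",
        [
            # extracellular at Vm=0.087, gate-energy endpoints
            (LI7, 3, "extra", 2.2e-3),
            (LI7, 7, "extra", 6.3e-14),
            (LI6, 3, "extra", 3.5e-3),
            # intracellular (thermal only)
            (LI7, 3, "intra", 8.4e-11),
            (LI6, 7, "intra", 1.9e-18),
        ],
    )
    def test_printed_probabilities(self, ion, G, side, expected):
        gate = GateBarrier.from_scaled(G, 1)
        ke = _extra() if side == "extra" else intracellular_kinetic_energy(PAPER)
        if side == "extra":
            ke = extracellular_kinetic_energy(0.087, ion, PAPER)
        assert tunneling_probability(ion, gate, ke, PAPER).probability == pytest.approx(
            expected, rel=0.05
        )

    def test_zero_length_gate_is_transparent(self):
        gate = GateBarrier.from_scaled(5, 0)
        for ke in (_extra(), intracellular_kinetic_energy(PAPER)):
            assert tunneling_probability(LI7, gate, ke, PAPER).probability == 1.0

    def test_barrier_surmounted_clamp(self):
        gate = GateBarrier.from_scaled(3, 1)
        hot = KineticEnergy(5e-20, "extracellular")
        assert tunneling_exponent(LI7, gate, hot, PAPER) == 0.0
        assert tunneling_probability(LI7, gate, hot, PAPER).probability == 1.0

    def test_probability_is_exp_of_minus_exponent(self):
        gate = GateBarrier.from_scaled(5, 1)
        res = tunneling_probability(LI7, gate, _extra(), PAPER)
        assert res.probability == math.exp(-res.exponent)

    def test_extracellular_exceeds_intracellular(self):
        gate = GateBarrier.from_scaled(5, 1)
        intra = tunneling_probability(LI7, gate, intracellular_kinetic_energy(PAPER), PAPER)
        for Vm in (0.01, 0.05, 0.087):
            extra = tunneling_probability(
                LI7, gate, extracellular_kinetic_energy(Vm, LI7, PAPER), PAPER
            )
            assert extra.probability > intra.probability

    @pytest.mark.parametrize("var", ["m", "w", "g"])
    def test_monotone_decreasing(self, var):
        grids = {
            "m": [9e-27, 1.15e-26, 3e-26, 6.5e-26],
            "w": [0.2, 0.5, 1.0, 1.5, 2.0],
            "g": [3, 4, 5, 6, 7],
        }
        previous = None
        for v in grids[var]:
            ion = LI7 if var != "m" else type(LI7)("x", v)
            G = 5 if var != "g" else v
            L = 1 if var != "w" else v
            gate = GateBarrier.from_scaled(G, L)
            p = tunneling_probability(ion, gate, _extra(), PAPER).probability
            if previous is not None:
                assert p < previous
            previous = p

    def test_monotone_increasing_in_kinetic_energy(self):
        gate = GateBarrier.from_scaled(5, 1)
        probs = [
            tunneling_probability(
                LI7, gate, extracellular_kinetic_energy(v, LI7, PAPER), PAPER
            ).probability
            for v in (0.0, 0.02, 0.05, 0.087)
        ]
        assert probs == sorted(probs)

    def test_gate_validation(self):
        with pytest.raises(ValueError):
            GateBarrier(g=-1e-20, w=1e-10)
        with pytest.raises(ValueError):
            GateBarrier(g=5e-20, w=-1e-10)

    def test_out_of_range_gate_warns(self):
        with pytest.warns(PlausibilityWarning):
            GateBarrier.from_scaled(10, 1)


class TestQuadratureOracle:
    @given(
        G=st.floats(min_value=3, max_value=7),
        L=st.floats(min_value=0.05, max_value=2),
        Vm=st.floats(min_value=0.0, max_value=0.087),
        label=st.sampled_from(["Li-7", "Li-6"]),
    )
    def test_closed_form_matches_quadrature(self, G, L, Vm, label):
        """The barrier-penetration integral has the stated closed form."""
        ion = get_ion(label)
        gate = GateBarrier.from_scaled(G, L)
        ke = extracellular_kinetic_energy(Vm, ion, CODATA)
        closed = tunneling_exponent(ion, gate, ke, CODATA)
        numeric = exponent_integral_oracle(ion, BarrierProfile(gate), ke, CODATA)
        assert numeric == pytest.approx(closed, rel=1e-6)

    def test_empty_forbidden_region(self):
        gate = GateBarrier.from_scaled(3, 1)
        hot = KineticEnergy(5e-20, "extracellular")
        assert exponent_integral_oracle(LI7, BarrierProfile(gate), hot, CODATA) == 0.0

    def test_mass_scaling_of_prefactor(self):
        gate = GateBarrier.from_scaled(5, 1)
        ke = intracellular_kinetic_energy(CODATA)
        e7 = exponent_integral_oracle(LI7, BarrierProfile(gate), ke, CODATA)
        e6 = exponent_integral_oracle(LI6, BarrierProfile(gate), ke, CODATA)
        assert e6 / e7 == pytest.approx(math.sqrt(LI6.mass / LI7.mass), rel=1e-6)


class TestConductances:
    def test_conductance_quantum_at_unit_transmission(self):
        gate = GateBarrier.from_scaled(5, 0)
        tq = tunneling_probability(LI7, gate, _extra(), PAPER)
        assert single_channel_conductance(LI7, tq, PAPER) == pytest.approx(3.88e-5, rel=1e-9)

    @pytest.mark.parametrize(
        "ion,G,L,side,expected",
        [
            (LI7, 3, 1, "extra", 8.6e-8),  # single-channel at the G=3 endpoint
            (LI7, 5, 2, "intra", 1.7e-35),
        ],
    )
    def test_printed_single_channel_values(self, ion, G, L, side, expected):
        gate = GateBarrier.from_scaled(G, L)
        ke = (
            extracellular_kinetic_energy(0.087, ion, PAPER)
            if side == "extra"
            else intracellular_kinetic_energy(PAPER)
        )
        tq = tunneling_probability(ion, gate, ke, PAPER)
        assert single_channel_conductance(ion, tq, PAPER) == pytest.approx(expected, rel=0.05)

    def test_membrane_conductance_printed_values(self):
        gate = GateBarrier.from_scaled(5, 1)
        tq = tunneling_probability(LI7, gate, _extra(), PAPER)
        mc = membrane_conductance(LI7, tq, ChannelPopulation(1e11, gate), PAPER)
        assert mc == pytest.approx(11.5, rel=0.05)
        tq_i = tunneling_probability(LI7, gate, intracellular_kinetic_energy(PAPER), PAPER)
        mc_i = membrane_conductance(LI7, tq_i, ChannelPopulation(1e9, gate), PAPER)
        assert mc_i == pytest.approx(2.6e-8, rel=0.05)

    def test_membrane_conductance_linear_in_density(self):
        gate = GateBarrier.from_scaled(5, 1)
        tq = tunneling_probability(LI7, gate, _extra(), PAPER)
        one = membrane_conductance(LI7, tq, ChannelPopulation(1e10, gate), PAPER)
        two = membrane_conductance(LI7, tq, ChannelPopulation(2e10, gate), PAPER)
        assert two == 2 * one
        assert membrane_conductance(LI7, tq, ChannelPopulation(0.0, gate), PAPER) == 0.0
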