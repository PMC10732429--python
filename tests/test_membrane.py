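"""Plasma-membrane kinetics: gating curves, channel fluxes, pumps and
exchangers."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from merkelsim import membrane

mV = 1e-3
uM = 1e-3  # mol/m^3


class TestNernst:
    def test_equal_concentrations_give_zero(self):
        for z in (-1, 1, 2):
            assert membrane.nernst_potential(10.0, 10.0, z, 310.0) == 0.0

    def test_log_antisymmetry(self):
        e1 = membrane.nernst_potential(140.0, 5.0, 1, 310.0)
        e2 = membrane.nernst_potential(5.0, 140.0, 1, 310.0)
        assert e1 == pytest.approx(-e2, rel=1e-12)

    def test_potassium_gradient_value(self):
        # closed form: -(RT/F) ln 28 at 310 K
        e = membrane.nernst_potential(140.0, 5.0, 1, 310.0)
        assert e == pytest.approx(-8.901562196464e-02, rel=1e-10)

    def test_divalent_halves_the_potential(self):
        e1 = membrane.nernst_potential(2.0, 200.0, 1, 310.0)
        e2 = membrane.nernst_potential(2.0, 200.0, 2, 310.0)
        assert e1 == pytest.approx(2 * e2, rel=1e-12)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            membrane.nernst_potential(0.0, 5.0, 1, 310.0)
        with pytest.raises(ValueError):
            membrane.nernst_potential(5.0, -1.0, 1, 310.0)
        with pytest.raises(ValueError):
            membrane.nernst_potential(5.0, 5.0, 0, 310.0)


# (channel, gate, Vm at midpoint [V], C_Ca [mol/m^3])
MIDPOINTS = [
    ("Kv1.4", "m", -23.12 * mV, 0.1 * uM),
    ("Kv1.4", "h_fast", -44.36 * mV, 0.1 * uM),
    ("Kv4.2", "m", 17.66 * mV, 0.1 * uM),
    ("Kv4.2", "h", -44.36 * mV, 0.1 * uM),
    ("BKCa", "n", -110.0 * mV, 1.0),        # pCa = 0 at C_Ca = K_BKCa = 1 mM
    ("KDR", "n", -33.3 * mV, 0.1 * uM),
    ("Cav1.2", "m", 8.46 * mV, 0.1 * uM),
    ("Cav1.2", "h", -42.52 * mV, 0.1 * uM),
    ("Cav1.2", "hCa", 0.0, 1.0 * uM),       # K_hCa midpoint, any Vm
    ("Cav2.1", "n", -5.1 * mV, 0.1 * uM),
]


class TestGatingRates:
    @pytest.mark.parametrize("channel,gate,vm,c_ca", MIDPOINTS)
    def test_steady_state_midpoints(self, channel, gate, vm, c_ca, params):
        kin = membrane.gating_rates(channel, vm, c_ca, params)
        assert kin[gate].steady == pytest.approx(0.5, abs=1e-12)

    def test_shared_inactivation_curve_of_a_type_channels(self, params):
        # the two A-type K+ channels inactivate with the same steady curve
        for vm in np.linspace(-0.12, 0.08, 41):
            h14 = membrane.gating_rates("Kv1.4", vm, 1e-4, params)["h_fast"]
            h42 = membrane.gating_rates("Kv4.2", vm, 1e-4, params)["h"]
            assert h14.steady == pytest.approx(h42.steady, rel=1e-12)

    def test_unknown_channel_rejected(self, params):
        with pytest.raises(ValueError):
            membrane.gating_rates("Nav1.7", -0.06, 1e-4, params)

    @given(vm=st.floats(-0.12, 0.08), c_ca=st.floats(1e-5, 10.0))
    def test_steady_values_in_unit_interval_and_taus_positive(
            self, vm, c_ca, params):
        for channel in membrane.CHANNELS:
            for name, kin in membrane.gating_rates(channel, vm, c_ca,
                                                   params).items():
                assert 0.0 <= kin.steady <= 1.0
                if name != "hCa":
                    assert kin.tau > 0.0

    def test_activation_monotone_increasing_in_vm(self, params):
        grid = np.linspace(-0.12, 0.08, 201)
        rising = [("Kv1.4", "m"), ("Kv4.2", "m"), ("BKCa", "n"),
                  ("KDR", "n"), ("Cav1.2", "m"), ("Cav2.1", "n")]
        falling = [("Kv1.4", "h_fast"), ("Kv4.2", "h"), ("Cav1.2", "h")]
        for channel, gate in rising + falling:
            vals = [membrane.gating_rates(channel, v, 1e-4, params)[gate].steady
                    for v in grid]
            d = np.diff(vals)
            if (channel, gate) in rising:
                assert np.all(d > 0)
            else:
                assert np.all(d < 0)

    def test_bkca_curve_right_shifts_as_calcium_falls(self, params):
        # lower Ca2+ shifts the half-activation voltage (where n_inf = 0.5)
        # to more positive potentials
        from scipy.optimize import brentq

        def v_half(c_ca):
            return brentq(
                lambda v: membrane.gating_rates("BKCa", v, c_ca,
                                                params)["n"].steady - 0.5,
                -0.3, 0.3)

        halves = [v_half(c * uM) for c in (1.0, 0.1, 0.01)]
        assert halves[0] < halves[1] < halves[2]


class TestChannelFluxes:
    def _gates(self, channel, value):
        names = {"Kv1.4": ("m", "h_fast", "h_slow"), "Kv4.2": ("m", "h"),
                 "BKCa": ("n",), "KDR": ("n",), "Cav2.1": ("n",),
                 "Cav1.2": ("m", "h", "hCa")}[channel]
        return {n: value for n in names}

    @pytest.mark.parametrize("channel", membrane.CHANNELS)
    def test_zero_at_reversal_and_when_closed(self, channel):
        assert membrane.voltage_gated_flux(
            channel, self._gates(channel, 1.0), -0.03, -0.03, 2.0) == 0.0
        assert membrane.voltage_gated_flux(
            channel, self._gates(channel, 0.0), 0.05, -0.09, 2.0) == 0.0

    def test_kv14_open_flux_magnitude(self):
        # g = 0.25 mS/cm^2 (2.5 S/m^2), fully open, 100 mV above E_K:
        # |J| = g*dV/F, outward (negative in the inward-positive convention)
        j = membrane.voltage_gated_flux(
            "Kv1.4", {"m": 1.0, "h_fast": 1.0, "h_slow": 1.0},
            0.011, -0.089, 2.5)
        assert j == pytest.approx(-2.591067414154e-06, rel=1e-10)

    def test_kv14_open_probability_weighting(self):
        # m^4 (0.7 h_fast + 0.3 h_slow)
        p = membrane.open_probability(
            "Kv1.4", {"m": 0.5, "h_fast": 1.0, "h_slow": 0.0})
        assert p == pytest.approx(0.5 ** 4 * 0.7, rel=1e-12)

    def test_out_of_range_gate_rejected(self):
        with pytest.raises(ValueError):
            membrane.voltage_gated_flux("KDR", {"n": 1.5}, 0.0, -0.09, 1.0)
        with pytest.raises(ValueError):
            membrane.voltage_gated_flux("KDR", {"n": 0.5}, 0.0, -0.09, -1.0)

    def test_piezo2_flux_examples(self):
        assert membrane.piezo2_flux(0.0, 1.0, -0.06, 30.0, 6e-3) == 0.0
        assert membrane.piezo2_flux(1.0, 1.0, 6e-3, 30.0, 6e-3) == 0.0
        j = membrane.piezo2_flux(1.0, 1.0, -0.06, 30.0, 6e-3)
        assert j == pytest.approx(2.052125392010e-05, rel=1e-10)
        assert j > 0  # inward Ca2+ below the reversal potential


class TestLeaks:
    def test_zero_at_equilibrium(self):
        for ion in membrane.LEAK_IONS:
            assert membrane.leak_flux(ion, -0.06, -0.06, 0.5) == 0.0

    def test_calcium_leak_is_inward_at_rest(self):
        # E_Ca is far above the resting potential
        assert membrane.leak_flux("Ca", -0.06, 0.13, 2e-4) > 0.0

    def test_potassium_leak_is_outward_above_reversal(self):
        assert membrane.leak_flux("K", -0.05, -0.089, 0.9) < 0.0

    def test_chloride_leak_sign(self):
        # Vm above E_Cl drives Cl- into the cell (positive molar influx)
        assert membrane.leak_flux("Cl", -0.03, -0.06, 0.05) > 0.0

    def test_linearity_in_conductance(self):
        j1 = membrane.leak_flux("Na", -0.06, 0.07, 0.43)
        j2 = membrane.leak_flux("Na", -0.06, 0.07, 0.86)
        assert j2 == pytest.approx(2 * j1, rel=1e-12)


class TestPumpsAndTransporters:
    def test_nak_pump_half_saturation_product(self, params):
        # C_Na = K_Na and C_K = K_K give (1/2)^3 (1/2)^2 = 1/32 of maximum
        p = 1.0
        j = membrane.nak_pump_flux(10.0, 140.0, p, params)
        assert j == pytest.approx(1.0 / 32.0, rel=1e-12)

    def test_nak_pump_limits(self, params):
        assert membrane.nak_pump_flux(1e9, 1e-9, 1.0, params) == \
            pytest.approx(1.0, rel=1e-6)
        assert membrane.nak_pump_flux(1e-12, 140.0, 1.0, params) == \
            pytest.approx(0.0, abs=1e-20)

    def test_nkcc1_equilibrium_sign_linearity(self):
        assert membrane.nkcc1_flux(10, 140, 10, 10, 140, 10, 3.0) == 0.0
        # larger outside products load the cell (positive)
        assert membrane.nkcc1_flux(10, 5, 10, 145, 5, 110, 3.0) > 0.0
        j1 = membrane.nkcc1_flux(10, 140, 10, 145, 5, 110, 1.0)
        j2 = membrane.nkcc1_flux(10, 140, 10, 145, 5, 110, 2.0)
        assert j2 == pytest.approx(2 * j1, rel=1e-12)

    def test_kcc2_equilibrium_and_extrusion_direction(self):
        # zero when the internal K*Cl product equals the external one
        assert membrane.kcc2_flux(55.0, 10.0, 5.0, 110.0, 1.0) == \
            pytest.approx(0.0, abs=1e-15)
        assert membrane.kcc2_flux(140.0, 10.0, 5.0, 110.0, 1.0) > 0.0
        assert membrane.kcc2_flux(10.0, 5.0, 5.0, 110.0, 1.0) < 0.0

    def test_pmca_half_saturation_and_limits(self, params):
        k = params.K_Capump
        assert membrane.pmca_flux(k, 1.0, params) == pytest.approx(0.5, rel=1e-12)
        assert membrane.pmca_flux(0.0, 1.0, params) == 0.0
        assert membrane.pmca_flux(1e6 * k, 1.0, params) == \
            pytest.approx(1.0, rel=1e-9)

    def test_ncx_reversal_condition(self, params):
        # at Vm = 0 the flux sign follows C_Na^3 C_Ca,out - C_Na,out^3 C_Ca,
        # and the flux vanishes when the two terms balance
        c_na, c_na_out, c_ca_out = 10.0, 145.0, 2.0
        c_ca_rev = c_na ** 3 * c_ca_out / c_na_out ** 3
        j = membrane.ncx_flux(0.0, c_na, c_ca_rev, c_na_out, c_ca_out,
                              310.0, 1e-6, params)
        assert j == pytest.approx(0.0, abs=1e-18)
        j_fwd = membrane.ncx_flux(0.0, c_na, 10 * c_ca_rev, c_na_out,
                                  c_ca_out, 310.0, 1e-6, params)
        assert j_fwd < 0.0  # forward mode: Ca2+ extrusion

    def test_ncx_reference_value(self, params):
        # direct evaluation at Vm = 0, Na 10/145 mM, Ca 0.1 uM / 2 mM
        j = membrane.ncx_flux(0.0, 10.0, 1e-4, 145.0, 2.0, 310.0, 1.0, params)
        assert j == pytest.approx(1.687949101777e-04, rel=1e-10)
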