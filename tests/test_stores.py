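"""ER and mitochondrial Ca2+ handling, IP3 turnover."""
import numpy as np
import pytest

from merkelsim import stores

uM = 1e-3  # mol/m^3


class TestSerca:
    def test_half_saturation_at_dissociation_constant(self, params):
        assert stores.serca_flux(0.1 * uM, 2.0, params) == \
            pytest.approx(1.0, rel=1e-12)

    def test_limits(self, params):
        assert stores.serca_flux(0.0, 2.0, params) == 0.0
        assert stores.serca_flux(1e3, 2.0, params) == pytest.approx(2.0, rel=1e-8)


class TestRyR:
    def test_closed_below_and_at_threshold(self, params):
        assert stores.ryr_flux(0.2 * uM, 100 * uM, 85.0, params) == 0.0
        assert stores.ryr_flux(0.3 * uM, 100 * uM, 85.0, params) == 0.0

    def test_fully_open_far_above_threshold(self, params):
        # sigmoid -> 1: flux approaches P * (C_ER - C_Ca)
        c, c_er = 2.0 * uM, 100.0 * uM
        j = stores.ryr_flux(c, c_er, 85.0, params)
        assert j == pytest.approx(85.0 * (c_er - c), rel=1e-9)

    def test_no_gradient_no_flux(self, params):
        assert stores.ryr_flux(1.0 * uM, 1.0 * uM, 85.0, params) == 0.0

    def test_direction_follows_gradient(self, params):
        assert stores.ryr_flux(1.0 * uM, 10 * uM, 85.0, params) > 0
        assert stores.ryr_flux(1.0 * uM, 0.1 * uM, 85.0, params) < 0


class TestIP3R:
    def test_gate_midpoints(self, params):
        m_inf, _ = stores.ip3r_rates(0.4 * uM, params)
        _, h_inf = stores.ip3r_rates(0.6 * uM, params)
        assert m_inf == pytest.approx(0.5, abs=1e-12)
        assert h_inf == pytest.approx(0.5, abs=1e-12)

    def test_open_probability_is_bell_shaped(self, params):
        grid = np.geomspace(0.01 * uM, 10 * uM, 300)
        prod = np.array([np.prod(stores.ip3r_rates(c, params)) for c in grid])
        i_max = int(np.argmax(prod))
        assert 0 < i_max < len(grid) - 1
        assert prod[i_max] > 10 * max(prod[0], prod[-1])

    def test_gate_relaxation_rates(self, params):
        # gates relax exponentially toward their steady values with the
        # fixed time constants
        c = 0.5 * uM
        m_inf, h_inf = stores.ip3r_rates(c, params)
        dm, dh = stores.ip3r_gate_derivatives(c, 0.0, 1.0, params)
        assert dm == pytest.approx(m_inf / params.tau_m_IP3, rel=1e-12)
        assert dh == pytest.approx((h_inf - 1.0) / params.tau_h_IP3, rel=1e-12)

    def test_literal_h_equation_switch(self, params):
        literal = params.replace(literal_ip3r_h_equation=True)
        c, m, h = 0.5 * uM, 0.3, 0.9
        _, h_inf = stores.ip3r_rates(c, params)
        _, dh = stores.ip3r_gate_derivatives(c, m, h, literal)
        assert dh == pytest.approx((h_inf - m) / params.tau_h_IP3, rel=1e-12)

    def test_flux_reduces_to_leak_without_ip3_pathway(self, params):
        j = stores.ip3r_flux(0.1 * uM, 50 * uM, 1 * uM, 0.5, 0.5,
                             p_leak=7e-3, p_ip3=0.0, params=params)
        assert j == pytest.approx(7e-3 * (50 * uM - 0.1 * uM), rel=1e-12)

    def test_hill_midpoint_in_ip3(self, params):
        # at C_IP3 = K_IP3 the receptor term contributes P_IP3*m*h/2
        m = h = 0.8
        dc = 50 * uM - 0.1 * uM
        j = stores.ip3r_flux(0.1 * uM, 50 * uM, params.K_IP3, m, h,
                             0.0, 2.0, params)
        assert j == pytest.approx(2.0 * 0.5 * m * h * dc, rel=1e-12)

    def test_no_gradient_no_flux(self, params):
        assert stores.ip3r_flux(1 * uM, 1 * uM, 3 * uM, 0.5, 0.5,
                                7e-3, 17.5, params) == 0.0

    def test_nonnegative_when_store_is_fuller(self, params):
        for c_er in (0.2 * uM, 1 * uM, 100 * uM):
            assert stores.ip3r_flux(0.2 * uM, c_er, 3 * uM, 0.7, 0.7,
                                    7e-3, 17.5, params) >= 0.0


class TestIP3Turnover:
    def test_pure_decay_without_calcium(self, params):
        d_ip3, _ = stores.ip3_turnover(0.0, 2 * uM, 5 * uM, params)
        assert d_ip3 == pytest.approx(-params.k_dIP3 * 2 * uM, rel=1e-12)

    def test_replenishment_midpoint(self, params):
        # precursor production halves at the reference concentration
        _, d_pre = stores.ip3_turnover(0.0, 0.0, params.K_s_preIP3, params)
        assert d_pre == pytest.approx(params.k_preIP3 / 2.0, rel=1e-12)

    def test_quasi_steady_ip3_level(self, params):
        # dC_IP3/dt = 0 at C_IP3 = (k_IP3/k_dIP3) * sat(C_Ca) * C_preIP3;
        # direct evaluation at C_Ca = 2 uM, C_pre = 5 uM
        c_qss = 9.411764705882e-03
        d_ip3, _ = stores.ip3_turnover(2 * uM, c_qss, 5 * uM, params)
        assert d_ip3 == pytest.approx(0.0, abs=1e-15)


class TestMitochondria:
    def test_uptake_and_release_midpoints(self, params):
        up, _ = stores.mito_fluxes(params.K_MCU, 0.0, 2.0, 1.0, params)
        _, rel = stores.mito_fluxes(0.0, params.K_MNCX, 2.0, 1.0, params)
        assert up == pytest.approx(1.0, rel=1e-12)
        assert rel == pytest.approx(0.5, rel=1e-12)

    def test_both_vanish_without_calcium(self, params):
        assert stores.mito_fluxes(0.0, 0.0, 2.0, 1.0, params) == (0.0, 0.0)


class TestStoreBalances:
    def test_bookkeeping_identity(self, params):
        dn_er, dn_mt = stores.store_balances(3.0, 1.0, 0.5, 2.0, 0.25, params)
        assert dn_er == pytest.approx(params.S_ER * (3.0 - 1.0 - 0.5), rel=1e-12)
        assert dn_mt == pytest.approx(
            params.S_MT / 1.3 * (2.0 - 0.25), rel=1e-12)

    def test_zero_fluxes_zero_derivatives(self, params):
        assert stores.store_balances(0, 0, 0, 0, 0, params) == (0.0, 0.0)

    def test_mito_buffer_factor_scales_the_rate(self, params):
        unbuffered = params.replace(beta_MT=0.0)
        dn_b, _ = (None, None)
        _, dn_mt = stores.store_balances(0, 0, 0, 1.0, 0.0, params)
        _, dn_mt0 = stores.store_balances(0, 0, 0, 1.0, 0.0, unbuffered)
        assert dn_mt == pytest.approx(dn_mt0 / 1.3, rel=1e-12)
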