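"""Whole-model behaviour: resting state, derivative assembly, traces and
summaries."""
import math

import numpy as np
import pandas as pd
import pytest

from merkelsim import MerkelCellModel, ModelParameters, StimulusProtocol
from merkelsim.errors import SolverError
from merkelsim.simulator import Trace, summarize_trace
from merkelsim.state import STATE_NAMES


class TestRestingState:
    def test_residual_below_tolerance(self, model, rest_state):
        _, res, _ = model._scaled_residual(rest_state)
        assert res < model.options.rest_residual_tol

    def test_resting_potential_in_physiological_band(self, rest_state):
        assert -0.08 <= rest_state.vm <= -0.04

    def test_resting_water_flux_vanishes(self, model, rest_state):
        # fixed point of the volume equation: dP = dPi
        p = model.params
        conc = rest_state.concentrations(p)
        _, _, dp = model.mechanics_at(rest_state)
        osm_in = sum(conc[k] for k in ("Na", "K", "Cl", "Ca", "A"))
        dpi = (osm_in - model.external.osmolarity) * 8.31446 * 310.0
        assert dp == pytest.approx(dpi, rel=1e-6)

    def test_rest_is_stable_under_reintegration(self, model, rest_state):
        # a further 60 s of stimulus-free integration moves Vm < 0.01 mV
        final = model.final_state(rest_state,
                                  StimulusProtocol(kind="none"), 60.0)
        assert abs(final.vm - rest_state.vm) < 1e-5

    def test_null_protocol_trace_is_flat(self, model, rest_state):
        trace = model.run_protocol(rest_state,
                                   StimulusProtocol(kind="none"), 60.0)
        vm = trace.column("Vm_mV")
        assert np.max(np.abs(vm - vm[0])) < 0.1


class TestDerivativeAssembly:
    def test_silent_membrane_freezes_amounts_and_volume(self, rest_state):
        # with every conductance, pump, transporter, store rate and the
        # water permeability zeroed, the flux-driven state components have
        # exactly zero derivative
        zeroed = {name: 0.0 for name in (
            "g_Kv1_4", "g_Kv4_2", "g_BKCa", "g_KDR", "g_Cav1_2", "g_Cav2_1",
            "g_Piezo2", "g_Na_leak", "g_K_leak", "g_Cl_leak", "g_Ca_leak",
            "P_NaKpump", "P_NKCC1", "P_KCC2", "P_Capump", "P_Cana",
            "P_pump_ER", "P_RYR", "P_leak_ER", "P_IP3", "P_MCU", "P_MNCX")}
        params = ModelParameters.preset("fig2", **zeroed).replace(
            alpha_water=0.0)
        silent = MerkelCellModel(params)
        dy = silent.derivatives(0.0, rest_state.to_vector(),
                                template=rest_state)
        for name in ("n_na", "n_k", "n_cl", "n_ca", "vm", "n_ca_er",
                     "n_ca_mt", "volume"):
            assert dy[STATE_NAMES.index(name)] == 0.0

    def test_nan_state_raises_naming_a_pathway(self, model, rest_state):
        y = rest_state.to_vector()
        y[4] = math.nan
        with pytest.raises(SolverError, match="pathway"):
            model.derivatives(0.0, y, template=rest_state)

    def test_flux_vector_reported_at_rest_balances_calcium(self, model,
                                                           rest_state):
        fv = model.compute_fluxes(rest_state)
        # at rest the ER exchange must balance exactly
        assert fv.j_serca == pytest.approx(fv.j_ip3r + fv.j_ryr, rel=1e-6)


class TestRunProtocol:
    def test_compression_raises_stress_during_ramp(self, model, rest_state):
        comp = StimulusProtocol(kind="compression", onset=0.002,
                                duration=10.0, depth=5e-6, ramp_speed=1e-3)
        trace = model.run_protocol(rest_state, comp, 0.05)
        t = trace.column("time_ms")
        sigma = trace.column("sigma_Pa")
        ramp = (t > 2.01) & (t <= 7.0)
        # stress jumps on contact and grows as the cylinder flattens; the
        # shape map is slightly non-monotone below ~2 um of depth, so
        # strict growth is asserted over the deeper part of the ramp
        assert np.all(sigma[ramp] > sigma[0] + 500.0)
        deep = (t >= 5.5) & (t <= 7.0)
        assert np.all(np.diff(sigma[deep]) > 0.0)

    def test_invalid_horizon_rejected(self, model, rest_state):
        with pytest.raises(ValueError):
            model.run_protocol(rest_state, StimulusProtocol(kind="none"), 0.0)


class TestSummaries:
    def _trace(self, t_ms, vm, ca, exo):
        n = len(t_ms)
        df = pd.DataFrame({
            "time_ms": t_ms, "Vm_mV": vm, "C_Ca_uM": ca,
            "exo_rate_per_ms": exo,
            **{c: np.zeros(n) for c in Trace.COLUMNS
               if c not in ("time_ms", "Vm_mV", "C_Ca_uM",
                            "exo_rate_per_ms")}})
        return Trace(df[list(Trace.COLUMNS)])

    def test_constant_trace_has_no_transients(self):
        t = np.linspace(0, 1000, 101)
        tr = self._trace(t, np.full(101, -55.0), np.full(101, 0.1),
                         np.full(101, 1e-5))
        s = summarize_trace(tr)
        assert s["peak_vm_mV"] == s["steady_vm_mV"] == -55.0
        assert s["ca_duration_ms"] == 0.0
        assert s["exo_duration_ms"] == 0.0
        assert s["vm_settle_ms"] == 0.0

    def test_triangular_calcium_pulse_duration(self):
        t = np.linspace(0, 1000, 2001)
        ca = np.full_like(t, 0.1)
        pulse = (t >= 200) & (t <= 400)  # 200 ms triangle
        ca[pulse] += np.interp(t[pulse], [200, 300, 400], [0, 1, 0])
        tr = self._trace(t, np.full_like(t, -55.0), ca, np.zeros_like(t))
        s = summarize_trace(tr, ca_fraction=0.0)
        assert s["ca_duration_ms"] == pytest.approx(200.0, abs=2.0)
        assert s["peak_c_ca_uM"] == pytest.approx(1.1, abs=1e-9)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            Trace(pd.DataFrame(columns=list(Trace.COLUMNS)))
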