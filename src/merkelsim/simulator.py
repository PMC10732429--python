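"""Whole-cell simulator: assembles the coupled ODE system, finds the
resting state, runs stimulus protocols and extracts summaries.

The integrated state holds 28 variables: four cytosolic ion amounts, the
membrane potential, ten voltage-gate variables, four Piezo2 variables, six
store variables (ER and mitochondrial Ca2+, IP3, its precursor, the IP3R
gates), the cell volume, the unstressed reference surface and the vesicle
count.  Everything is integrated together by a stiff adaptive solver (BDF);
protocol onsets and offsets are solver restart points.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import mechanics, membrane, piezo2, stores, vesicles
from .constants import FARADAY
from .errors import RestConvergenceError, SolverError
from .parameters import ModelParameters
from .piezo2 import Piezo2State
from .protocols import ExternalSolution, StimulusProtocol
from .state import GATE_NAMES, N_STATE, STATE_NAMES, CellState, FluxVector

logger = logging.getLogger(__name__)

_NULL_PROTOCOL = StimulusProtocol(kind="none")


#: indices solved by the fast-block Newton (all but S_ref and n_ve, whose
#: intrinsic time constants are hours and which are pinned algebraically)
_FAST = tuple(i for i in range(N_STATE) if STATE_NAMES[i] not in ("s_ref",
                                                                  "n_ve"))


def _newton_fast_block(residual: Callable[[np.ndarray], np.ndarray],
                       y0: np.ndarray, scales: np.ndarray,
                       tol: float = 1e-12, max_iter: int = 40) -> np.ndarray:
    """Damped Newton on the fast sub-block with an explicit FD Jacobian.

    ``residual`` maps the full state vector to the scaled full residual;
    only the ``_FAST`` components are solved, the two ultra-slow membrane
    -turnover variables stay frozen.  The rest system mixes eigenvalues
    over ~10 decades, which defeats generic quasi-Newton root finders; an
    explicit Jacobian with a least-squares solve (the charge-conservation
    identity makes it rank-deficient by one) handles it.
    """
    fast = list(_FAST)
    y = y0.astype(float).copy()
    r = residual(y)[fast]
    for _ in range(max_iter):
        norm2 = float(np.linalg.norm(r))
        if float(np.max(np.abs(r))) < tol:
            break
        jac = np.empty((len(fast), len(fast)))
        for kj, j in enumerate(fast):
            h = 1e-6 * scales[j]
            yp = y.copy()
            yp[j] += h
            jac[:, kj] = (residual(yp)[fast] - r) / 1e-6
        try:
            dx = np.linalg.lstsq(jac, -r, rcond=None)[0]
        except np.linalg.LinAlgError:
            break
        alpha, ok = 1.0, False
        while alpha > 1e-12:
            y_new = y.copy()
            y_new[fast] += alpha * dx * scales[fast]
            try:
                r_new = residual(y_new)[fast]
            except (ValueError, FloatingPointError):
                alpha *= 0.5
                continue
            if np.linalg.norm(r_new) < norm2:
                y, r, ok = y_new, r_new, True
                break
            alpha *= 0.5
        if not ok:
            break
    return y


def _clip01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


@dataclass
class SolverOptions:
    rtol: float = 1e-6
    atol_scale: float = 1e-10       # atol = atol_scale * per-variable scale
    method: str = "BDF"
    sample_points: int = 2000       # trace grid size over the horizon
    rest_horizon: float = 600.0     # s of relaxation toward rest
    rest_residual_tol: float = 1e-8  # max-norm of the scaled derivative, 1/s
    vm_band: tuple[float, float] = (-0.08, -0.04)  # sanity band for resting Vm


class Trace:
    """Time-indexed record of selected state variables and summaries.

    ``data`` is a pandas DataFrame in display units (time ms, potentials mV,
    cytosolic/store concentrations uM, bulk ions mM, stress Pa, volume um^3,
    exocytosis rate vesicles/ms).
    """

    COLUMNS = ("time_ms", "Vm_mV", "C_Ca_uM", "C_Ca_ER_uM", "C_Ca_MT_uM",
               "C_IP3_uM", "C_Na_mM", "C_K_mM", "C_Cl_mM", "sigma_Pa",
               "V_um3", "S_ref_um2", "n_ve", "exo_rate_per_ms", "d_um")

    def __init__(self, data: pd.DataFrame, meta: dict | None = None):
        if data.empty:
            raise ValueError("empty trace")
        t = data["time_ms"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError("trace time grid must be strictly increasing")
        self.data = data
        self.meta = meta or {}

    def __len__(self) -> int:
        return len(self.data)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def summarize_trace(trace: Trace, ca_fraction: float = 0.1,
                    exo_factor: float = 2.0,
                    steady_window: float = 0.1) -> dict[str, float]:
    """Scalar descriptors of a trace.

    * ``peak_vm_mV`` / ``steady_vm_mV``: extremum of Vm (largest excursion
      from the initial value) and mean over the trailing window.
    * ``peak_c_ca_uM`` and ``ca_duration_ms``: peak cytosolic Ca2+ and the
      time spent above baseline + ``ca_fraction``*(peak - baseline).
    * ``exo_duration_ms``: time the exocytosis rate exceeds ``exo_factor``
      times its value in the first sample.
    * ``vm_settle_ms``: the standard 10-90% rise time of the
      membrane-potential step from its initial to its steady value (slow
      residual drift of Vm alongside the Ca2+ transient does not count;
      0 when there is no net step).

    The thresholds used are returned alongside the values.
    """
    t = trace.column("time_ms")
    vm = trace.column("Vm_mV")
    ca = trace.column("C_Ca_uM")
    exo = trace.column("exo_rate_per_ms")
    dt = np.diff(t, append=t[-1] + (t[-1] - t[-2] if len(t) > 1 else 0.0))

    i_ext = int(np.argmax(np.abs(vm - vm[0])))
    peak_vm = vm[i_ext]
    n_tail = max(1, int(len(t) * steady_window))
    steady_vm = float(np.mean(vm[-n_tail:]))

    ca_base = ca[0]
    peak_ca = float(np.max(ca))
    ca_thr = ca_base + ca_fraction * (peak_ca - ca_base)
    ca_duration = float(np.sum(dt[ca > ca_thr])) if peak_ca > ca_base else 0.0

    exo_thr = exo_factor * exo[0]
    exo_duration = float(np.sum(dt[exo > exo_thr]))

    step = steady_vm - vm[0]
    if abs(step) > 0:
        progress = (vm - vm[0]) / step
        hit10 = progress >= 0.10
        hit90 = progress >= 0.90
        if hit10.any() and hit90.any():
            vm_settle = float(t[int(np.argmax(hit90))]
                              - t[int(np.argmax(hit10))])
        else:
            vm_settle = float(t[-1] - t[0])
    else:
        vm_settle = 0.0

    return {
        "peak_vm_mV": float(peak_vm), "steady_vm_mV": steady_vm,
        "peak_c_ca_uM": peak_ca, "ca_duration_ms": ca_duration,
        "ca_threshold_uM": float(ca_thr), "exo_duration_ms": exo_duration,
        "exo_threshold_per_ms": float(exo_thr), "vm_settle_ms": vm_settle,
        "ca_fraction": ca_fraction, "exo_factor": exo_factor,
    }


class MerkelCellModel:
    """The assembled whole-cell model.

    Parameters
    ----------
    params : ModelParameters
        Full SI parameter set (see :mod:`merkelsim.parameters`).
    external : ExternalSolution, optional
        Baseline bath composition; defaults to the configured parameter
        values (145 Na / 5 K / 110 Cl / 2 Ca mM plus any mannitol).
    """

    def __init__(self, params: ModelParameters,
                 external: ExternalSolution | None = None,
                 options: SolverOptions | None = None):
        self.params = params
        self.external = external or ExternalSolution(
            c_na=params.C_Na_out, c_k=params.C_K_out, c_cl=params.C_Cl_out,
            c_ca=params.C_Ca_out, c_mannitol=params.C_mannitol_out,
            temperature=params.temperature)
        self.options = options or SolverOptions()

    # ------------------------------------------------------------------
    # fluxes
    # ------------------------------------------------------------------
    def compute_fluxes(self, state: CellState,
                       external: ExternalSolution | None = None) -> FluxVector:
        """Every pathway's molar flux density for the given state."""
        p = self.params
        ext = external or self.external
        conc = state.concentrations(p)
        t_k = ext.temperature
        c_na, c_k, c_cl, c_ca = conc["Na"], conc["K"], conc["Cl"], conc["Ca"]
        vm = state.vm
        # tolerate solver-grade excursions of the bounded variables
        g = {k: _clip01(v) for k, v in state.gates.items()}
        pz_o = _clip01(state.piezo2.o)
        pz_h = _clip01(state.piezo2.h_slow)

        e_na = membrane.nernst_potential(c_na, ext.c_na, 1, t_k)
        e_k = membrane.nernst_potential(c_k, ext.c_k, 1, t_k)
        e_cl = membrane.nernst_potential(c_cl, ext.c_cl, -1, t_k)
        e_ca = membrane.nernst_potential(c_ca, ext.c_ca, 2, t_k)

        h_ca = 1.0 / (1.0 + (c_ca / p.K_hCa) ** 4)
        kv14 = {"m": g["m_kv14"], "h_fast": g["hf_kv14"], "h_slow": g["hs_kv14"]}
        kv42 = {"m": g["m_kv42"], "h": g["h_kv42"]}
        cav12 = {"m": g["m_cav12"], "h": g["h_cav12"], "hCa": h_ca}

        fv = FluxVector(
            j_kv14=membrane.voltage_gated_flux("Kv1.4", kv14, vm, e_k, p.g_Kv1_4),
            j_kv42=membrane.voltage_gated_flux("Kv4.2", kv42, vm, e_k, p.g_Kv4_2),
            j_bkca=membrane.voltage_gated_flux("BKCa", {"n": g["n_bk"]}, vm, e_k, p.g_BKCa),
            j_kdr=membrane.voltage_gated_flux("KDR", {"n": g["n_kdr"]}, vm, e_k, p.g_KDR),
            j_cav12=membrane.voltage_gated_flux("Cav1.2", cav12, vm, e_ca, p.g_Cav1_2),
            j_cav21=membrane.voltage_gated_flux("Cav2.1", {"n": g["n_cav21"]}, vm, e_ca, p.g_Cav2_1),
            j_piezo2=membrane.piezo2_flux(pz_o, pz_h, vm, p.g_Piezo2,
                                          p.E_Piezo2),
            j_na_leak=membrane.leak_flux("Na", vm, e_na, p.g_Na_leak),
            j_k_leak=membrane.leak_flux("K", vm, e_k, p.g_K_leak),
            j_cl_leak=membrane.leak_flux("Cl", vm, e_cl, p.g_Cl_leak),
            j_ca_leak=membrane.leak_flux("Ca", vm, e_ca, p.g_Ca_leak),
            j_nak=membrane.nak_pump_flux(c_na, c_k, p.P_NaKpump, p),
            j_nkcc1=membrane.nkcc1_flux(c_na, c_k, c_cl, ext.c_na, ext.c_k,
                                        ext.c_cl, p.P_NKCC1),
            j_kcc2=membrane.kcc2_flux(c_k, c_cl, ext.c_k, ext.c_cl, p.P_KCC2),
            j_pmca=membrane.pmca_flux(c_ca, p.P_Capump, p),
            j_ncx=membrane.ncx_flux(vm, c_na, c_ca, ext.c_na, ext.c_ca,
                                    t_k, p.P_Cana, p),
            j_serca=stores.serca_flux(c_ca, p.P_pump_ER, p),
            j_ryr=stores.ryr_flux(c_ca, conc["Ca_ER"], p.P_RYR, p),
            j_ip3r=stores.ip3r_flux(c_ca, conc["Ca_ER"], state.c_ip3,
                                    _clip01(state.m_ip3), _clip01(state.h_ip3),
                                    p.P_leak_ER, p.P_IP3, p),
            j_mcu=stores.mito_fluxes(c_ca, conc["Ca_MT"], p.P_MCU, p.P_MNCX, p)[0],
            j_mncx=stores.mito_fluxes(c_ca, conc["Ca_MT"], p.P_MCU, p.P_MNCX, p)[1],
        )
        for name, value in zip(fv._fields, fv):
            if not math.isfinite(value):
                raise SolverError(f"non-finite flux in pathway {name}")
        return fv

    # ------------------------------------------------------------------
    # geometry / mechanics at a state
    # ------------------------------------------------------------------
    def mechanics_at(self, state: CellState) -> tuple[mechanics.Geometry, float, float]:
        """(geometry, cortex stress sigma, hydrostatic pressure dP)."""
        p = self.params
        geo = mechanics.compressed_geometry(state.volume, p.r_ini,
                                            state.indentation)
        sigma = mechanics.cortex_stress(geo.area, state.s_ref,
                                        p.K_cortex, p.sigma_a)
        delta_p = mechanics.hydrostatic_pressure(sigma, geo.radius, p.h_cortex)
        return geo, sigma, delta_p

    # ------------------------------------------------------------------
    # the right-hand side
    # ------------------------------------------------------------------
    def derivatives(self, t: float, y: np.ndarray,
                    protocol: StimulusProtocol = _NULL_PROTOCOL,
                    template: CellState | None = None) -> np.ndarray:
        """d(state)/dt for the packed state vector ``y`` at time ``t``."""
        p = self.params
        if template is None:
            template = self._blank_state()
        depth, phase = protocol.indentation(t)
        ext = protocol.external(t, self.external)
        # sanitise solver trial values: gates into [0,1], amounts/areas
        # positive (floors only bite on non-physical probe points)
        y = np.asarray(y, dtype=float)
        yc = y.copy()
        yc[5:19] = np.clip(yc[5:19], 0.0, 1.0)
        yc[25] = min(max(yc[25], (p.V_ER + p.V_MT) * 1.05), 1e-12)
        v_cyt = yc[25] - p.V_ER - p.V_MT
        c_cap = 1e5  # mol/m^3; orders beyond physical, finite for probes
        for i in range(4):
            yc[i] = min(max(yc[i], 1e-9 * v_cyt), c_cap * v_cyt)
        yc[4] = min(max(yc[4], -10.0), 10.0)
        yc[19] = min(max(yc[19], 1e-9 * p.V_ER), c_cap * p.V_ER)
        yc[20] = min(max(yc[20], 0.0), c_cap * p.V_MT)
        yc[21] = min(max(yc[21], 0.0), c_cap)
        yc[22] = min(max(yc[22], 0.0), c_cap)
        yc[26] = min(max(yc[26], 1e-14), 1e-6)
        yc[27] = min(max(yc[27], 0.0), 1e9)
        state = template.with_vector(yc, phase=phase, indentation=depth)

        v_cyt = state.cytosol_volume(p)
        conc = state.concentrations(p)
        fv = self.compute_fluxes(state, ext)
        geo, sigma, delta_p = self.mechanics_at(state)

        # --- mechanics / volume ---
        osm_in = conc["Na"] + conc["K"] + conc["Cl"] + conc["Ca"] + conc["A"]
        delta_pi = mechanics.osmotic_pressure_difference(
            osm_in, ext.osmolarity, ext.temperature)
        j_w = mechanics.water_flux(delta_p, delta_pi, p.alpha_water)
        d_volume = geo.area * j_w

        # --- ion balances (canonical positive-inward fluxes) ---
        s_ref = state.s_ref
        i_app = protocol.applied_current(t)
        d_na = s_ref * (-3.0 * fv.j_nak + fv.j_nkcc1 - 3.0 * fv.j_ncx
                        + fv.j_na_leak)
        # the pipette current is carried by K+ from the pipette solution
        # (a sustained injection otherwise drains the cell's entire K+
        # content, which a whole-cell pipette in reality replenishes)
        d_k = s_ref * (fv.j_kv14 + fv.j_kv42 + fv.j_kdr + fv.j_bkca
                       + 2.0 * fv.j_nak + fv.j_nkcc1 - fv.j_kcc2
                       + fv.j_k_leak) + i_app / FARADAY
        d_cl = s_ref * (2.0 * fv.j_nkcc1 - fv.j_kcc2 + fv.j_cl_leak)
        d_ca = (s_ref * (fv.j_cav12 + fv.j_cav21 - fv.j_pmca + fv.j_ncx
                         + fv.j_piezo2 + fv.j_ca_leak)
                + p.S_ER * (fv.j_ip3r + fv.j_ryr - fv.j_serca)
                + p.S_MT / (1.0 + p.beta_MT) * (fv.j_mncx - fv.j_mcu))

        # --- membrane potential (electrogenic bookkeeping) ---
        electro = (fv.j_kv14 + fv.j_kv42 + fv.j_kdr + fv.j_bkca
                   + fv.j_k_leak + fv.j_na_leak - fv.j_cl_leak
                   + 2.0 * (fv.j_cav12 + fv.j_cav21 + fv.j_piezo2
                            + fv.j_ca_leak)
                   - fv.j_nak - fv.j_ncx - 2.0 * fv.j_pmca)
        d_vm = (FARADAY / p.C_m) * electro + i_app / (p.C_m * s_ref)

        # --- gating ---
        dy = np.empty(N_STATE)
        dy[0], dy[1], dy[2], dy[3], dy[4] = d_na, d_k, d_cl, d_ca, d_vm
        c_ca = conc["Ca"]
        i = 5
        for channel in membrane.CHANNELS:
            rates = membrane.gating_rates(channel, state.vm, c_ca, p)
            for gate_name, kin in rates.items():
                if kin.tau == 0.0:   # algebraic factor (Cav1.2 hCa)
                    continue
                dy[i] = (kin.steady - yc[i]) / kin.tau
                i += 1
        assert i == 15

        # --- Piezo2 ---
        dy[15:19] = piezo2.derivatives(yc[15], yc[16], yc[17], yc[18],
                                       sigma, phase, p)

        # --- stores ---
        dn_er, dn_mt = stores.store_balances(fv.j_serca, fv.j_ip3r, fv.j_ryr,
                                             fv.j_mcu, fv.j_mncx, p)
        dy[19], dy[20] = dn_er, dn_mt
        d_ip3, d_pre = stores.ip3_turnover(c_ca, max(state.c_ip3, 0.0),
                                           max(state.c_preip3, 0.0), p)
        dy[21], dy[22] = d_ip3, d_pre
        dy[23], dy[24] = stores.ip3r_gate_derivatives(
            c_ca, _clip01(state.m_ip3), _clip01(state.h_ip3), p)

        # --- volume / surface / vesicles ---
        dy[25] = d_volume
        dy[26] = vesicles.surface_turnover(c_ca, max(state.n_ve, 0.0), sigma, p)
        dy[27] = vesicles.vesicle_derivative(c_ca, max(state.n_ve, 0.0), p)
        return dy

    # ------------------------------------------------------------------
    # resting state
    # ------------------------------------------------------------------
    def _blank_state(self) -> CellState:
        p = self.params
        v0 = 4.0 / 3.0 * math.pi * p.r_ini ** 3
        geo = mechanics.sphere_geometry(v0)
        sigma0 = mechanics.cortex_stress(geo.area, geo.area, p.K_cortex, p.sigma_a)
        return CellState(
            n_na=0.0, n_k=0.0, n_cl=0.0, n_ca=0.0, vm=-0.06,
            gates={name: 0.0 for name in GATE_NAMES},
            piezo2=Piezo2State(c=piezo2.c_inf(sigma0, p), o=0.0,
                               inact=piezo2.in_inf(sigma0, p),
                               h_slow=piezo2.h_slow_inf(sigma0, p)),
            n_ca_er=0.0, n_ca_mt=0.0, c_ip3=0.0, c_preip3=0.0,
            m_ip3=0.0, h_ip3=0.0, volume=v0, s_ref=geo.area, n_ve=500.0)

    def initial_guess(self, c_na: float = 10.0, c_k: float = 140.0,
                      c_cl: float = 10.0, c_ca: float = 1e-4,
                      vm: float = -0.06) -> CellState:
        """Physiological starting point with the impermeant species solved
        for simultaneous osmotic balance and bulk electroneutrality."""
        p = self.params
        ext = self.external
        base = self._blank_state()
        v_cyt = base.volume - p.V_ER - p.V_MT
        geo = mechanics.sphere_geometry(base.volume)
        sigma0 = mechanics.cortex_stress(geo.area, base.s_ref, p.K_cortex, p.sigma_a)
        dp0 = mechanics.hydrostatic_pressure(sigma0, geo.radius, p.h_cortex)
        c_a, z_a = mechanics.solve_impermeant_species(
            c_na, c_k, c_cl, c_ca, ext.osmolarity, dp0, ext.temperature)
        gates = {}
        for channel in membrane.CHANNELS:
            short = {"Kv1.4": "kv14", "Kv4.2": "kv42", "BKCa": "bk",
                     "KDR": "kdr", "Cav1.2": "cav12", "Cav2.1": "cav21"}[channel]
            for gname, kin in membrane.gating_rates(channel, vm, c_ca, p).items():
                if kin.tau == 0.0:
                    continue
                key = {"m": f"m_{short}", "h": f"h_{short}",
                       "h_fast": f"hf_{short}", "h_slow": f"hs_{short}",
                       "n": f"n_{short}"}[gname]
                gates[key] = kin.steady
        m_inf, h_inf = stores.ip3r_rates(c_ca, p)
        state = CellState(
            n_na=c_na * v_cyt, n_k=c_k * v_cyt, n_cl=c_cl * v_cyt,
            n_ca=c_ca * v_cyt, vm=vm, gates=gates, piezo2=base.piezo2,
            n_ca_er=c_ca * p.V_ER, n_ca_mt=c_ca * p.V_MT,
            c_ip3=1e-4, c_preip3=5e-3, m_ip3=m_inf, h_ip3=h_inf,
            volume=base.volume, s_ref=base.s_ref, n_ve=500.0,
            n_a=c_a * v_cyt, z_a=z_a)
        state.validate(p)
        return state

    def _scaled_residual(self, state: CellState) -> tuple[np.ndarray, float, str]:
        f = self.derivatives(0.0, state.to_vector(), _NULL_PROTOCOL, state)
        scaled = f / state.scales()
        worst = int(np.argmax(np.abs(scaled)))
        return scaled, float(np.max(np.abs(scaled))), STATE_NAMES[worst]

    def _presolve_slow_variables(self, state: CellState) -> CellState:
        """Jump the very slow vesicle/surface variables to their algebraic
        fixed point at the current Ca2+ level (their own time constants are
        hours, far beyond any useful relaxation horizon)."""
        p = self.params
        c_ca = state.concentrations(p)["Ca"]

        def f(n):
            return vesicles.vesicle_derivative(c_ca, n, p)
        try:
            n_star = brentq(f, 0.0, 1e6, xtol=1e-9)
        except ValueError:
            return state
        exo = vesicles.exocytosis_rate(c_ca, n_star, p)
        if not 0.0 < exo < p.k_endo:
            return state
        sigma_star = p.sigma_ve_s + p.sigma_ve_f * math.log(p.k_endo / exo - 1.0)
        ratio = 1.0 + 2.0 * (sigma_star + p.sigma_a) / p.K_cortex
        if ratio <= 0:
            return state
        geo = mechanics.sphere_geometry(state.volume)
        y = state.to_vector()
        y[26] = geo.area / ratio
        y[27] = n_star
        # park the Piezo2 machinery at its steady point for the new stress
        y[15] = piezo2.c_inf(sigma_star, p)
        y[16] = 0.0
        y[17] = piezo2.in_inf(sigma_star, p)
        y[18] = piezo2.h_slow_inf(sigma_star, p)
        return state.with_vector(y)

    def initialize_rest(self, guess: CellState | None = None) -> CellState:
        """Relax the full system with no stimulus to its fixed point.

        Runs a long stiff relaxation, jumps the ultra-slow vesicle/surface
        pair to their algebraic balance, relaxes again, then polishes with
        a Newton solve on the scaled right-hand side.  Fails if the scaled
        derivative's max-norm cannot be brought below the configured
        tolerance.
        """
        opts = self.options
        state = guess or self.initial_guess()
        state = self._relax(state, opts.rest_horizon)

        scales = state.scales()

        def residual(y):
            r = self.derivatives(0.0, y, _NULL_PROTOCOL, state) / scales
            # the short-inactivated Piezo2 fraction has no feedback under
            # loading kinetics (zero Jacobian column); pin it with the
            # simplex constraint C + O + In = 1 instead of its derivative
            r[17] = y[15] + y[16] + y[17] - 1.0
            return r

        # alternate: algebraic balance of the ultra-slow membrane-turnover
        # pair (+ Piezo2 re-park), then Newton on everything else; the
        # coupling between the two blocks is weak, so this converges in a
        # couple of cycles.
        polished = state
        res_norm, worst = math.inf, ""
        for cycle in range(5):
            polished = self._presolve_slow_variables(polished)
            y = _newton_fast_block(residual, polished.to_vector(), scales)
            polished = polished.with_vector(y)
            _, res_norm, worst = self._scaled_residual(polished)
            if res_norm < opts.rest_residual_tol:
                break
            # near the fixed point the stiff solver takes huge steps, so an
            # escalated extra relaxation is nearly free and closes slow
            # (hundreds of seconds) ion drifts that Newton struggles with
            polished = self._relax(polished, opts.rest_horizon * 2 ** (cycle + 2))
        if res_norm > opts.rest_residual_tol:
            raise RestConvergenceError(
                f"rest state not converged: scaled residual {res_norm:.3e} "
                f"(largest component: {worst})")
        polished.validate(self.params)
        lo, hi = opts.vm_band
        if not lo <= polished.vm <= hi:
            raise RestConvergenceError(
                f"resting Vm {polished.vm * 1e3:.2f} mV outside the "
                f"configured band [{lo * 1e3:.0f}, {hi * 1e3:.0f}] mV")
        logger.info("rest state: Vm=%.2f mV, C_Ca=%.4f uM, residual=%.2e",
                    polished.vm * 1e3,
                    polished.concentrations(self.params)["Ca"] * 1e3, res_norm)
        return polished

    def _relax(self, state: CellState, horizon: float) -> CellState:
        y = self._integrate(state, _NULL_PROTOCOL, horizon,
                            t_eval=np.array([horizon]))[1][:, -1]
        return state.with_vector(y)

    # ------------------------------------------------------------------
    # protocol runs
    # ------------------------------------------------------------------
    def _integrate(self, state: CellState, protocol: StimulusProtocol,
                   horizon: float, t_eval: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
        opts = self.options
        scales = state.scales()
        atol = scales * opts.atol_scale
        edges = [0.0, *protocol.breakpoints(horizon), horizon]
        ts: list[np.ndarray] = []
        ys: list[np.ndarray] = []
        y0 = state.to_vector()
        n_steps = 0
        for a, b in zip(edges[:-1], edges[1:]):
            pts = t_eval[(t_eval > a) & (t_eval <= b)]
            seg_eval = np.unique(np.concatenate([pts, [b]]))
            sol = solve_ivp(self.derivatives, (a, b), y0,
                            method=opts.method, rtol=opts.rtol, atol=atol,
                            t_eval=seg_eval, args=(protocol, state))
            if not sol.success:
                raise SolverError(
                    f"solver failed in [{a:g}, {b:g}] s at t={sol.t[-1] if sol.t.size else a:g} s: "
                    f"{sol.message}")
            keep = np.isin(sol.t, pts)
            ts.append(sol.t[keep])
            ys.append(sol.y[:, keep])
            y0 = sol.y[:, -1]
            n_steps += sol.t.size
        t_all = np.concatenate([[0.0], *ts])
        y_all = np.concatenate([state.to_vector()[:, None], *ys], axis=1)
        logger.debug("integrated %d segments, %d samples", len(edges) - 1,
                     t_all.size)
        return t_all, y_all

    def run_protocol(self, initial: CellState, protocol: StimulusProtocol,
                     horizon: float) -> Trace:
        """Integrate a stimulus protocol from a rest state and return a Trace."""
        if horizon <= 0:
            raise ValueError("horizon must be positive")
        opts = self.options
        p = self.params
        t_eval = np.linspace(0.0, horizon, opts.sample_points + 1)[1:]
        t_all, y_all = self._integrate(initial, protocol, horizon, t_eval)

        rows = []
        for t, y in zip(t_all, y_all.T):
            depth, phase = protocol.indentation(t)
            st = initial.with_vector(y, phase=phase, indentation=depth)
            conc = st.concentrations(p)
            _, sigma, _ = self.mechanics_at(st)
            exo = vesicles.exocytosis_rate(conc["Ca"], max(st.n_ve, 0.0), p)
            rows.append((
                t * 1e3, st.vm * 1e3, conc["Ca"] * 1e3, conc["Ca_ER"] * 1e3,
                conc["Ca_MT"] * 1e3, st.c_ip3 * 1e3, conc["Na"], conc["K"],
                conc["Cl"], sigma, st.volume * 1e18, st.s_ref * 1e12,
                st.n_ve, exo * 1e-3, depth * 1e6,
            ))
        df = pd.DataFrame(rows, columns=Trace.COLUMNS)
        meta = {"kind": protocol.kind, "horizon_s": horizon,
                "rtol": opts.rtol, "method": opts.method}
        return Trace(df, meta)

    def final_state(self, initial: CellState, protocol: StimulusProtocol,
                    horizon: float) -> CellState:
        """State at the end of a protocol run (no trace bookkeeping)."""
        _, y = self._integrate(initial, protocol, horizon,
                               t_eval=np.array([horizon]))
        depth, phase = protocol.indentation(horizon)
        return initial.with_vector(y[:, -1], phase=phase, indentation=depth)
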