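"""Plasma-membrane channels, pumps, cotransporters and exchangers.

Gating kinetics follow the Hodgkin–Huxley form dx/dt = (x_inf − x)/tau_x.
The steady-state/time-constant expressions below are voltage-dependent fits
(voltages in mV, time constants in ms inside the formulas; the public
functions take and return SI).

Sign convention
---------------
Every flux returned here is a molar flux density in mol m^-2 s^-1,
**positive into the cytosol**.  For a cation conductance this is
J = -g * p_open * (Vm - E)/F; for the Cl- leak the inward anion flux is
J = +g * (Vm - E_Cl)/F.  Electrogenic bookkeeping (which fluxes carry how
much charge) lives in :mod:`merkelsim.simulator`.
"""
from __future__ import annotations

import math
from typing import NamedTuple

from ._math import logistic, safe_exp
from .constants import FARADAY, GAS_CONSTANT
from .parameters import ModelParameters

CHANNELS = ("Kv1.4", "Kv4.2", "BKCa", "KDR", "Cav1.2", "Cav2.1")
LEAK_IONS = ("Na", "K", "Cl", "Ca")


def nernst_potential(c_in: float, c_out: float, z: int, temperature: float) -> float:
    """Equilibrium (Nernst) potential in volts.

    E = -(RT/zF) ln(c_in/c_out).  Concentrations in any common unit.
    """
    if c_in <= 0 or c_out <= 0:
        raise ValueError("concentrations must be positive for a Nernst potential")
    if z == 0:
        raise ValueError("valence must be non-zero")
    return -(GAS_CONSTANT * temperature) / (z * FARADAY) * math.log(c_in / c_out)


class GateKinetics(NamedTuple):
    steady: float
    tau: float  # s


def _kv14_m(v: float) -> GateKinetics:
    return GateKinetics(logistic((v + 23.12) / 11.46),
                        (0.6 + safe_exp(-(v + 12.02) / 25.87)) * 1e-3)


def _kv_h_inf(v: float) -> float:
    # shared inactivation steady state of the two A-type K+ channels
    return logistic(-(v + 44.36) / 2.73)


def gating_rates(channel_id: str, vm: float, c_ca: float,
                 params: ModelParameters) -> dict[str, GateKinetics]:
    """Steady values and time constants of a channel's dynamic gates.

    Parameters
    ----------
    channel_id : one of ``CHANNELS``.
    vm : membrane potential, V.
    c_ca : cytosolic Ca2+ concentration, mol/m^3 (used by BKCa and by the
        algebraic Ca-inactivation factor of Cav1.2).

    Returns
    -------
    dict mapping gate name to (steady value, time constant in s).  Cav1.2
    additionally reports ``hCa``, the instantaneous Ca-dependent
    inactivation 1/(1+(C_Ca/K_hCa)^4), with tau 0 (algebraic).
    """
    v = vm * 1e3  # mV
    if channel_id == "Kv1.4":
        return {
            "m": _kv14_m(v),
            "h_fast": GateKinetics(_kv_h_inf(v), (-0.1086 * v + 48.67) * 1e-3),
            "h_slow": GateKinetics(_kv_h_inf(v), 17.28e-3),
        }
    if channel_id == "Kv4.2":
        return {
            "m": GateKinetics(logistic((v - 17.66) / 22.75),
                              (3.0 + 2.0 * safe_exp(-(v - 19.68) / 41.23)) * 1e-3),
            "h": GateKinetics(_kv_h_inf(v),
                              (10.0 + safe_exp(-(v - 488.0) / 165.84)) * 1e-3),
        }
    if channel_id == "BKCa":
        if c_ca <= 0:
            raise ValueError("BKCa gating requires a positive Ca2+ concentration")
        p_ca = math.log10(c_ca / params.K_BKCa)
        v_half = -43.3 * p_ca - 110.0
        sf = 33.88 * math.exp(-(((p_ca + 5.42) / 2.2) ** 2))
        n_inf = logistic((v - v_half) / sf)
        tau = (0.75 + 5.55 * safe_exp(v / 42.91) - 0.12 * v) * 1e-3
        return {"n": GateKinetics(n_inf, tau)}
    if channel_id == "KDR":
        return {
            "n": GateKinetics(logistic((v + 33.3) / 8.7),
                              (2.2 + 20.0 * math.exp(-(((v + 13.03) / 29.55) ** 2))) * 1e-3),
        }
    if channel_id == "Cav1.2":
        if c_ca <= 0:
            raise ValueError("Cav1.2 gating requires a positive Ca2+ concentration")
        h_ca = 1.0 / (1.0 + (c_ca / params.K_hCa) ** 4)
        return {
            "m": GateKinetics(logistic((v - 8.46) / 4.26),
                              (2.11 + 3.86 * math.exp(-2.0 * ((v + 10.0) / 16.02) ** 2)) * 1e-3),
            "h": GateKinetics(logistic(-(v + 42.52) / 7.48),
                              (825.80 + 637.91 * math.exp(-2.0 * (v / 39.75) ** 2)) * 1e-3),
            "hCa": GateKinetics(h_ca, 0.0),
        }
    if channel_id == "Cav2.1":
        return {
            "n": GateKinetics(logistic((v + 5.1) / 3.1),
                              (0.35 + 5.51 * math.exp(-2.0 * ((v + 9.73) / 18.14) ** 2)) * 1e-3),
        }
    raise ValueError(f"unknown channel {channel_id!r}")


def open_probability(channel_id: str, gates: dict[str, float]) -> float:
    """Open-probability product of a voltage-gated channel.

    ``gates`` maps gate names to current values (Cav1.2 needs the algebraic
    ``hCa`` included).
    """
    for name, x in gates.items():
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"gating variable {name} out of [0,1]: {x}")
    if channel_id == "Kv1.4":
        return gates["m"] ** 4 * (0.7 * gates["h_fast"] + 0.3 * gates["h_slow"])
    if channel_id == "Kv4.2":
        return gates["m"] * gates["h"]
    if channel_id in ("BKCa", "KDR", "Cav2.1"):
        return gates["n"]
    if channel_id == "Cav1.2":
        return gates["m"] * gates["h"] * gates["hCa"]
    raise ValueError(f"unknown channel {channel_id!r}")


def voltage_gated_flux(channel_id: str, gates: dict[str, float], vm: float,
                       reversal: float, g: float) -> float:
    """Molar flux density through a voltage-gated channel, positive inward."""
    if g < 0:
        raise ValueError("conductance must be non-negative")
    return -g * open_probability(channel_id, gates) * (vm - reversal) / FARADAY


def piezo2_flux(o: float, h_slow: float, vm: float, g_piezo2: float,
                e_piezo2: float) -> float:
    """Ca2+ molar flux density through Piezo2, positive inward.

    Only open channels whose slow-availability factor is high conduct; the
    whole flux is booked as Ca2+ by the balance equations.
    """
    return -g_piezo2 * o * h_slow * (vm - e_piezo2) / FARADAY


def leak_flux(ion_id: str, vm: float, e_ion: float, g_leak: float) -> float:
    """Ohmic leak molar flux density, positive = ion entering the cytosol."""
    if g_leak < 0:
        raise ValueError("leak conductance must be non-negative")
    if ion_id not in LEAK_IONS:
        raise ValueError(f"unknown leak ion {ion_id!r}")
    j = -g_leak * (vm - e_ion) / FARADAY
    # for the anion the inward MOLAR flux has the opposite sign of the
    # inward-cation form (same ohmic current, opposite carrier charge)
    return -j if ion_id == "Cl" else j


def nak_pump_flux(c_na: float, c_k: float, p: float, params: ModelParameters) -> float:
    """Na+/K+-ATPase cycle rate density (cycles mol m^-2 s^-1, always >= 0).

    Consumers book 3 Na+ out, 2 K+ in and one net charge out per cycle.
    """
    if c_na <= 0 or c_k <= 0:
        raise ValueError("pump flux needs positive Na+ and K+ concentrations")
    return (p * (c_na / (c_na + params.K_Na_NaK)) ** 3
            * (params.K_K_NaK / (params.K_K_NaK + c_k)) ** 2)


def nkcc1_flux(c_na: float, c_k: float, c_cl: float, c_na_out: float,
               c_k_out: float, c_cl_out: float, p: float) -> float:
    """Na-K-2Cl cotransport rate density; positive = 1 Na + 1 K + 2 Cl inward.

    Electro-neutral: contributes nothing to the charge balance.
    """
    return p * (c_na_out * c_k_out * c_cl_out ** 2 - c_na * c_k * c_cl ** 2)


def kcc2_flux(c_k: float, c_cl: float, c_k_out: float, c_cl_out: float,
              p: float) -> float:
    """K-Cl cotransport rate density; positive = 1 K + 1 Cl extruded.

    Product-difference driving force normalised by the external product:
    zero when C_K*C_Cl equals C_K,out*C_Cl,out, extruding when the internal
    product is larger.  Electro-neutral.
    """
    if c_k_out <= 0 or c_cl_out <= 0:
        raise ValueError("KCC2 needs positive external K+ and Cl- concentrations")
    return p * (c_k * c_cl / (c_k_out * c_cl_out) - 1.0)


def pmca_flux(c_ca: float, p: float, params: ModelParameters) -> float:
    """Plasma-membrane Ca2+-ATPase rate density (Ca2+ efflux, >= 0)."""
    if c_ca < 0:
        raise ValueError("Ca2+ concentration must be non-negative")
    if c_ca == 0.0:
        return 0.0
    return p / (1.0 + (params.K_Capump / c_ca) ** 2)


def ncx_flux(vm: float, c_na: float, c_ca: float, c_na_out: float,
             c_ca_out: float, temperature: float, p: float,
             params: ModelParameters) -> float:
    """Na+/Ca2+ exchanger cycle rate density.

    Positive = reverse mode (1 Ca2+ in, 3 Na+ out, net one charge out per
    cycle); negative = forward mode (Ca2+ extrusion), the resting direction.
    """
    if min(c_na, c_ca, c_na_out, c_ca_out) <= 0:
        raise ValueError("NCX needs positive concentrations")
    eta, ksat = params.eta_NCX, params.ksat_NCX
    vfrt = vm * FARADAY / (GAS_CONSTANT * temperature)
    num = (safe_exp(eta * vfrt) * c_na ** 3 * c_ca_out
           - safe_exp((eta - 1.0) * vfrt) * c_na_out ** 3 * c_ca)
    den = ((params.K_mNa ** 3 + c_na_out ** 3) * (params.K_mCa + c_ca_out)
           * (1.0 + ksat * safe_exp((eta - 1.0) * vfrt)))
    return p * num / den
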