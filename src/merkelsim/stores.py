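"""Intracellular Ca2+ stores: ER (SERCA, RyR, IP3R) and mitochondria
(MCU uptake, mitochondrial Na+/Ca2+ exchange), plus IP3 / IP3-precursor
turnover.

Fluxes across the ER membrane are molar flux densities (mol m^-2 s^-1)
referred to the ER surface S_ER; positive SERCA loads the ER, positive
RyR/IP3R release into the cytosol.  Mitochondrial fluxes are referred to
S_MT and damped by the membrane buffer factor 1/(1+beta_MT) in the store
balance.
"""
from __future__ import annotations

import math

from ._math import logistic
from .parameters import ModelParameters


def serca_flux(c_ca: float, p: float, params: ModelParameters) -> float:
    """ER Ca2+-ATPase uptake (cytosol -> ER), Hill coefficient 2."""
    if c_ca < 0:
        raise ValueError("negative Ca2+ concentration")
    if c_ca == 0.0:
        return 0.0
    return p / (1.0 + (params.K_ERpump / c_ca) ** 2)


def ryr_flux(c_ca: float, c_ca_er: float, p: float,
             params: ModelParameters) -> float:
    """Ryanodine-receptor Ca2+-induced Ca2+ release (ER -> cytosol).

    Gated by cytosolic Ca2+ with a hard threshold at K_s_RYR (the threshold
    concentration itself is on the closed branch); above it, a sigmoidal
    open fraction times the ER-cytosol gradient.
    """
    if p == 0.0 or c_ca <= params.K_s_RYR:
        return 0.0
    gate = logistic((c_ca - params.K_s_RYR) / params.K_f_RYR)
    # the piecewise rate law jumps from 0 to half-max at the threshold;
    # bridge the jump over a band 1e-3*K_f wide (~4e-5 uM, far below any
    # physical resolution) so the stiff solver sees a C1-continuous flux
    width = 1e-3 * params.K_f_RYR
    if c_ca < params.K_s_RYR + width:
        u = (c_ca - params.K_s_RYR) / width
        gate *= u * u * (3.0 - 2.0 * u)
    return p * gate * (c_ca_er - c_ca)


def ip3r_rates(c_ca: float, params: ModelParameters) -> tuple[float, float]:
    """Steady values (m_inf, h_inf) of the IP3R activation/inhibition gates.

    m rises with cytosolic Ca2+ around K_s1_IP3, h falls around K_s2_IP3;
    the gates relax with the fixed constants tau_m_IP3 and tau_h_IP3 so
    that m_inf*h_inf is bell-shaped in Ca2+ (activation at low, inhibition
    at high concentration).
    """
    m_inf = logistic((c_ca - params.K_s1_IP3) / params.K_f1_IP3)
    h_inf = logistic(-(c_ca - params.K_s2_IP3) / params.K_f2_IP3)
    return m_inf, h_inf


def ip3r_gate_derivatives(c_ca: float, m: float, h: float,
                          params: ModelParameters) -> tuple[float, float]:
    """(dm/dt, dh/dt) of the IP3R gates, 1/s.

    The printed inhibition equation relaxes h toward h_inf using m in the
    difference; the standard relaxation (h_inf - h)/tau is the default and
    the printed variant is available via ``literal_ip3r_h_equation``.
    """
    m_inf, h_inf = ip3r_rates(c_ca, params)
    tau_m = params.tau_m_IP3
    tau_h = params.tau_h_IP3
    dm = (m_inf - m) / tau_m
    if params.literal_ip3r_h_equation:
        dh = (h_inf - m) / tau_h
    else:
        dh = (h_inf - h) / tau_h
    return dm, dh


def ip3r_flux(c_ca: float, c_ca_er: float, c_ip3: float, m: float, h: float,
              p_leak: float, p_ip3: float, params: ModelParameters) -> float:
    """IP3-receptor + ER leak release (ER -> cytosol)."""
    if not (0.0 <= m <= 1.0 and 0.0 <= h <= 1.0):
        raise ValueError("IP3R gates must lie in [0,1]")
    if p_leak == 0.0 and p_ip3 == 0.0:
        return 0.0
    hill = 1.0 / (1.0 + (params.K_IP3 / c_ip3) ** 3) if c_ip3 > 0 else 0.0
    return (p_leak + p_ip3 * hill * m * h) * (c_ca_er - c_ca)


def _ip3_production(c_ca: float, params: ModelParameters) -> float:
    """Ca-dependent saturation factor of IP3 production."""
    if c_ca == 0.0:
        return 0.0
    if params.literal_ip3_production:
        # as printed: unsquared dissociation constant in the denominator
        return 1.0 / (1.0 + params.K_IP3Ca / c_ca ** 2)
    return 1.0 / (1.0 + (params.K_IP3Ca / c_ca) ** 2)


def ip3_turnover(c_ca: float, c_ip3: float, c_pre_ip3: float,
                 params: ModelParameters) -> tuple[float, float]:
    """(dC_IP3/dt, dC_preIP3/dt) in mol m^-3 s^-1.

    IP3 is produced from its precursor at a Ca2+-saturable rate and decays
    first-order; the precursor is replenished by a self-limiting sigmoidal
    source and consumed by IP3 production.
    """
    if min(c_ca, c_ip3, c_pre_ip3) < 0:
        raise ValueError("negative concentration")
    production = params.k_IP3 * _ip3_production(c_ca, params) * c_pre_ip3
    replenish = params.k_preIP3 * logistic(
        -(c_pre_ip3 - params.K_s_preIP3) / params.K_f_preIP3)
    return production - params.k_dIP3 * c_ip3, replenish - production


def mito_fluxes(c_ca: float, c_ca_mt: float, p_mcu: float, p_mncx: float,
                params: ModelParameters) -> tuple[float, float]:
    """(MCU uptake, MNCX release) flux densities on the mitochondrial surface."""
    if c_ca < 0 or c_ca_mt < 0:
        raise ValueError("negative concentration")
    if c_ca > 0:
        uptake = p_mcu / (1.0 + (params.K_MCU / c_ca) ** 2.3)
    else:
        uptake = 0.0
    release = p_mncx * c_ca_mt / (c_ca_mt + params.K_MNCX)
    return uptake, release


def store_balances(j_serca: float, j_ip3r: float, j_ryr: float,
                   j_mcu: float, j_mncx: float,
                   params: ModelParameters) -> tuple[float, float]:
    """(dn_Ca_ER/dt, dn_Ca_MT/dt) in mol/s.

    The cytosolic balance receives exactly the negatives of these terms,
    so total calcium is conserved when the plasma membrane is silent.
    """
    dn_er = params.S_ER * (j_serca - j_ip3r - j_ryr)
    dn_mt = params.S_MT / (1.0 + params.beta_MT) * (j_mcu - j_mncx)
    return dn_er, dn_mt
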