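"""Vesicle cycle: Ca2+-dependent exocytosis, tension-dependent endocytosis,
and the membrane-area bookkeeping that couples them to the mechanics.

Exocytosis consumes vesicles in proportion to the pool size with a
sigmoidal Ca2+ dependence; synthesis refills the pool and, per the model's
stated assumption, slows as the pool grows.  Each fused vesicle adds
4*pi*r_ve^2 of membrane to the unstressed reference surface S_ref;
endocytosis removes the same area per retrieved vesicle and is suppressed
by cortex stress.
"""
from __future__ import annotations

from ._math import logistic
from .parameters import ModelParameters

import math


def exocytosis_rate(c_ca: float, n_ve: float, params: ModelParameters) -> float:
    """Vesicle fusion rate (vesicles/s), the neurotransmitter-release proxy."""
    if n_ve < 0:
        raise ValueError("vesicle count must be non-negative")
    gate = logistic((c_ca - params.c_Ca_s) / params.c_Ca_f)
    return params.k_exo * gate * n_ve


def synthesis_rate(n_ve: float, params: ModelParameters) -> float:
    """Vesicle synthesis rate (vesicles/s), decreasing in the pool size.

    The printed equation's sigmoid rises with n_ve, contradicting the
    stated inverse relation; the inverse form is the default, the printed
    sign is available via ``literal_vesicle_synthesis``.
    """
    sign = 1.0 if params.literal_vesicle_synthesis else -1.0
    return params.k_ve * logistic(sign * (n_ve - params.n_ve_s)
                                  / params.n_ve_f)


def vesicle_derivative(c_ca: float, n_ve: float, params: ModelParameters) -> float:
    """d n_ve/dt = synthesis - exocytosis (vesicles/s)."""
    return synthesis_rate(n_ve, params) - exocytosis_rate(c_ca, n_ve, params)


def endocytosis_rate(sigma: float, params: ModelParameters) -> float:
    """Membrane-retrieval rate (vesicles/s), suppressed by cortex stress."""
    return params.k_endo * logistic(-(sigma - params.sigma_ve_s)
                                    / params.sigma_ve_f)


def surface_turnover(c_ca: float, n_ve: float, sigma: float,
                     params: ModelParameters) -> float:
    """dS_ref/dt (m^2/s): vesicle area gained by fusion minus area retrieved."""
    a_ve = 4.0 * math.pi * params.r_ve ** 2
    return a_ve * (exocytosis_rate(c_ca, n_ve, params)
                   - endocytosis_rate(sigma, params))
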