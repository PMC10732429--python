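"""Piezo2 mechanosensitive-channel state machine.

Four quantities describe the channel population: C (closed fraction),
O (open fraction), In (short-term-inactivated fraction) and h_slow, an
independent slow-availability factor (the fraction of channels past
long-term inactivation).  C + O + In = 1 at all times.  Gating is driven
by the cortex stress sigma (Pa), not by voltage.

Two kinetic regimes are used, selected by an explicit, protocol-driven
phase flag:

* ``loading`` (stimulus being applied or held)::

      dC/dt  = (C_inf - C)/tau_C
      dO/dt  = -O/tau_O - (C_inf - C)/tau_C
      dIn/dt = O/tau_O

* ``unloading`` (after release)::

      dC/dt  = -(In_inf - In)/tau_In
      dIn/dt = (In_inf - In)/tau_In       (O unchanged)

h_slow always relaxes to h_slow_inf(sigma) with tau_hslow(sigma).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

from ._math import logistic
from .parameters import ModelParameters

Phase = Literal["loading", "unloading"]

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class Piezo2State:
    c: float = 1.0
    o: float = 0.0
    inact: float = 0.0
    h_slow: float = 0.0
    phase: Phase = "loading"

    def validate(self) -> None:
        for name in ("c", "o", "inact", "h_slow"):
            x = getattr(self, name)
            if not -_SIMPLEX_TOL <= x <= 1.0 + _SIMPLEX_TOL:
                raise ValueError(f"Piezo2 fraction {name} out of [0,1]: {x}")
        if abs(self.c + self.o + self.inact - 1.0) > 1e-6:
            raise ValueError("Piezo2 state fractions do not sum to 1")


def c_inf(sigma: float, p: ModelParameters) -> float:
    return logistic(-(sigma - p.sigma_s1) / p.sigma_f1)


def in_inf(sigma: float, p: ModelParameters) -> float:
    return logistic((sigma - p.sigma_s1) / p.sigma_f1)


def tau_c(sigma: float, p: ModelParameters) -> float:
    return (0.5 + 1.5 * logistic((sigma - p.sigma_s2) / p.sigma_f2)) * 1e-3


def tau_o(sigma: float, p: ModelParameters) -> float:
    return (2.5 + 5.5 * logistic((sigma - p.sigma_s4) / p.sigma_f4)) * 1e-3


tau_in = tau_c  # the short-inactivation recovery shares the C time constant


def h_slow_inf(sigma: float, p: ModelParameters) -> float:
    return logistic((sigma - p.sigma_s7) / p.sigma_f7)


def tau_h_slow(sigma: float, p: ModelParameters) -> float:
    return 150.0 * logistic(-(sigma - p.sigma_s8) / p.sigma_f8) * 1e-3


def derivatives(state_c: float, state_o: float, state_in: float,
                state_h: float, sigma: float, phase: Phase,
                p: ModelParameters) -> tuple[float, float, float, float]:
    """(dC, dO, dIn, dh_slow)/dt at the given stress and phase (SI, 1/s)."""
    dh = (h_slow_inf(sigma, p) - state_h) / tau_h_slow(sigma, p)
    if phase == "loading":
        dc = (c_inf(sigma, p) - state_c) / tau_c(sigma, p)
        din = state_o / tau_o(sigma, p)
        do = -dc - din
    else:
        din = (in_inf(sigma, p) - state_in) / tau_in(sigma, p)
        dc = -din
        do = 0.0
    return dc, do, din, dh


def _relax(x0: float, x_inf: float, tau: float, dt: float) -> float:
    return x_inf + (x0 - x_inf) * math.exp(-dt / tau)


def advance(state: Piezo2State, sigma: float, dt: float,
            p: ModelParameters) -> Piezo2State:
    """Advance the state by ``dt`` seconds at constant stress, exactly.

    The kinetics at fixed sigma are linear, so each component has a closed
    form; this kernel is the unit-testable reference for the ODE right-hand
    side, which integrates the same equations inside the global solver.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.validate()
    h = _relax(state.h_slow, h_slow_inf(sigma, p), tau_h_slow(sigma, p), dt)
    if state.phase == "loading":
        ci, tc, to = c_inf(sigma, p), tau_c(sigma, p), tau_o(sigma, p)
        c = _relax(state.c, ci, tc, dt)
        # dO/dt = -O/tau_o - (ci - c0) e^{-t/tc} / tc  (linear, closed form)
        a = (ci - state.c) / tc
        if abs(1.0 / to - 1.0 / tc) < 1e-12:
            o = (state.o - a * dt) * math.exp(-dt / to)
        else:
            k = 1.0 / to - 1.0 / tc
            o = (state.o * math.exp(-dt / to)
                 - a / k * (math.exp(-dt / tc) - math.exp(-dt / to)))
        inact = 1.0 - c - o
    else:
        inact = _relax(state.inact, in_inf(sigma, p), tau_in(sigma, p), dt)
        o = state.o
        c = 1.0 - inact - o
    new = replace(state, c=c, o=o, inact=inact, h_slow=h)
    new.validate()
    return new
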