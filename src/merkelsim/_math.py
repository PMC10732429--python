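"""Overflow-safe scalar sigmoid helpers for the kinetic rate laws.

Stiff-solver trial steps and finite-difference Jacobian probes can push
state variables far outside their physical range; the rate laws must stay
finite there so the step-size control can recover.
"""
import math

_EXP_MAX = 700.0  # just below the float64 overflow threshold of math.exp


def safe_exp(x: float) -> float:
    """exp(x) clamped against overflow (monotone, finite for all x)."""
    return math.exp(x if x < _EXP_MAX else _EXP_MAX)


def logistic(x: float) -> float:
    """1/(1+exp(-x)), numerically safe for any finite x."""
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x) if x > -_EXP_MAX else 0.0
    return e / (1.0 + e)
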