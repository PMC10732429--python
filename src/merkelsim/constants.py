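"""Physical constants and unit-conversion factors.

All internal computation is in coherent SI units:

==============  ==========================
quantity        internal unit
==============  ==========================
time            s
length          m
area            m^2
volume          m^3
potential       V
concentration   mol/m^3  (== mM)
amount          mol
conductance     S/m^2
capacitance     F/m^2
molar flux      mol m^-2 s^-1
pressure        Pa
temperature     K
==============  ==========================

Parameter tables in the literature use mS/cm^2, mol/(cm^2 ms), cm/ms, uM,
um, ms and pA; the ``UNIT_TO_SI`` map converts those at the config
boundary and nowhere else.
"""

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446261815324  # J/(mol K)

#: multiply a value carrying the given unit string by this factor to get SI.
UNIT_TO_SI: dict[str, float] = {
    # electrical
    "mS/cm^2": 10.0,               # -> S/m^2
    "uF/um^2": 1.0e6,              # -> F/m^2
    "mV": 1.0e-3,                  # -> V
    "pA": 1.0e-12,                 # -> A
    # molar flux / rate constants
    "mol/(cm^2 ms)": 1.0e7,        # -> mol m^-2 s^-1
    "cm^10/(mol^3 ms)": 1.0e-17,   # -> m^10 mol^-3 s^-1
    "cm/ms": 10.0,                 # -> m/s
    "1/ms": 1.0e3,                 # -> 1/s
    "mol/(cm^3 ms)": 1.0e9,        # -> mol m^-3 s^-1
    # concentration
    "mM": 1.0,                     # -> mol/m^3
    "uM": 1.0e-3,                  # -> mol/m^3
    # geometry
    "um": 1.0e-6,                  # -> m
    "um^2": 1.0e-12,               # -> m^2
    "um^3": 1.0e-18,               # -> m^3
    # mechanics
    "Pa": 1.0,
    "cm/(ms Pa)": 10.0,            # -> m s^-1 Pa^-1
    "um/ms": 1.0e-3,               # -> m/s
    # time
    "ms": 1.0e-3,                  # -> s
    "s": 1.0,
    "K": 1.0,
    "1": 1.0,                      # dimensionless
}


def to_si(value: float, unit: str) -> float:
    """Convert ``value`` carrying ``unit`` to the internal SI system."""
    try:
        return value * UNIT_TO_SI[unit]
    except KeyError:
        raise ValueError(f"unknown unit string: {unit!r}") from None


def from_si(value: float, unit: str) -> float:
    """Convert an internal SI value back to the given display unit."""
    try:
        return value / UNIT_TO_SI[unit]
    except KeyError:
        raise ValueError(f"unknown unit string: {unit!r}") from None
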