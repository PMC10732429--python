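"""Model parameters: registry, presets and the `ModelParameters` container.

Every physical constant of the model is declared once in ``PARAM_TABLE``
with the unit it is conventionally printed in, its default value in that
unit, and (where the two published electrophysiology presets differ) a
second value.  ``ModelParameters`` stores everything in SI.

The two presets, ``"fig2"`` and ``"fig3"``, are the two parameter columns
used to reproduce the passive/peaked and the oscillatory membrane-potential
phenotypes respectively; they differ in capacitance, K+/Ca2+ conductances
and two pump rates.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .constants import to_si

#: name -> (unit, fig2 value, fig3 value).  Values are in the printed unit.
PARAM_TABLE: dict[str, tuple[str, float, float]] = {
    # --- plasma membrane: specific conductances ------------------------------
    "g_Kv1_4":    ("mS/cm^2", 0.25, 4.0),
    "g_Kv4_2":    ("mS/cm^2", 0.2, 0.2),
    "g_BKCa":     ("mS/cm^2", 0.18, 0.3),
    "g_KDR":      ("mS/cm^2", 0.01, 0.01),
    "g_Cav1_2":   ("mS/cm^2", 2.0, 0.8),
    "g_Cav2_1":   ("mS/cm^2", 0.1e-2, 0.05e-2),
    "g_Piezo2":   ("mS/cm^2", 3.0, 3.0),
    "g_Na_leak":  ("mS/cm^2", 0.043, 0.045),
    "g_K_leak":   ("mS/cm^2", 0.09, 0.09),
    "g_Cl_leak":  ("mS/cm^2", 0.5e-2, 0.5e-2),
    "g_Ca_leak":  ("mS/cm^2", 0.2e-4, 0.2e-4),
    "C_m":        ("uF/um^2", 4e-8, 2e-8),
    # --- pumps / cotransporters / exchangers ---------------------------------
    "P_NaKpump":  ("mol/(cm^2 ms)", 0.37312e-12, 0.1696e-12),
    "P_NKCC1":    ("cm^10/(mol^3 ms)", 0.24e2, 0.24e2),
    "P_KCC2":     ("mol/(cm^2 ms)", 0.25e-14, 0.25e-14),
    "P_Capump":   ("mol/(cm^2 ms)", 0.3e-15, 150 * 0.3e-15),
    "P_Cana":     ("mol/(cm^2 ms)", 0.1e-12, 0.1e-12),
    "K_Na_NaK":   ("mM", 10.0, 10.0),
    "K_K_NaK":    ("mM", 140.0, 140.0),
    "K_Capump":   ("uM", 0.3, 0.3),
    "K_mNa":      ("mM", 87.5, 87.5),
    "K_mCa":      ("uM", 0.5, 0.5),
    "eta_NCX":    ("1", 0.1, 0.1),
    "ksat_NCX":   ("1", 0.35, 0.35),
    "K_BKCa":     ("mM", 1.0, 1.0),
    "K_hCa":      ("uM", 1.0, 1.0),
    # --- Piezo2 stress gating ------------------------------------------------
    "sigma_s1":   ("Pa", 1450.0, 1450.0),
    "sigma_f1":   ("Pa", 120.0, 120.0),
    "sigma_s2":   ("Pa", 1450.0, 1450.0),
    "sigma_f2":   ("Pa", 40.0, 40.0),
    "sigma_s4":   ("Pa", 1450.0, 1450.0),
    "sigma_f4":   ("Pa", 100.0, 100.0),
    "sigma_s7":   ("Pa", 1450.0, 1450.0),
    "sigma_f7":   ("Pa", 200.0, 200.0),
    "sigma_s8":   ("Pa", 1450.0, 1450.0),
    "sigma_f8":   ("Pa", 2000.0, 2000.0),
    "E_Piezo2":   ("mV", 6.0, 6.0),
    # --- ER / mitochondria ---------------------------------------------------
    "P_pump_ER":  ("mol/(cm^2 ms)", 0.7e-17, 0.7e-17),
    "K_ERpump":   ("uM", 0.1, 0.1),
    "P_RYR":      ("cm/ms", 8.5, 8.5),
    "K_s_RYR":    ("uM", 0.3, 0.3),
    "K_f_RYR":    ("uM", 0.04, 0.04),
    "P_leak_ER":  ("cm/ms", 0.7e-3, 0.7e-3),
    "P_IP3":      ("cm/ms", 1.75, 1.75),
    "K_IP3":      ("uM", 3.0, 3.0),
    "K_s1_IP3":   ("uM", 0.4, 0.4),
    "K_f1_IP3":   ("uM", 0.04, 0.04),
    "K_s2_IP3":   ("uM", 0.6, 0.6),
    "K_f2_IP3":   ("uM", 0.04, 0.04),
    "tau_m_IP3":  ("ms", 10000.0, 10000.0),
    "tau_h_IP3":  ("ms", 20000.0, 20000.0),
    "k_IP3":      ("1/ms", 4e-5, 4e-5),
    "k_dIP3":     ("1/ms", 2e-5, 2e-5),
    "K_IP3Ca":    ("uM", 0.5, 0.5),
    "k_preIP3":   ("mol/(cm^3 ms)", 1e-12, 1e-12),
    "K_s_preIP3": ("uM", 5.0, 5.0),
    "K_f_preIP3": ("uM", 1.0, 1.0),
    "P_MCU":      ("mol/(cm^2 ms)", 0.5e-15, 0.5e-15),
    "K_MCU":      ("uM", 0.6, 0.6),
    "P_MNCX":     ("mol/(cm^2 ms)", 0.1e-15, 0.1e-15),
    "K_MNCX":     ("uM", 1.0, 1.0),
    "S_ER":       ("um^2", 150.0, 150.0),
    "V_ER":       ("um^3", 100.0, 100.0),
    "S_MT":       ("um^2", 150.0, 150.0),
    "V_MT":       ("um^3", 10.0, 10.0),
    "beta_MT":    ("1", 0.3, 0.3),
    # --- mechanics -----------------------------------------------------------
    "alpha_water": ("cm/(ms Pa)", 1e-9, 1e-9),
    "K_cortex":    ("Pa", 6000.0, 6000.0),
    "sigma_a":     ("Pa", -100.0, -100.0),
    "h_cortex":    ("um", 0.5, 0.5),
    "r_ini":       ("um", 5.0, 5.0),
    # --- vesicle cycle -------------------------------------------------------
    "k_ve":       ("1/ms", 0.1, 0.1),
    "n_ve_s":     ("1", 500.0, 500.0),
    "n_ve_f":     ("1", 50.0, 50.0),
    "k_exo":      ("1/ms", 2e-4, 2e-4),
    "c_Ca_s":     ("uM", 0.2, 0.2),
    "c_Ca_f":     ("uM", 0.01, 0.01),
    "r_ve":       ("um", 0.05, 0.05),
    "k_endo":     ("1/ms", 1.0, 1.0),
    "sigma_ve_s": ("Pa", 1000.0, 1000.0),
    "sigma_ve_f": ("Pa", 15.0, 15.0),
    # --- environment ---------------------------------------------------------
    "C_Na_out":   ("mM", 145.0, 145.0),
    "C_K_out":    ("mM", 5.0, 5.0),
    "C_Cl_out":   ("mM", 110.0, 110.0),
    "C_Ca_out":   ("mM", 2.0, 2.0),
    "C_mannitol_out": ("mM", 0.0, 0.0),
    "temperature": ("K", 310.0, 310.0),
}

#: parameters that may legitimately be negative (everything else must be >= 0)
_SIGNED = {"sigma_a"}

PRESETS = ("fig2", "fig3")

# literal-equation switches: reproduce exactly-as-printed variants of three
# equations whose printed form contradicts their own accompanying text.
_SWITCHES = ("literal_ip3r_h_equation", "literal_ip3_production",
             "literal_vesicle_synthesis")


def _si_defaults(preset: str) -> dict[str, float]:
    col = {"fig2": 1, "fig3": 2}[preset]
    return {name: to_si(row[col], row[0]) for name, row in PARAM_TABLE.items()}


@dataclass(frozen=True)
class ModelParameters:
    """All model constants in SI units, immutable.

    Construct with :meth:`preset` (optionally overriding individual values,
    already in SI) or through :func:`merkelsim.config.load_config` which
    converts printed units.
    """
    values: dict[str, float] = field(default_factory=lambda: _si_defaults("fig2"))
    literal_ip3r_h_equation: bool = False
    literal_ip3_production: bool = False
    literal_vesicle_synthesis: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(PARAM_TABLE)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        missing = set(PARAM_TABLE) - set(self.values)
        if missing:
            raise ValueError(f"missing parameter(s): {sorted(missing)}")
        for name, v in self.values.items():
            if name not in _SIGNED and v < 0:
                raise ValueError(f"parameter {name} must be non-negative, got {v}")
        for name in ("K_Na_NaK", "K_K_NaK", "K_Capump", "K_mNa", "K_mCa",
                     "K_BKCa", "K_hCa", "K_ERpump", "K_IP3", "K_MCU", "K_MNCX",
                     "K_IP3Ca", "K_cortex", "h_cortex", "r_ini",
                     "S_ER", "V_ER", "S_MT", "V_MT", "C_m", "temperature"):
            if self.values[name] <= 0:
                raise ValueError(f"parameter {name} must be positive")
        # expose every parameter as a plain attribute (fast lookup in the
        # ODE right-hand side; the dataclass is frozen so this is safe)
        for name, v in self.values.items():
            object.__setattr__(self, name, v)

    def __getattr__(self, name: str) -> float:
        # dataclass fields are found normally; everything else is a parameter
        try:
            return object.__getattribute__(self, "values")[name]
        except KeyError:
            raise AttributeError(name) from None

    @classmethod
    def preset(cls, name: str = "fig2", **overrides: float) -> "ModelParameters":
        """Build a named preset, with optional SI-valued overrides.

        Boolean literal-equation switches may also be passed as overrides.
        """
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; available: {PRESETS}")
        vals = _si_defaults(name)
        switches = {}
        for key, v in overrides.items():
            if key in _SWITCHES:
                switches[key] = bool(v)
            elif key in PARAM_TABLE:
                vals[key] = float(v)
            else:
                raise ValueError(f"unknown parameter {key!r}")
        return cls(values=vals, **switches)

    def replace(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given SI-valued overrides applied."""
        vals = dict(self.values)
        switches = {s: getattr(self, s) for s in _SWITCHES}
        for key, v in overrides.items():
            if key in _SWITCHES:
                switches[key] = bool(v)
            elif key in PARAM_TABLE:
                vals[key] = float(v)
            else:
                raise ValueError(f"unknown parameter {key!r}")
        return dataclasses.replace(self, values=vals, **switches)
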