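"""The full dynamic state of the cell and the per-pathway flux record.

``CellState`` carries the 28 integrated quantities plus the two constants
of the impermeant internal species (amount and mean valence) fixed at
initialisation.  ``FluxVector`` is the named snapshot of every pathway's
molar flux density at one instant, used both by the balance equations and
by the independent charge-consistency checks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .parameters import ModelParameters
from .piezo2 import Piezo2State

#: integrated-state layout (vector index order)
STATE_NAMES = (
    "n_na", "n_k", "n_cl", "n_ca", "vm",
    "m_kv14", "hf_kv14", "hs_kv14", "m_kv42", "h_kv42",
    "n_bk", "n_kdr", "m_cav12", "h_cav12", "n_cav21",
    "pz_c", "pz_o", "pz_in", "pz_h",
    "n_ca_er", "n_ca_mt", "c_ip3", "c_preip3", "m_ip3", "h_ip3",
    "volume", "s_ref", "n_ve",
)
N_STATE = len(STATE_NAMES)

GATE_NAMES = STATE_NAMES[5:15]


class FluxVector(NamedTuple):
    """Molar flux densities (mol m^-2 s^-1), positive into the cytosol
    for membrane pathways; store fluxes follow their module conventions
    (SERCA into ER, RyR/IP3R out of ER, MCU into mitochondria, MNCX out).
    """
    j_kv14: float
    j_kv42: float
    j_bkca: float
    j_kdr: float
    j_cav12: float
    j_cav21: float
    j_piezo2: float
    j_na_leak: float
    j_k_leak: float
    j_cl_leak: float
    j_ca_leak: float
    j_nak: float      # pump cycle rate (>= 0)
    j_nkcc1: float    # positive = 1 Na + 1 K + 2 Cl inward
    j_kcc2: float     # positive = 1 K + 1 Cl extruded
    j_pmca: float     # Ca2+ efflux (>= 0)
    j_ncx: float      # positive = reverse mode (Ca in, 3 Na out)
    j_serca: float
    j_ryr: float
    j_ip3r: float
    j_mcu: float
    j_mncx: float


@dataclass(frozen=True)
class CellState:
    """Snapshot of every dynamic variable, SI units."""
    n_na: float
    n_k: float
    n_cl: float
    n_ca: float
    vm: float
    gates: dict[str, float]          # keyed by GATE_NAMES
    piezo2: Piezo2State
    n_ca_er: float
    n_ca_mt: float
    c_ip3: float
    c_preip3: float
    m_ip3: float
    h_ip3: float
    volume: float
    s_ref: float
    n_ve: float
    n_a: float = 0.0                 # impermeant species, constant
    z_a: float = -1.0                # its mean valence, constant
    indentation: float = 0.0         # current depth d (protocol-driven)

    # -- derived -------------------------------------------------------------
    def cytosol_volume(self, params: ModelParameters) -> float:
        v = self.volume - params.V_ER - params.V_MT
        if v <= 0:
            raise ValueError("cytosolic volume is non-positive")
        return v

    def concentrations(self, params: ModelParameters) -> dict[str, float]:
        v = self.cytosol_volume(params)
        return {
            "Na": self.n_na / v, "K": self.n_k / v, "Cl": self.n_cl / v,
            "Ca": self.n_ca / v, "A": self.n_a / v,
            "Ca_ER": self.n_ca_er / params.V_ER,
            "Ca_MT": self.n_ca_mt / params.V_MT,
        }

    def validate(self, params: ModelParameters) -> None:
        if not math.isfinite(self.vm):
            raise ValueError("membrane potential is not finite")
        conc = self.concentrations(params)
        for ion in ("Na", "K", "Cl", "Ca"):
            if conc[ion] <= 0:
                raise ValueError(f"non-positive {ion} concentration")
        for name, x in self.gates.items():
            if not -1e-9 <= x <= 1.0 + 1e-9:
                raise ValueError(f"gating variable {name} out of [0,1]: {x}")
        self.piezo2.validate()
        if self.s_ref <= 0:
            raise ValueError("reference surface must be positive")
        if self.n_ve < 0:
            raise ValueError("vesicle count must be non-negative")

    # -- vector packing --------------------------------------------------------
    def to_vector(self) -> np.ndarray:
        g = self.gates
        return np.array([
            self.n_na, self.n_k, self.n_cl, self.n_ca, self.vm,
            g["m_kv14"], g["hf_kv14"], g["hs_kv14"], g["m_kv42"], g["h_kv42"],
            g["n_bk"], g["n_kdr"], g["m_cav12"], g["h_cav12"], g["n_cav21"],
            self.piezo2.c, self.piezo2.o, self.piezo2.inact, self.piezo2.h_slow,
            self.n_ca_er, self.n_ca_mt, self.c_ip3, self.c_preip3,
            self.m_ip3, self.h_ip3, self.volume, self.s_ref, self.n_ve,
        ])

    def with_vector(self, y: np.ndarray, phase: str | None = None,
                    indentation: float | None = None) -> "CellState":
        gates = dict(zip(GATE_NAMES, (float(v) for v in y[5:15])))
        pz = Piezo2State(c=float(y[15]), o=float(y[16]), inact=float(y[17]),
                         h_slow=float(y[18]),
                         phase=phase if phase is not None else self.piezo2.phase)
        return replace(
            self, n_na=float(y[0]), n_k=float(y[1]), n_cl=float(y[2]),
            n_ca=float(y[3]), vm=float(y[4]), gates=gates, piezo2=pz,
            n_ca_er=float(y[19]), n_ca_mt=float(y[20]), c_ip3=float(y[21]),
            c_preip3=float(y[22]), m_ip3=float(y[23]), h_ip3=float(y[24]),
            volume=float(y[25]), s_ref=float(y[26]), n_ve=float(y[27]),
            indentation=(self.indentation if indentation is None else indentation),
        )

    def scales(self) -> np.ndarray:
        """Per-variable magnitude scales (for tolerances and residual norms)."""
        floors = np.array([
            1e-16, 1e-16, 1e-16, 1e-19, 1e-2,      # amounts, Vm
            *([1e-3] * 10),                        # gates
            *([1e-3] * 4),                         # piezo2
            1e-19, 1e-20, 1e-6, 1e-5, 1e-3, 1e-3,  # stores
            1e-19, 1e-13, 1.0,                     # V, S_ref, n_ve
        ])
        return np.maximum(np.abs(self.to_vector()), floors)
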