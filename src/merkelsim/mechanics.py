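"""Cell mechanics: osmotic water flow, elastic cortex stress, Laplace
pressure, and the indentation geometry.

The cell is a sphere of volume V at rest.  Under indentation to depth d it
is modelled as a volume-conserving cylinder of height H = 2*r_ini - d and
radius chosen so the cylinder holds the current volume; the surface area
of that shape (two discs plus the lateral wall) drives the cortex stress.
The geometry function is deliberately isolated so an alternative shape
map can be swapped in.
"""
from __future__ import annotations

import math
from typing import NamedTuple

from .constants import GAS_CONSTANT


class Geometry(NamedTuple):
    height: float   # m (2*r for the sphere)
    radius: float   # m (sphere radius, or cylinder radius when compressed)
    area: float     # m^2


def sphere_geometry(volume: float) -> Geometry:
    r = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    return Geometry(2.0 * r, r, 4.0 * math.pi * r * r)


def compressed_geometry(volume: float, r_ini: float, depth: float) -> Geometry:
    """Shape of the cell compressed to depth ``depth`` at constant volume.

    Returns the sphere at zero depth; otherwise a cylinder of height
    H = 2*r_ini - depth whose radius conserves the volume.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    if depth < 0 or depth >= 2.0 * r_ini:
        raise ValueError("indentation depth must satisfy 0 <= d < 2*r_ini")
    if depth == 0.0:
        return sphere_geometry(volume)
    h = 2.0 * r_ini - depth
    r_cyl = math.sqrt(volume / (math.pi * h))
    area = 2.0 * math.pi * r_cyl ** 2 + 2.0 * math.pi * r_cyl * h
    return Geometry(h, r_cyl, area)


def osmotic_pressure_difference(total_c_in: float, total_c_out: float,
                                temperature: float) -> float:
    """van 't Hoff osmotic pressure difference RT*(sum C_in - sum C_out), Pa.

    The totals must include every osmotically active species: the four
    permeant ions plus the impermeant internal species A and any external
    impermeant osmolyte (mannitol).
    """
    if total_c_in < 0 or total_c_out < 0:
        raise ValueError("osmolarities must be non-negative")
    return GAS_CONSTANT * temperature * (total_c_in - total_c_out)


def water_flux(delta_p: float, delta_pi: float, alpha: float) -> float:
    """Transmembrane water velocity -alpha*(dP - dPi), m/s, positive inward.

    The volume rate is the cell surface times this velocity.
    """
    return -alpha * (delta_p - delta_pi)


def cortex_stress(area: float, area_ref: float, k_cortex: float,
                  sigma_a: float) -> float:
    """Elastic cortex stress K/2*(S/S_ref - 1) - sigma_a, Pa."""
    if area_ref <= 0:
        raise ValueError("reference area must be positive")
    return 0.5 * k_cortex * (area / area_ref - 1.0) - sigma_a


def hydrostatic_pressure(sigma: float, radius: float, h_cortex: float) -> float:
    """Laplace pressure jump 2*h_c*sigma/r across a thin shell, Pa."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return 2.0 * h_cortex * sigma / radius


def solve_impermeant_species(c_na: float, c_k: float, c_cl: float,
                             c_ca: float, external_osmolarity: float,
                             delta_p: float, temperature: float
                             ) -> tuple[float, float]:
    """Concentration and mean valence of the impermeant internal species A.

    Solved once at initialisation so that the starting state is
    simultaneously osmotically balanced (dPi = dP) and bulk
    electro-neutral.  Returns (C_A, z_A); z_A is negative.
    """
    c_a = (external_osmolarity + delta_p / (GAS_CONSTANT * temperature)
           - (c_na + c_k + c_cl + c_ca))
    if c_a <= 0:
        raise ValueError(
            "initial interior osmolarity already exceeds the exterior; "
            "no impermeant-species concentration can balance it")
    z_a = -(c_na + c_k + 2.0 * c_ca - c_cl) / c_a
    if z_a >= 0:
        raise ValueError("impermeant species must carry net negative charge")
    return c_a, z_a
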