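"""Channel-flow and dispersed-phase hydraulics.

Covers the rectangular-duct Reynolds number Re = 2 rho Q / ((w + h) mu),
the laminar criterion (critical Re 2300), the Haider–Levenspiel drag
correlation for (non)spherical particles, and the buoyant slip
(terminal rise) velocity of an air bubble obtained by balancing
buoyancy against that drag.

Unit policy: the published formulas mix g/mm^3, uL/min, mm and Pa.s,
which is not a coherent system; everything here converts to SI
internally and exposes the field-customary units (uL/min, mm, mm/s) at
the API boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ChannelSpec",
    "FluidPair",
    "WATER_AIR",
    "CRITICAL_REYNOLDS",
    "GRAVITY_M_S2",
    "reynolds_rectangular",
    "is_laminar",
    "drag_coefficient_hl",
    "slip_velocity",
    "stokes_velocity",
]

CRITICAL_REYNOLDS = 2300.0
GRAVITY_M_S2 = 9.81

# Unit converters to SI
_G_MM3_TO_KG_M3 = 1.0e6          # g/mm^3 -> kg/m^3
_UL_MIN_TO_M3_S = 1.0e-9 / 60.0  # uL/min -> m^3/s
_MM_TO_M = 1.0e-3


@dataclass(frozen=True)
class ChannelSpec:
    """Rectangular channel cross section, dimensions in mm."""

    width_mm: float
    height_mm: float

    def __post_init__(self) -> None:
        if not (self.width_mm > 0 and self.height_mm > 0):
            raise ValueError(f"channel dimensions must be positive, got {self}")


@dataclass(frozen=True)
class FluidPair:
    """Continuous (water) and dispersed (air) phase properties.

    Densities in g/mm^3 and viscosities in Pa.s, matching the units the
    constants are customarily quoted in for this system.
    """

    rho_c: float = 0.001       # water density, g/mm^3
    mu_c: float = 8.90e-4      # water dynamic viscosity, Pa.s
    rho_d: float = 1.2e-6      # air density, g/mm^3
    mu_d: float = 1.81e-5      # air dynamic viscosity, Pa.s

    def __post_init__(self) -> None:
        if min(self.rho_c, self.mu_c, self.rho_d, self.mu_d) <= 0:
            raise ValueError("all fluid properties must be positive")

    @property
    def rho_c_si(self) -> float:
        return self.rho_c * _G_MM3_TO_KG_M3

    @property
    def rho_d_si(self) -> float:
        return self.rho_d * _G_MM3_TO_KG_M3


#: Default air-in-water pair.
WATER_AIR = FluidPair()


def reynolds_rectangular(q_ul_min: float, channel: ChannelSpec, fluids: FluidPair = WATER_AIR) -> float:
    """Reynolds number of flow in a rectangular duct: 2 rho Q / ((w+h) mu).

    Equivalent to rho U D_h / mu with hydraulic diameter
    D_h = 2wh/(w+h) and mean velocity U = Q/(wh).  Linear in Q.

    Parameters are in field units (flow rate uL/min, channel mm); the
    computation is done in SI.
    """
    if q_ul_min < 0:
        raise ValueError(f"flow rate must be non-negative, got {q_ul_min}")
    q_si = q_ul_min * _UL_MIN_TO_M3_S
    perimeter_term = (channel.width_mm + channel.height_mm) * _MM_TO_M
    return 2.0 * fluids.rho_c_si * q_si / (perimeter_term * fluids.mu_c)


def is_laminar(re: float) -> bool:
    """True iff Re is strictly below the critical value 2300."""
    if re < 0:
        raise ValueError(f"Reynolds number must be non-negative, got {re}")
    return re < CRITICAL_REYNOLDS


def _hl_constants(sphericity: float) -> tuple[float, float, float, float]:
    # Haider & Levenspiel (1989) sphericity polynomials for the drag fit
    # C_D = 24/Re (1 + A Re^B) + C / (1 + D/Re):
    #   A = exp(2.3288 - 6.4581 phi + 2.4486 phi^2)
    #   B = 0.0964 + 0.5565 phi
    #   C = exp(4.905 - 13.8944 phi + 18.4222 phi^2 - 10.2599 phi^3)
    #   D = exp(1.4681 + 12.2584 phi - 20.7322 phi^2 + 15.8855 phi^3)
    p = sphericity
    a = math.exp(2.3288 - 6.4581 * p + 2.4486 * p * p)
    b = 0.0964 + 0.5565 * p
    c = math.exp(4.905 - 13.8944 * p + 18.4222 * p * p - 10.2599 * p**3)
    d = math.exp(1.4681 + 12.2584 * p - 20.7322 * p * p + 15.8855 * p**3)
    return a, b, c, d


def drag_coefficient_hl(re_p: float, sphericity: float = 1.0) -> float:
    """Haider–Levenspiel drag coefficient for a particle at Reynolds re_p.

    Reduces to the Stokes law C_D = 24/Re as re_p -> 0 for a sphere.
    """
    if not re_p > 0:
        raise ValueError(f"particle Reynolds number must be positive, got {re_p}")
    if not 0 < sphericity <= 1:
        raise ValueError(f"sphericity must be in (0, 1], got {sphericity}")
    a, b, c, d = _hl_constants(sphericity)
    return (24.0 / re_p) * (1.0 + a * re_p**b) + c / (1.0 + d / re_p)


def stokes_velocity(d_b_mm: float, fluids: FluidPair = WATER_AIR) -> float:
    """Stokes-regime terminal rise speed u = g d^2 (rho_c - rho_d) / (18 mu_c),
    returned in mm/s.  Valid as a closed form only at small particle Re."""
    d = d_b_mm * _MM_TO_M
    u = GRAVITY_M_S2 * d * d * (fluids.rho_c_si - fluids.rho_d_si) / (18.0 * fluids.mu_c)
    return u / _MM_TO_M


def slip_velocity(
    d_b_mm: float,
    fluids: FluidPair = WATER_AIR,
    sphericity: float = 1.0,
    *,
    rel_tol: float = 1e-8,
    max_iter: int = 500,
) -> float:
    """Terminal slip (rise) speed of a buoyant bubble, in mm/s.

    Solves buoyancy = drag, (rho_c - rho_d) g V = C_D(Re) (1/2) rho_c
    u^2 A, for a volume-equivalent sphere of diameter ``d_b_mm`` using
    damped fixed-point iteration on u, with the Haider–Levenspiel drag.
    Converges to relative tolerance ``rel_tol``; raises on
    non-convergence.
    """
    if not d_b_mm > 0:
        raise ValueError(f"bubble diameter must be positive, got {d_b_mm}")
    delta_rho = fluids.rho_c_si - fluids.rho_d_si
    if delta_rho == 0:
        return 0.0
    d = d_b_mm * _MM_TO_M
    # u^2 = 4 g d |delta_rho| / (3 C_D rho_c)
    coef = 4.0 * GRAVITY_M_S2 * d * abs(delta_rho) / (3.0 * fluids.rho_c_si)
    u = abs(stokes_velocity(d_b_mm, fluids)) * _MM_TO_M  # initial guess, m/s
    for _ in range(max_iter):
        re_p = fluids.rho_c_si * u * d / fluids.mu_c
        cd = drag_coefficient_hl(re_p, sphericity)
        u_new = math.sqrt(coef / cd)
        if abs(u_new - u) <= rel_tol * abs(u_new):
            return math.copysign(u_new / _MM_TO_M, delta_rho)
        u = 0.5 * (u + u_new)  # damping for stability at high Re
    raise RuntimeError(
        f"slip velocity did not converge in {max_iter} iterations for d={d_b_mm} mm"
    )
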