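"""First-integral ODEs for the aqueous regions and the linear bilayer.

Each aqueous region obeys

    (dpsi/dx)^2 = Gj(psi) = alpha_j cosh(u) + beta_j cosh(2u) - f_j psi + K_j

with u = q (psi - psi_bar_j)/kT.  The constant K_j is fixed by one boundary
condition: vanishing slope in a bulk region, or a prescribed interface field
for the glycocalyx.  Taking the square root selects a branch; the sign is
chosen per region so the potential runs monotonically from its interface
value toward its bulk value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .electrolyte_core import RegionCoefficients
from .units_and_parameters import PhysicalConstants, RegionGeometry

__all__ = [
    "BranchError",
    "FirstIntegralConstant",
    "RegionODE",
    "first_integral_constant",
    "extracellular_constant",
    "cytoplasm_constant",
    "glycocalyx_constant",
    "bilayer_profile",
]

#: relative clamp tolerance for tiny negative square-root arguments
TURNING_POINT_TOL = 1e-12


class BranchError(ValueError):
    """The potential left the branch reachable from the boundary condition."""


@dataclass(frozen=True)
class FirstIntegralConstant:
    value: float
    region: str


def first_integral_constant(
    coeffs: RegionCoefficients,
    psi_at: float,
    constants: PhysicalConstants,
    slope_at: float = 0.0,
) -> FirstIntegralConstant:
    """K_j such that (dpsi/dx)^2 = slope_at^2 holds exactly at psi_at."""
    u = (psi_at - coeffs.psi_bound) / constants.thermal_voltage
    value = slope_at * slope_at - (
        coeffs.alpha * math.cosh(u)
        + coeffs.beta * math.cosh(2.0 * u)
        - coeffs.fixed_term * psi_at
    )
    return FirstIntegralConstant(value=value, region=coeffs.region)


def extracellular_constant(
    coeffs: RegionCoefficients,
    psi_inf: float = 0.0,
    constants: PhysicalConstants | None = None,
) -> FirstIntegralConstant:
    """K_e from dpsi/dx -> 0 as psi -> psi(-inf) (= 0 in this model)."""
    constants = constants or PhysicalConstants()
    if coeffs.fixed_term != 0.0:
        raise ValueError("extracellular region carries no fixed charge")
    if coeffs.alpha == 0.0 and coeffs.beta == 0.0:
        raise ValueError("degenerate coefficients: no mobile ions, K_e unphysical")
    return first_integral_constant(coeffs, psi_inf, constants, slope_at=0.0)


def cytoplasm_constant(
    coeffs: RegionCoefficients,
    psi_cyt_bulk: float,
    constants: PhysicalConstants | None = None,
) -> FirstIntegralConstant:
    """K_c from dpsi/dx -> 0 as psi -> psi(+inf) = delta_psi.

    The cytoplasmic fixed-charge term enters through ``coeffs.fixed_term``.
    """
    constants = constants or PhysicalConstants()
    return first_integral_constant(coeffs, psi_cyt_bulk, constants, slope_at=0.0)


def glycocalyx_constant(
    psi2: float,
    field_at_s2_glyco_side: float,
    coeffs: RegionCoefficients,
    constants: PhysicalConstants | None = None,
) -> FirstIntegralConstant:
    """K_g from the glycocalyx-side electric field at S2.

    ``field_at_s2_glyco_side`` is E_g(S2) = -dpsi/dx, so its square is the
    slope squared required at (x_S2, psi2).
    """
    constants = constants or PhysicalConstants()
    return first_integral_constant(
        coeffs, psi2, constants, slope_at=-field_at_s2_glyco_side
    )


@dataclass(frozen=True)
class RegionODE:
    """dpsi/dx = slope_sign * sqrt(G_j(psi)) anchored at ``boundary_point``."""

    region: str
    coefficients: RegionCoefficients
    constant: FirstIntegralConstant
    slope_sign: float
    boundary_point: tuple[float, float]  # (x, psi)
    constants: PhysicalConstants
    #: if True, a negative first-integral argument parks the trajectory at
    #: the turning point (slope 0) instead of raising; used when stitching
    #: profiles, where the region width is not constrained by the surface
    #: system and the trajectory may exhaust its branch inside the region
    saturating: bool = False

    def rhs_squared(self, psi: float) -> float:
        """The first-integral expression G_j(psi) = (dpsi/dx)^2."""
        c = self.coefficients
        u = (psi - c.psi_bound) / self.constants.thermal_voltage
        return (
            c.alpha * math.cosh(u)
            + c.beta * math.cosh(2.0 * u)
            - c.fixed_term * psi
            + self.constant.value
        )

    def rhs_squared_derivative(self, psi: float) -> float:
        """d/dpsi of the first-integral expression (analytic)."""
        c = self.coefficients
        vt = self.constants.thermal_voltage
        u = (psi - c.psi_bound) / vt
        return (
            c.alpha * math.sinh(u) / vt
            + 2.0 * c.beta * math.sinh(2.0 * u) / vt
            - c.fixed_term
        )

    def rhs_squared_second_derivative(self, psi: float) -> float:
        """d2/dpsi2 of the first-integral expression (analytic)."""
        c = self.coefficients
        vt = self.constants.thermal_voltage
        u = (psi - c.psi_bound) / vt
        return (c.alpha * math.cosh(u) + 4.0 * c.beta * math.cosh(2.0 * u)) / (vt * vt)

    def rhs_squared_third_derivative(self, psi: float) -> float:
        """d3/dpsi3 of the first-integral expression (analytic)."""
        c = self.coefficients
        vt = self.constants.thermal_voltage
        u = (psi - c.psi_bound) / vt
        return (c.alpha * math.sinh(u) + 8.0 * c.beta * math.sinh(2.0 * u)) / (vt ** 3)

    def turning_point(self) -> tuple[float, float] | None:
        """Nearest simple zero of G_j along the travel direction, if any.

        Returns ``(psi_t, abs(G_j'(psi_t)))`` or ``None`` when the branch has
        no reachable simple turning point (e.g. the exponential approach to
        an uncharged bulk, where the zero is a double root).  The location is
        found to machine precision and is independent of any step size, so
        integrators can hand over to the local closed form reproducibly.
        """
        s = self.slope_sign
        if s == 0.0:
            return None
        psi0 = self.boundary_point[1]
        # geometric offsets resolve zeros arbitrarily close to the anchor;
        # the span is capped before cosh overflows (and far beyond any
        # physical potential)
        span = 200.0 * self.constants.thermal_voltage
        offsets = np.geomspace(1e-12, span, 2400)
        g_prev = self.rhs_squared(psi0)
        psi_prev = psi0
        bracket = None
        for off in offsets:
            p = psi0 + s * off
            try:
                g = self.rhs_squared(p)
            except OverflowError:
                break  # cosh blow-up: G is hugely positive, no zero beyond
            if g <= 0.0 and g_prev > 0.0:
                bracket = (psi_prev, p)
                break
            g_prev, psi_prev = g, p
        if bracket is None:
            return None
        from scipy.optimize import brentq

        psi_t = brentq(self.rhs_squared, bracket[0], bracket[1],
                       xtol=1e-300, rtol=8.9e-16)
        gprime = abs(self.rhs_squared_derivative(psi_t))
        vt = self.constants.thermal_voltage
        if gprime < 1e-9 * self._scale() / vt:
            return None  # effectively a double root: smooth asymptote
        return float(psi_t), float(gprime)

    def _scale(self) -> float:
        c = self.coefficients
        return max(abs(c.alpha), abs(c.beta), abs(self.constant.value), 1e-300)

    def slope(self, psi: float) -> float:
        """dpsi/dx at ``psi`` (statV/cm), clamping turning-point noise."""
        val = self.rhs_squared(psi)
        if val < 0.0:
            if self.saturating or val >= -TURNING_POINT_TOL * self._scale():
                val = 0.0
            else:
                raise BranchError(
                    f"potential {psi!r} outside reachable branch in region "
                    f"{self.region!r} (rhs^2 = {val:.3e})"
                )
        return self.slope_sign * math.sqrt(val)


def bilayer_profile(
    psi2: float,
    psi3: float,
    geometry: RegionGeometry,
    x: float,
) -> float:
    """Linear potential inside the charge-free bilayer.

    The implied field E_m = -(psi3 - psi2)/hb is constant.
    """
    if not (geometry.x_s2 <= x <= geometry.x_s3):
        raise ValueError(
            f"x={x!r} outside bilayer [{geometry.x_s2!r}, {geometry.x_s3!r}]"
        )
    t = (x - geometry.x_s2) / geometry.bilayer_thickness_hb
    return psi2 + t * (psi3 - psi2)
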