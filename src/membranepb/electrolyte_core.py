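"""Boltzmann ion statistics and the ionic coefficients of the first integral.

For a symmetric electrolyte truncated to mono- and divalent salt pairs, the
mean-field charge density in an aqueous region j is

    rho_ions(psi) = -2 q N_A [ C1_j sinh(u) + 2 C2_j sinh(2u) ],
    u = q (psi - psi_bar_j) / (kT),

and the first integral of the Gaussian-units Poisson-Boltzmann equation is

    (dpsi/dx)^2 = alpha_j cosh(u) + beta_j cosh(2u) - f_j psi + K_j,

with alpha_j = 16 pi N_A kT C1_j / eps_j, beta_j the same with C2_j, and
f_j = 8 pi rho_fj / eps_j the protein fixed-charge term.

The Debye length and Gouy-Chapman closed forms below are classical
validation oracles; they are not part of the simulator path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .units_and_parameters import (
    AVOGADRO,
    PhysicalConstants,
    RegionBoundary,
)

__all__ = [
    "IonSpecies",
    "RegionCoefficients",
    "boltzmann_concentration",
    "volumetric_charge_density",
    "region_coefficients",
    "debye_length",
    "gouy_chapman_profile",
    "symmetric_species",
]

_ALLOWED_VALENCES = (1, -1, 2, -2)


@dataclass(frozen=True)
class IonSpecies:
    """One mobile ion species with its regional boundary concentration."""

    valence_z: int
    boundary_conc: float  # mol/cm3
    region: str = "e"

    def __post_init__(self):
        if self.valence_z not in _ALLOWED_VALENCES:
            raise ValueError(
                f"valence must be one of {_ALLOWED_VALENCES}, got {self.valence_z}"
            )


@dataclass(frozen=True)
class RegionCoefficients:
    """alpha/beta ionic-strength coefficients of the PB first integral.

    ``fixed_term`` is f_j = 8 pi rho_fj / eps_j (statV/cm^2 per statV once
    multiplied by psi); it is 0 in the extracellular region.
    """

    alpha: float
    beta: float
    fixed_term: float
    region: str
    psi_bound: float  # statV; reference potential of the boundary pair


def symmetric_species(boundary: RegionBoundary, region: str) -> list[IonSpecies]:
    """The four species (+-1, +-2) of the symmetric-electrolyte truncation."""
    return [
        IonSpecies(+1, boundary.mono_conc_bound, region),
        IonSpecies(-1, boundary.mono_conc_bound, region),
        IonSpecies(+2, boundary.div_conc_bound, region),
        IonSpecies(-2, boundary.div_conc_bound, region),
    ]


def boltzmann_concentration(
    species: IonSpecies,
    psi: float,
    psi_bound: float,
    constants: PhysicalConstants,
) -> float:
    """Molar density of ``species`` at potential ``psi``.

    C = C_bar * exp(-z q (psi - psi_bar) / kT).
    """
    if not math.isfinite(psi):
        raise ValueError("psi must be finite")
    u = species.valence_z * constants.electron_charge_q * (psi - psi_bound) / constants.kT
    return species.boundary_conc * math.exp(-u)


def volumetric_charge_density(
    concs: Sequence[tuple[IonSpecies, float]],
    constants: PhysicalConstants,
) -> float:
    """Net mobile charge density, statC/cm3, from (species, molar conc) pairs.

    Avogadro scaling from molar density to particle density is applied here.
    """
    if len(concs) == 0:
        raise ValueError("species list must be non-empty")
    total = 0.0
    for sp, c in concs:
        total += sp.valence_z * c
    return constants.electron_charge_q * AVOGADRO * total


def region_coefficients(
    boundary: RegionBoundary,
    rho_f: float,
    dielectric: float,
    constants: PhysicalConstants,
    region: str,
) -> RegionCoefficients:
    """Build the alpha/beta/fixed-term coefficient triple for one region."""
    if region not in ("e", "g", "c"):
        raise ValueError(f"region must be 'e', 'g' or 'c', got {region!r}")
    if dielectric <= 0:
        raise ValueError("dielectric constant must be positive")
    if region == "e" and rho_f != 0.0:
        raise ValueError("extracellular fixed charge density must be zero")
    kT = constants.kT
    pref = 16.0 * math.pi * AVOGADRO * kT / dielectric
    return RegionCoefficients(
        alpha=pref * boundary.mono_conc_bound,
        beta=pref * boundary.div_conc_bound,
        fixed_term=8.0 * math.pi * rho_f / dielectric,
        region=region,
        psi_bound=boundary.psi_bound,
    )


def debye_length(
    boundary: RegionBoundary,
    dielectric: float,
    constants: PhysicalConstants,
) -> float:
    """Debye screening length (cm) for the symmetric mono+divalent mixture.

    kappa^2 = (4 pi q^2 N_A / (eps kT)) * sum_i z_i^2 C_i
            = (4 pi q^2 N_A / (eps kT)) * (2 C1 + 8 C2).
    """
    strength = 2.0 * boundary.mono_conc_bound + 8.0 * boundary.div_conc_bound
    if strength <= 0:
        raise ValueError("ionic strength must be positive")
    q = constants.electron_charge_q
    kappa_sq = 4.0 * math.pi * q * q * AVOGADRO * strength / (dielectric * constants.kT)
    return 1.0 / math.sqrt(kappa_sq)


def gouy_chapman_profile(
    psi0: float,
    mono_conc: float,
    dielectric: float,
    constants: PhysicalConstants,
    x_grid: Iterable[float],
) -> np.ndarray:
    """Closed-form nonlinear diffuse-layer potential for a 1:1 electrolyte.

    psi(x) = (4 kT / q) * atanh( tanh(q psi0 / 4kT) * exp(-kappa x) ),
    with x >= 0 the distance from the charged plane.  Valid only with no
    divalent ions and no fixed charges; used as an independent oracle.
    """
    x = np.asarray(list(x_grid), dtype=float)
    if mono_conc <= 0:
        raise ValueError("monovalent concentration must be positive")
    boundary = RegionBoundary(mono_conc_bound=mono_conc, div_conc_bound=0.0, psi_bound=0.0)
    kappa = 1.0 / debye_length(boundary, dielectric, constants)
    vt = constants.thermal_voltage
    gamma = math.tanh(psi0 / (4.0 * vt))
    return 4.0 * vt * np.arctanh(gamma * np.exp(-kappa * x))
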