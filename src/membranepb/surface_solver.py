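"""Surface potentials psi1, psi2, psi3 of the four-region membrane.

psi1 follows from electrophoretic mobility through the
Helmholtz-Smoluchowski relation.  psi2 and psi3 solve a two-variable
nonlinear system obtained by matching the Gauss-law field discontinuities
at S2 and S3 against the first-integral fields of the glycocalyx and
cytoplasm regions:

    S1:  eps_g E_g(S1) - eps_e E_e(S1) = 4 pi sigma1
    S2:  eps_b E_m     - eps_g E_g(S2) = 4 pi sigma2
    S3:  eps_c E_c(S3) - eps_b E_m     = 4 pi sigma3

with E_m = -(psi3 - psi2)/hb the constant bilayer field.  Writing the
interface fields with the regional first integrals turns S2 into an
implicit map psi2 = G(psi3) and S3 into psi3 = F(psi2); the solver finds
the fixed point of their composition.

The default root search mirrors the published scan-and-iterate heuristic
(tolerance eps = 1e-4 mV, acceptance band delta = 20 mV); a bracketed
scalar solve on h(psi3) = F(G(psi3)) - psi3 is kept as a deterministic
fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .electrolyte_core import RegionCoefficients, region_coefficients
from .region_odes import (
    BranchError,
    FirstIntegralConstant,
    cytoplasm_constant,
    extracellular_constant,
    glycocalyx_constant,
)
from .units_and_parameters import (
    ElectrokineticParams,
    ModelInputs,
    mv_to_statv,
    statv_to_mv,
)

__all__ = [
    "SurfacePotentials",
    "JumpCondition",
    "NoRootError",
    "psi1_from_mobility",
    "check_jump",
    "surface_map_G",
    "surface_map_F",
    "solve_surface_potentials",
    "MembraneSystem",
]

#: published fixed-point convergence tolerance, statV
EPSILON = mv_to_statv(1e-4)
#: published initial acceptance band for an iteration step, statV
DELTA = mv_to_statv(20.0)
#: default scan window for psi3 (and psi2 roots), statV
PSI3_WINDOW = (mv_to_statv(-200.0), mv_to_statv(100.0))
PSI2_WINDOW = (mv_to_statv(-300.0), mv_to_statv(150.0))
#: initial-guess spacing for the scan, statV
SCAN_STEP = mv_to_statv(0.1)

_MAP_GRID_N = 1500
_MAX_FIXED_POINT_ITER = 100
#: restart budget for the scan-and-iterate heuristic; beyond this the window
#: is declared rootless (the bracketed fallback remains available)
_MAX_SCAN_CANDIDATES = 250
#: hard cap on map evaluations per solve, to bound worst-case runtime
_MAX_TOTAL_ITER = 2000


class NoRootError(RuntimeError):
    """No root of the surface system inside the configured scan window."""


@dataclass(frozen=True)
class SurfacePotentials:
    psi1: float
    psi2: float
    psi3: float
    residual_F: float
    residual_G: float
    iterations: int
    method: str  # "paper_fixed_point" | "bracketed_fallback"
    converged: bool = True
    warnings: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "psi1_mV": statv_to_mv(self.psi1),
            "psi2_mV": statv_to_mv(self.psi2),
            "psi3_mV": statv_to_mv(self.psi3),
            "residual_F_mV": statv_to_mv(self.residual_F),
            "residual_G_mV": statv_to_mv(self.residual_G),
            "iterations": self.iterations,
            "method": self.method,
            "converged": self.converged,
            "warnings": list(self.warnings),
        }


@dataclass(frozen=True)
class JumpCondition:
    surface: str  # "S1" | "S2" | "S3"
    sigma: float  # statC/cm2
    eps_left: float
    eps_right: float
    field_left: float   # statV/cm, x-component on the smaller-x side
    field_right: float  # statV/cm, x-component on the larger-x side


def check_jump(cond: JumpCondition) -> float:
    """Signed residual (statV/cm) of the Gauss-law field discontinuity.

    The relation is eps_right E_right - eps_left E_left = 4 pi sigma; the
    residual is normalized by the mean dielectric so that with sigma = 0
    and equal dielectrics it reduces to field_left - field_right.
    """
    eps_mean = 0.5 * (cond.eps_left + cond.eps_right)
    return (
        cond.eps_left * cond.field_left
        + 4.0 * math.pi * cond.sigma
        - cond.eps_right * cond.field_right
    ) / eps_mean


def psi1_from_mobility(
    kinetics: ElectrokineticParams,
    dielectric: float,
    psi_extracellular_bulk: float = 0.0,
) -> float:
    """psi1 from the Helmholtz-Smoluchowski zeta potential.

    zeta = 4 pi eta mu / eps (Gaussian units); with the extracellular bulk
    potential defined as 0, psi1 = zeta + psi(-inf).
    """
    if kinetics.viscosity_eta <= 0:
        raise ValueError("viscosity must be positive")
    zeta = (
        4.0 * math.pi * kinetics.viscosity_eta * kinetics.electrophoretic_mobility
        / dielectric
    )
    return zeta + psi_extracellular_bulk


def _find_roots(fun_vec, window: tuple[float, float], n_grid: int) -> list[float]:
    """All simple roots of ``fun_vec`` (vectorized) inside ``window``."""
    lo, hi = window
    xs = np.linspace(lo, hi, n_grid)
    with np.errstate(over="ignore", invalid="ignore"):
        ys = fun_vec(xs)
    good = np.isfinite(ys)
    roots: list[float] = []
    sign = np.sign(ys)
    for i in range(len(xs) - 1):
        if not (good[i] and good[i + 1]):
            continue
        if ys[i] == 0.0:
            roots.append(float(xs[i]))
            continue
        if sign[i] * sign[i + 1] < 0:
            r = brentq(lambda t: float(fun_vec(t)), xs[i], xs[i + 1],
                       xtol=1e-16, rtol=8.9e-16)
            roots.append(float(r))
    if len(xs) and good[-1] and ys[-1] == 0.0:
        roots.append(float(xs[-1]))
    if not roots and good.any():
        # tangent (double) root: |f| dips to ~0 without a sign change, e.g.
        # the source-free configuration where both sides vanish quadratically
        from scipy.optimize import minimize_scalar

        i = int(np.nanargmin(np.where(good, np.abs(ys), np.inf)))
        a = xs[max(i - 1, 0)]
        b = xs[min(i + 1, len(xs) - 1)]
        res = minimize_scalar(lambda t: abs(float(fun_vec(t))),
                              bounds=(a, b), method="bounded",
                              options={"xatol": 1e-16})
        scale = float(np.nanmax(np.abs(np.where(good, ys, 0.0)))) + 1e-300
        if abs(res.fun) <= 1e-10 * scale:
            roots.append(float(res.x))
    return roots


class MembraneSystem:
    """Precomputed coefficients and interface relations for one input set.

    Builds the regional alpha/beta coefficients, the extracellular and
    cytoplasmic first-integral constants, psi1, and the glycocalyx-side
    field at S1 implied by the S1 jump condition.
    """

    def __init__(self, inputs: ModelInputs):
        self.inputs = inputs
        cst = inputs.constants
        d = inputs.dielectrics
        ions = inputs.ions
        ch = inputs.charges

        self.psi1 = psi1_from_mobility(
            inputs.kinetics, d.eps_extracellular, ions.extracellular.psi_bound
        )
        # the glycocalyx Boltzmann reference pair is (C_S1, psi1)
        gly_boundary = replace(ions.glycocalyx, psi_bound=self.psi1)

        self.coeffs_e = region_coefficients(
            ions.extracellular, 0.0, d.eps_extracellular, cst, "e")
        self.coeffs_g = region_coefficients(
            gly_boundary, ch.rho_f_glycocalyx, d.eps_glycocalyx, cst, "g")
        self.coeffs_c = region_coefficients(
            ions.cytoplasm, ch.rho_f_cytoplasm, d.eps_cytoplasm, cst, "c")

        self.delta_psi = inputs.state.transmembrane_potential
        self.K_e = extracellular_constant(
            self.coeffs_e, ions.extracellular.psi_bound, cst)
        self.K_c = cytoplasm_constant(self.coeffs_c, self.delta_psi, cst)

        # extracellular field on S1 from the diffuse-layer first integral
        psi_inf = ions.extracellular.psi_bound
        g_e = self._expr(self.coeffs_e, self.K_e, self.psi1)
        slope_e = math.copysign(math.sqrt(max(g_e, 0.0)), self.psi1 - psi_inf)
        self.E_e_s1 = -slope_e
        # S1 jump condition fixes the glycocalyx-side field at S1
        self.E_g_s1 = (
            d.eps_extracellular * self.E_e_s1 + 4.0 * math.pi * ch.sigma_s1
        ) / d.eps_glycocalyx
        self.K_g = glycocalyx_constant(self.psi1, self.E_g_s1, self.coeffs_g, cst)

    # -- first-integral expression ------------------------------------
    def _expr(self, coeffs: RegionCoefficients, K: FirstIntegralConstant,
              psi) -> float | np.ndarray:
        vt = self.inputs.constants.thermal_voltage
        u = (psi - coeffs.psi_bound) / vt
        return (
            coeffs.alpha * np.cosh(u)
            + coeffs.beta * np.cosh(2.0 * u)
            - coeffs.fixed_term * psi
            + K.value
        )

    def bilayer_field(self, psi2, psi3):
        """E_m = -(psi3 - psi2)/hb."""
        return -(psi3 - psi2) / self.inputs.geometry.bilayer_thickness_hb

    # -- the two implicit surface relations ----------------------------
    def residual_s2(self, psi2, psi3):
        """S2 relation: [ (eps_b E_m - 4 pi sigma2)/eps_g ]^2 - G_g(psi2)."""
        d = self.inputs.dielectrics
        lhs = (
            d.eps_bilayer * self.bilayer_field(psi2, psi3)
            - 4.0 * math.pi * self.inputs.charges.sigma_s2
        ) / d.eps_glycocalyx
        return lhs * lhs - self._expr(self.coeffs_g, self.K_g, psi2)

    def residual_s3(self, psi2, psi3):
        """S3 relation: [ (eps_b E_m + 4 pi sigma3)/eps_c ]^2 - G_c(psi3)."""
        d = self.inputs.dielectrics
        lhs = (
            d.eps_bilayer * self.bilayer_field(psi2, psi3)
            + 4.0 * math.pi * self.inputs.charges.sigma_s3
        ) / d.eps_cytoplasm
        return lhs * lhs - self._expr(self.coeffs_c, self.K_c, psi3)

    def map_G(self, psi3: float, window=PSI2_WINDOW) -> float:
        """psi2 = G(psi3): root of the S2 relation, nearest to psi1.

        The squared field match admits a branch whose glycocalyx-side field
        direction at S2 contradicts a monotone run from psi1 to psi2; such
        roots are filtered out before the proximity tie-break.
        """
        d = self.inputs.dielectrics
        roots = _find_roots(lambda p2: self.residual_s2(p2, psi3), window,
                            _MAP_GRID_N)
        if not roots:
            raise NoRootError(
                f"no psi2 root in window for psi3 = {statv_to_mv(psi3):.3f} mV")

        def consistent(p2: float) -> bool:
            e_g_s2 = (
                d.eps_bilayer * self.bilayer_field(p2, psi3)
                - 4.0 * math.pi * self.inputs.charges.sigma_s2
            ) / d.eps_glycocalyx
            # slope at S2 is -E_g(S2); it must point from psi1 toward psi2
            return (-e_g_s2) * (p2 - self.psi1) >= 0.0

        keep = [r for r in roots if consistent(r)] or roots
        return min(keep, key=lambda r: abs(r - self.psi1))

    def map_F(self, psi2: float, window=PSI3_WINDOW) -> float:
        """psi3 = F(psi2): root of the S3 relation, nearest to delta_psi.

        Roots where the cytoplasm-side field direction at S3 contradicts a
        monotone approach from psi3 to the bulk value are filtered out.
        """
        d = self.inputs.dielectrics
        roots = _find_roots(lambda p3: self.residual_s3(psi2, p3), window,
                            _MAP_GRID_N)
        if not roots:
            raise NoRootError(
                f"no psi3 root in window for psi2 = {statv_to_mv(psi2):.3f} mV")

        def consistent(p3: float) -> bool:
            e_c_s3 = (
                d.eps_bilayer * self.bilayer_field(psi2, p3)
                + 4.0 * math.pi * self.inputs.charges.sigma_s3
            ) / d.eps_cytoplasm
            # slope at S3 is -E_c(S3); it must point from psi3 toward bulk
            return (-e_c_s3) * (self.delta_psi - p3) >= 0.0

        keep = [r for r in roots if consistent(r)] or roots
        return min(keep, key=lambda r: abs(r - self.delta_psi))

    # -- interface fields at a converged solution -----------------------
    def interface_fields(self, psi2: float, psi3: float) -> dict:
        d = self.inputs.dielectrics
        ch = self.inputs.charges
        E_m = self.bilayer_field(psi2, psi3)
        E_g_s2 = (d.eps_bilayer * E_m - 4.0 * math.pi * ch.sigma_s2) / d.eps_glycocalyx
        E_c_s3 = (d.eps_bilayer * E_m + 4.0 * math.pi * ch.sigma_s3) / d.eps_cytoplasm
        return {
            "E_e_s1": self.E_e_s1,
            "E_g_s1": self.E_g_s1,
            "E_g_s2": E_g_s2,
            "E_m": E_m,
            "E_c_s3": E_c_s3,
        }

    def jump_conditions(self, psi2: float, psi3: float) -> list[JumpCondition]:
        """The three Gauss conditions with ODE-side fields on the aqueous side.

        The aqueous-side fields at S2 and S3 are recomputed from the regional
        first integrals (signed to match the jump-derived direction), so the
        residuals measure how well the surface system is actually solved.
        """
        d = self.inputs.dielectrics
        ch = self.inputs.charges
        f = self.interface_fields(psi2, psi3)
        g_g2 = self._expr(self.coeffs_g, self.K_g, psi2)
        g_c3 = self._expr(self.coeffs_c, self.K_c, psi3)
        E_g_s2_ode = math.copysign(math.sqrt(max(g_g2, 0.0)), f["E_g_s2"])
        E_c_s3_ode = math.copysign(math.sqrt(max(g_c3, 0.0)), f["E_c_s3"])
        return [
            JumpCondition("S1", ch.sigma_s1, d.eps_extracellular,
                          d.eps_glycocalyx, f["E_e_s1"], f["E_g_s1"]),
            JumpCondition("S2", ch.sigma_s2, d.eps_glycocalyx,
                          d.eps_bilayer, E_g_s2_ode, f["E_m"]),
            JumpCondition("S3", ch.sigma_s3, d.eps_bilayer,
                          d.eps_cytoplasm, f["E_m"], E_c_s3_ode),
        ]


def surface_map_G(psi3: float, inputs: ModelInputs) -> float:
    """psi2 satisfying the S2 surface relation, given psi3."""
    return MembraneSystem(inputs).map_G(psi3)


def surface_map_F(psi2: float, inputs: ModelInputs) -> float:
    """psi3 satisfying the S3 surface relation, given psi2."""
    return MembraneSystem(inputs).map_F(psi2)


def _fixed_point(system: MembraneSystem, window) -> tuple[float, float, int]:
    """The published scan-and-iterate heuristic.

    Initial psi3 guesses cover the window at SCAN_STEP spacing, tried in
    order of proximity to the transmembrane potential.  An iteration step
    psi3 -> F(G(psi3)) is accepted while the update stays inside the
    delta = 20 mV band; otherwise the scan restarts from the next guess.
    """
    lo, hi = window
    n = max(2, int(round((hi - lo) / SCAN_STEP)) + 1)
    guesses = np.linspace(lo, hi, n)
    order = np.argsort(np.abs(guesses - system.delta_psi))
    total_iter = 0
    for idx in order[:_MAX_SCAN_CANDIDATES]:
        psi3 = float(guesses[idx])
        try:
            for _ in range(_MAX_FIXED_POINT_ITER):
                if total_iter >= _MAX_TOTAL_ITER:
                    raise NoRootError(
                        "fixed-point iteration budget exhausted without a root")
                total_iter += 1
                psi2 = system.map_G(psi3)
                psi3_new = system.map_F(psi2)
                diff = abs(psi3_new - psi3)
                if diff >= DELTA:
                    break  # outside the acceptance band: restart (Step 1)
                if diff < EPSILON:
                    return psi2, psi3_new, total_iter
                psi3 = psi3_new
            else:
                continue
        except (NoRootError, BranchError):
            continue
    raise NoRootError("fixed-point scan exhausted the window without a root")


def _bracketed(system: MembraneSystem, window) -> tuple[float, float, int]:
    """Deterministic fallback: bracketed solve of h(psi3) = F(G(psi3)) - psi3."""
    lo, hi = window
    evals = 0

    def h(psi3: float) -> float:
        nonlocal evals
        evals += 1
        return system.map_F(system.map_G(psi3)) - psi3

    n_coarse = 301
    xs = np.linspace(lo, hi, n_coarse)
    vals = np.full(n_coarse, np.nan)
    for i, x in enumerate(xs):
        try:
            vals[i] = h(float(x))
        except (NoRootError, BranchError):
            pass
    roots = []
    for i in range(n_coarse - 1):
        if np.isfinite(vals[i]) and np.isfinite(vals[i + 1]) \
                and vals[i] * vals[i + 1] < 0:
            r = brentq(h, float(xs[i]), float(xs[i + 1]),
                       xtol=1e-16, rtol=8.9e-16)
            roots.append(float(r))
        elif np.isfinite(vals[i]) and vals[i] == 0.0:
            roots.append(float(xs[i]))
    if not roots:
        raise NoRootError("bracketed fallback found no root in window")
    psi3 = min(roots, key=lambda r: abs(r - system.delta_psi))
    return system.map_G(psi3), psi3, evals


def solve_surface_potentials(
    inputs: ModelInputs,
    method: str = "paper_fixed_point",
    window: tuple[float, float] = PSI3_WINDOW,
) -> SurfacePotentials:
    """Solve the two-variable surface system for (psi2, psi3).

    ``method`` is ``"paper_fixed_point"`` (default) or
    ``"bracketed_fallback"``.  Raises :class:`NoRootError` when the scan
    window contains no solution.
    """
    system = MembraneSystem(inputs)
    if method == "paper_fixed_point":
        psi2, psi3, iters = _fixed_point(system, window)
    elif method == "bracketed_fallback":
        psi2, psi3, iters = _bracketed(system, window)
    else:
        raise ValueError(f"unknown method {method!r}")

    residual_G = abs(system.map_G(psi3) - psi2)
    residual_F = abs(system.map_F(psi2) - psi3)
    warnings: list[str] = []

    # multiplicity check at the solution
    try:
        roots3 = _find_roots(lambda p3: system.residual_s3(psi2, p3),
                             window, 1001)
        if len(roots3) > 1:
            warnings.append(
                f"multiple psi3 roots in window ({len(roots3)}); "
                "selected the one nearest the transmembrane potential")
    except Exception:  # pragma: no cover - diagnostic only
        pass

    return SurfacePotentials(
        psi1=system.psi1,
        psi2=psi2,
        psi3=psi3,
        residual_F=residual_F,
        residual_G=residual_G,
        iterations=iters,
        method=method,
        converged=max(residual_F, residual_G) < 10 * EPSILON,
        warnings=tuple(warnings),
    )
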