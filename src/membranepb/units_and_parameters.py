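"""Physical symbols, unit conversion, invariant checking and cell presets.

All internal computation is carried out in Gaussian CGS units (cm, statC,
statV, erg, poise): the Poisson equation then reads
``d2psi/dx2 = -4*pi*rho/eps`` with a dimensionless dielectric constant.
SI values are accepted and emitted at I/O boundaries only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

__all__ = [
    "AVOGADRO",
    "SPEED_OF_LIGHT_CM_S",
    "STATV_PER_VOLT",
    "PhysicalConstants",
    "RegionGeometry",
    "RegionDielectrics",
    "RegionBoundary",
    "IonicBoundary",
    "FixedCharges",
    "ElectrokineticParams",
    "MembraneState",
    "ModelInputs",
    "Check",
    "ValidationReport",
    "convert_units",
    "load_preset",
    "available_presets",
    "validate_inputs",
    "mv_to_statv",
    "statv_to_mv",
]

AVOGADRO = 6.02214076e23  # 1/mol
SPEED_OF_LIGHT_CM_S = 2.99792458e10
#: 1 statV = 299.792458 V
STATV_PER_VOLT = 1.0 / 299.792458


def mv_to_statv(value_mv: float) -> float:
    """Convert millivolts to statvolts."""
    return value_mv * 1e-3 * STATV_PER_VOLT


def statv_to_mv(value_statv: float) -> float:
    """Convert statvolts to millivolts."""
    return value_statv * 299.792458 * 1e3


# ---------------------------------------------------------------------------
# Unit conversion between the CGS system used internally and SI
# ---------------------------------------------------------------------------

# dimension -> multiplicative factor taking a CGS value to SI
_CGS_TO_SI = {
    "length": 1e-2,                       # cm -> m
    "concentration": 1e3,                 # mol/cm3 -> mol/L
    "charge": 1.0 / 2.99792458e9,         # statC -> C
    "surface_charge_density": 1e4 / 2.99792458e9,   # statC/cm2 -> C/m2
    "volume_charge_density": 1e6 / 2.99792458e9,    # statC/cm3 -> C/m3
    "potential": 299.792458,              # statV -> V
    "electric_field": 299.792458e2,       # statV/cm -> V/m
    "viscosity": 0.1,                     # poise -> Pa*s
    "mobility": 1e-4 / 299.792458,        # cm2/(statV*s) -> m2/(V*s)
    "energy": 1e-7,                       # erg -> J
    "temperature": 1.0,                   # K -> K
}


def convert_units(value: float, dimension: str, to: str) -> float:
    """Convert ``value`` of the given dimension between CGS and SI.

    Parameters
    ----------
    value:
        Numeric magnitude in the *source* system (the system other than
        ``to``).
    dimension:
        One of the supported dimensions (see ``_CGS_TO_SI``).
    to:
        Target system, ``"SI"`` or ``"CGS"``.
    """
    if dimension not in _CGS_TO_SI:
        raise ValueError(f"unsupported dimension: {dimension!r}")
    if to not in ("SI", "CGS"):
        raise ValueError(f"unknown target unit system: {to!r}")
    factor = _CGS_TO_SI[dimension]
    return value * factor if to == "SI" else value / factor


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants in CGS plus the working temperature."""

    boltzmann_k: float = 1.380649e-16   # erg/K
    electron_charge_q: float = 4.8032047126e-10  # statC
    temperature_T: float = 310.0        # K

    @property
    def kT(self) -> float:
        return self.boltzmann_k * self.temperature_T

    @property
    def thermal_voltage(self) -> float:
        """kT/q in statV."""
        return self.kT / self.electron_charge_q


@dataclass(frozen=True)
class RegionGeometry:
    """Slab geometry; x increases from extracellular to cytoplasm.

    The origin is pinned to the outer surface: x_S1 = 0, x_S2 = hg,
    x_S3 = hg + hb.
    """

    glycocalyx_width_hg: float  # cm
    bilayer_thickness_hb: float  # cm

    @property
    def x_s1(self) -> float:
        return 0.0

    @property
    def x_s2(self) -> float:
        return self.glycocalyx_width_hg

    @property
    def x_s3(self) -> float:
        return self.glycocalyx_width_hg + self.bilayer_thickness_hb


@dataclass(frozen=True)
class RegionDielectrics:
    eps_extracellular: float
    eps_glycocalyx: float
    eps_bilayer: float
    eps_cytoplasm: float

    def for_region(self, region: str) -> float:
        return {
            "e": self.eps_extracellular,
            "g": self.eps_glycocalyx,
            "b": self.eps_bilayer,
            "c": self.eps_cytoplasm,
        }[region]


@dataclass(frozen=True)
class RegionBoundary:
    """Reference (concentration, potential) pair for one aqueous region.

    ``mono_conc_bound`` / ``div_conc_bound`` are the limiting molar densities
    (mol/cm3) of the symmetric mono- and divalent salt, ``psi_bound`` the
    potential (statV) at which those concentrations are referenced.
    """

    mono_conc_bound: float
    div_conc_bound: float
    psi_bound: float


@dataclass(frozen=True)
class IonicBoundary:
    extracellular: RegionBoundary
    glycocalyx: RegionBoundary
    cytoplasm: RegionBoundary

    def for_region(self, region: str) -> RegionBoundary:
        return {
            "e": self.extracellular,
            "g": self.glycocalyx,
            "c": self.cytoplasm,
        }[region]


@dataclass(frozen=True)
class FixedCharges:
    """Protein-fixed volumetric and surface charge densities (CGS)."""

    rho_f_glycocalyx: float  # statC/cm3
    rho_f_cytoplasm: float   # statC/cm3
    sigma_s1: float          # statC/cm2
    sigma_s2: float          # statC/cm2
    sigma_s3: float          # statC/cm2


@dataclass(frozen=True)
class ElectrokineticParams:
    electrophoretic_mobility: float  # cm2/(statV*s)
    viscosity_eta: float             # poise
    zeta_potential: float | None = None  # statV, derived


@dataclass(frozen=True)
class MembraneState:
    """Boundary-condition state: resting or action-potential peak.

    ``transmembrane_potential`` is psi(bulk cytoplasm) - psi(bulk
    extracellular) with the extracellular bulk fixed at 0.
    """

    label: str  # "resting" | "action"
    transmembrane_potential: float  # statV


@dataclass(frozen=True)
class ModelInputs:
    constants: PhysicalConstants
    geometry: RegionGeometry
    dielectrics: RegionDielectrics
    ions: IonicBoundary
    charges: FixedCharges
    kinetics: ElectrokineticParams
    state: MembraneState
    cell_name: str = ""

    def with_scaled_charge(self, quantity: str, ratio: float) -> "ModelInputs":
        """Return a copy with one fixed-charge quantity scaled by ``ratio``."""
        ch = self.charges
        if quantity == "sigma_S2_ratio":
            ch = replace(ch, sigma_s2=ratio * ch.sigma_s2)
        elif quantity == "sigma_S3_ratio":
            ch = replace(ch, sigma_s3=ratio * ch.sigma_s3)
        elif quantity == "rho_fc_ratio":
            ch = replace(ch, rho_f_cytoplasm=ratio * ch.rho_f_cytoplasm)
        elif quantity == "rho_fg_ratio":
            ch = replace(ch, rho_f_glycocalyx=ratio * ch.rho_f_glycocalyx)
        else:
            raise ValueError(f"unknown swept quantity: {quantity!r}")
        return replace(self, charges=ch)


# ---------------------------------------------------------------------------
# Validation report (shared with profile_integrator)
# ---------------------------------------------------------------------------


@dataclass
class Check:
    name: str
    passed: bool
    residual: float | None = None
    message: str = ""
    severity: str = "error"  # "error" | "warning"


@dataclass
class ValidationReport:
    checks: list[Check] = field(default_factory=list)

    def add(self, name: str, passed: bool, residual: float | None = None,
            message: str = "", severity: str = "error") -> None:
        self.checks.append(Check(name, passed, residual, message, severity))

    @property
    def passed(self) -> bool:
        return bool(all(c.passed for c in self.checks if c.severity == "error"))

    @property
    def warnings(self) -> list[Check]:
        return [c for c in self.checks if not c.passed and c.severity == "warning"]

    def as_dict(self) -> dict:
        return {
            "passed": self.passed,
            "checks": [
                {
                    "name": c.name,
                    "passed": bool(c.passed),
                    "residual": None if c.residual is None else float(c.residual),
                    "message": c.message,
                    "severity": c.severity,
                }
                for c in self.checks
            ],
        }


# ---------------------------------------------------------------------------
# Preset files
# ---------------------------------------------------------------------------

# unit token -> (dimension, factor taking the stated value to internal CGS)
_UNIT_TO_CGS = {
    "nm": ("length", 1e-7),
    "cm": ("length", 1.0),
    "m": ("length", 1e2),
    "M": ("concentration", 1e-3),          # mol/L -> mol/cm3
    "mol/L": ("concentration", 1e-3),
    "mol/cm3": ("concentration", 1.0),
    "statC/cm2": ("surface_charge_density", 1.0),
    "C/m2": ("surface_charge_density", 2.99792458e9 / 1e4),
    "statC/cm3": ("volume_charge_density", 1.0),
    "C/m3": ("volume_charge_density", 2.99792458e9 / 1e6),
    "statC": ("charge", 1.0),
    "C": ("charge", 2.99792458e9),
    "mV": ("potential", 1e-3 * STATV_PER_VOLT),
    "V": ("potential", STATV_PER_VOLT),
    "statV": ("potential", 1.0),
    "K": ("temperature", 1.0),
    "erg/K": ("energy_per_kelvin", 1.0),
    "J/K": ("energy_per_kelvin", 1e7),
    "P": ("viscosity", 1.0),
    "Pa.s": ("viscosity", 10.0),
    "cm2/statV/s": ("mobility", 1.0),
    "m2/V/s": ("mobility", 299.792458 * 1e4),
    "1": ("dimensionless", 1.0),
}

_REQUIRED_KEYS = [
    "cell_name", "state",
    "temperature", "boltzmann_k", "electron_charge",
    "glycocalyx_width", "bilayer_thickness",
    "eps_extracellular", "eps_glycocalyx", "eps_bilayer", "eps_cytoplasm",
    "mono_conc_extracellular", "div_conc_extracellular",
    "mono_conc_s1", "div_conc_s1",
    "mono_conc_cytoplasm", "div_conc_cytoplasm",
    "psi_extracellular_bulk",
    "rho_f_glycocalyx", "rho_f_cytoplasm",
    "sigma_s1", "sigma_s2", "sigma_s3",
    "viscosity", "electrophoretic_mobility",
    "transmembrane_potential",
]


def _parse_preset_text(text: str, origin: str) -> dict[str, float | str]:
    values: dict[str, float | str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{origin}:{lineno}: expected 'key = value [unit]'")
        key, rhs = (s.strip() for s in line.split("=", 1))
        parts = rhs.split()
        if not parts:
            raise ValueError(f"{origin}:{lineno}: missing value for {key!r}")
        try:
            magnitude = float(parts[0])
        except ValueError:
            values[key] = rhs
            continue
        if len(parts) == 1:
            values[key] = magnitude
            continue
        unit = parts[1]
        if unit not in _UNIT_TO_CGS:
            raise ValueError(f"{origin}:{lineno}: unknown unit {unit!r}")
        values[key] = magnitude * _UNIT_TO_CGS[unit][1]
    return values


def _build_inputs(values: dict[str, float | str], origin: str) -> ModelInputs:
    missing = [k for k in _REQUIRED_KEYS if k not in values]
    if missing:
        raise KeyError(f"{origin}: preset missing required fields: {missing}")

    constants = PhysicalConstants(
        boltzmann_k=float(values["boltzmann_k"]),
        electron_charge_q=float(values["electron_charge"]),
        temperature_T=float(values["temperature"]),
    )
    geometry = RegionGeometry(
        glycocalyx_width_hg=float(values["glycocalyx_width"]),
        bilayer_thickness_hb=float(values["bilayer_thickness"]),
    )
    dielectrics = RegionDielectrics(
        eps_extracellular=float(values["eps_extracellular"]),
        eps_glycocalyx=float(values["eps_glycocalyx"]),
        eps_bilayer=float(values["eps_bilayer"]),
        eps_cytoplasm=float(values["eps_cytoplasm"]),
    )
    psi_bulk_e = float(values["psi_extracellular_bulk"])
    delta_psi = float(values["transmembrane_potential"])
    ions = IonicBoundary(
        extracellular=RegionBoundary(
            mono_conc_bound=float(values["mono_conc_extracellular"]),
            div_conc_bound=float(values["div_conc_extracellular"]),
            psi_bound=psi_bulk_e,
        ),
        # boundary concentrations for the glycocalyx are the measured S1
        # values, taken for every ion species alike
        glycocalyx=RegionBoundary(
            mono_conc_bound=float(values["mono_conc_s1"]),
            div_conc_bound=float(values["div_conc_s1"]),
            psi_bound=float(values.get("psi_s1", 0.0)),
        ),
        cytoplasm=RegionBoundary(
            mono_conc_bound=float(values["mono_conc_cytoplasm"]),
            div_conc_bound=float(values["div_conc_cytoplasm"]),
            psi_bound=delta_psi,
        ),
    )
    charges = FixedCharges(
        rho_f_glycocalyx=float(values["rho_f_glycocalyx"]),
        rho_f_cytoplasm=float(values["rho_f_cytoplasm"]),
        sigma_s1=float(values["sigma_s1"]),
        sigma_s2=float(values["sigma_s2"]),
        sigma_s3=float(values["sigma_s3"]),
    )
    kinetics = ElectrokineticParams(
        electrophoretic_mobility=float(values["electrophoretic_mobility"]),
        viscosity_eta=float(values["viscosity"]),
    )
    state = MembraneState(
        label=str(values["state"]),
        transmembrane_potential=delta_psi,
    )
    return ModelInputs(
        constants=constants,
        geometry=geometry,
        dielectrics=dielectrics,
        ions=ions,
        charges=charges,
        kinetics=kinetics,
        state=state,
        cell_name=str(values["cell_name"]),
    )


def available_presets() -> list[tuple[str, str]]:
    """List the (cell, state) pairs shipped with the package."""
    out = []
    for res in resources.files("membranepb.presets").iterdir():
        if res.name.endswith(".cfg"):
            cell, state = res.name[:-4].rsplit("_", 1)
            out.append((cell, state))
    return sorted(out)


def load_preset(cell_name: str, state_label: str) -> ModelInputs:
    """Load one of the built-in (cell, state) parameterizations.

    ``cell_name`` is ``"ganglion"`` or ``"neuroblastoma"``; ``state_label``
    is ``"resting"`` or ``"action"``.  Returns fully populated CGS inputs.
    """
    fname = f"{cell_name}_{state_label}.cfg"
    res = resources.files("membranepb.presets").joinpath(fname)
    if not res.is_file():
        raise ValueError(
            f"unknown preset {cell_name!r}/{state_label!r}; "
            f"available: {available_presets()}"
        )
    text = res.read_text(encoding="utf-8")
    return _build_inputs(_parse_preset_text(text, fname), fname)


def load_config(path: str | Path) -> ModelInputs:
    """Load a user configuration file in the preset key-value format."""
    p = Path(path)
    return _build_inputs(_parse_preset_text(p.read_text(encoding="utf-8"), str(p)), str(p))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_inputs(inputs: ModelInputs) -> ValidationReport:
    """Assert every type invariant; failures land in the report."""
    rep = ValidationReport()
    c, g, d = inputs.constants, inputs.geometry, inputs.dielectrics

    rep.add("boltzmann_k positive", c.boltzmann_k > 0)
    rep.add("electron charge positive", c.electron_charge_q > 0)
    rep.add("temperature positive", c.temperature_T > 0)

    rep.add("glycocalyx width must be positive", g.glycocalyx_width_hg > 0)
    rep.add("bilayer thickness must be positive", g.bilayer_thickness_hb > 0)
    rep.add("interface spacing consistent",
            math.isclose(g.x_s2 - g.x_s1, g.glycocalyx_width_hg)
            and math.isclose(g.x_s3 - g.x_s2, g.bilayer_thickness_hb))

    for name, eps in (("extracellular", d.eps_extracellular),
                      ("glycocalyx", d.eps_glycocalyx),
                      ("bilayer", d.eps_bilayer),
                      ("cytoplasm", d.eps_cytoplasm)):
        rep.add(f"dielectric {name} >= 1", eps >= 1.0)

    for region in ("e", "g", "c"):
        b = inputs.ions.for_region(region)
        rep.add(f"monovalent concentration positive ({region})", b.mono_conc_bound > 0)
        rep.add(f"divalent concentration non-negative ({region})", b.div_conc_bound >= 0)

    ch = inputs.charges
    rep.add("glycocalyx fixed charge non-positive", ch.rho_f_glycocalyx <= 0,
            severity="warning",
            message="sign contradicts the negatively charged glycocalyx")
    rep.add("cytoplasm fixed charge non-positive", ch.rho_f_cytoplasm <= 0,
            severity="warning",
            message="sign contradicts the negatively charged cytoplasmic proteins")
    rep.add("sigma_S2 non-positive", ch.sigma_s2 <= 0, severity="warning",
            message="sign contradicts the negatively charged outer bilayer surface")
    rep.add("sigma_S3 non-positive", ch.sigma_s3 <= 0, severity="warning",
            message="sign contradicts the negatively charged inner surface")

    rep.add("viscosity positive", inputs.kinetics.viscosity_eta > 0)

    st = inputs.state
    rep.add("state label known", st.label in ("resting", "action"))
    if st.label == "resting":
        rep.add("resting transmembrane potential negative",
                st.transmembrane_potential < 0, severity="warning")
    rep.add("extracellular bulk potential is zero",
            inputs.ions.extracellular.psi_bound == 0.0)
    return rep
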