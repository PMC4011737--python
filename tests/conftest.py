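import numpy as np
import pytest
from dataclasses import replace

from membranepb import load_preset
from membranepb.surface_solver import solve_surface_potentials
from membranepb.units_and_parameters import (
    ElectrokineticParams,
    FixedCharges,
    IonicBoundary,
    MembraneState,
    ModelInputs,
    PhysicalConstants,
    RegionBoundary,
    RegionDielectrics,
    RegionGeometry,
    mv_to_statv,
)


@pytest.fixture(scope="session")
def constants():
    return PhysicalConstants()


@pytest.fixture(scope="session")
def ganglion_resting():
    return load_preset("ganglion", "resting")


@pytest.fixture(scope="session")
def all_presets():
    return {
        (cell, state): load_preset(cell, state)
        for cell in ("ganglion", "neuroblastoma")
        for state in ("resting", "action")
    }


@pytest.fixture(scope="session")
def solved_presets(all_presets):
    """Surface solutions for every preset, shared across the suite."""
    return {key: solve_surface_potentials(inp) for key, inp in all_presets.items()}


@pytest.fixture(scope="session")
def symmetric_toy():
    """Source-free configuration: every charge zero, zero transmembrane
    potential, zero mobility.  The flat psi = 0 profile is the solution."""
    c = PhysicalConstants()
    bnd = RegionBoundary(mono_conc_bound=1.54e-4, div_conc_bound=2e-6, psi_bound=0.0)
    return ModelInputs(
        constants=c,
        geometry=RegionGeometry(glycocalyx_width_hg=2.5e-7, bilayer_thickness_hb=7.5e-7),
        dielectrics=RegionDielectrics(81.0, 81.0, 2.0, 81.0),
        ions=IonicBoundary(extracellular=bnd, glycocalyx=bnd,
                           cytoplasm=RegionBoundary(1.54e-4, 4e-7, 0.0)),
        charges=FixedCharges(0.0, 0.0, 0.0, 0.0, 0.0),
        kinetics=ElectrokineticParams(electrophoretic_mobility=0.0, viscosity_eta=1.0),
        state=MembraneState(label="resting", transmembrane_potential=0.0),
        cell_name="toy",
    )


def perturbed_inputs(base: ModelInputs, rng: np.random.Generator) -> ModelInputs:
    """A random physically plausible variation of ``base`` used by the
    randomized solver-agreement and constant-residual properties."""
    ch = base.charges
    ch = replace(
        ch,
        sigma_s2=ch.sigma_s2 * rng.uniform(0.8, 2.0),
        sigma_s3=ch.sigma_s3 * rng.uniform(0.5, 2.0),
        rho_f_glycocalyx=ch.rho_f_glycocalyx * rng.uniform(0.9, 1.6),
        rho_f_cytoplasm=ch.rho_f_cytoplasm * rng.uniform(0.5, 3.0),
    )
    st = replace(base.state,
                 transmembrane_potential=mv_to_statv(rng.uniform(-85.0, 30.0)))
    kin = replace(base.kinetics,
                  electrophoretic_mobility=base.kinetics.electrophoretic_mobility
                  * rng.uniform(0.8, 1.3))
    return replace(base, charges=ch, state=st, kinetics=kin)
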