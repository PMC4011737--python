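# membranepb

Equilibrium electrostatics of a four-region neuronal membrane —
extracellular solution, glycocalyx, lipid bilayer, cytoplasm — with mobile
mono- and divalent electrolyte and protein-fixed charges.  The nonlinear
Poisson–Boltzmann equation is reduced to its first integral per aqueous
region, the three interface potentials (ψ1, ψ2, ψ3) are obtained from the
Helmholtz–Smoluchowski relation and a two-variable nonlinear Gauss-law
system, and the full potential profile ψ(x) is assembled with fixed-step
4th-order Runge–Kutta integration.  Built-in parameter presets describe a
healthy spinal ganglion neuron and a neuroblastoma cell, each in the
resting and action-potential states.

## Layout

| module                | contents |
|-----------------------|----------|
| `units_and_parameters`| CGS/SI conversion, domain types, preset/config loading, input validation |
| `electrolyte_core`    | Boltzmann ion statistics, charge densities, first-integral coefficients, Debye/Gouy–Chapman oracles |
| `region_odes`         | first-integral constants K_j, the regional dψ/dx ODEs, linear bilayer |
| `surface_solver`      | ψ1 from mobility, Gauss jump conditions, scan-and-iterate fixed point for (ψ2, ψ3) plus bracketed fallback |
| `profile_integrator`  | RK4 region integration, profile stitching, validation report, CSV writer |
| `experiments_cli`     | charge-ratio sweeps, per-preset profiles, `membranepb` command line |

Internal computation is in Gaussian CGS (statV, statC, erg); SI is accepted
and emitted only at I/O boundaries.  Presets are plain-text key-value files
under `src/membranepb/presets/` with explicit unit suffixes; values masked
in the available source material are reconstructed on the documented
physical scales and annotated in the files.

## Command line

```sh
# surface potentials for one cell/state (JSON record on stdout)
membranepb solve --cell ganglion --state resting

# full potential profile -> CSV (+ JSON metadata sidecar)
membranepb profile --cell neuroblastoma --state action --out profile.csv

# charge-ratio sensitivity sweep -> CSV
membranepb sweep --quantity rho_fc_ratio --grid 1:10:32 --out sweep.csv

# assemble + validate, machine-readable report
membranepb validate --cell ganglion --state resting
```

`--config FILE` replaces a preset with a user-supplied parameter file in
the same format.  Exit codes: 0 success, 1 solver failure, 2 bad arguments.

## Python API

```python
from membranepb import load_preset, solve_surface_potentials, assemble_profile

inputs = load_preset("ganglion", "resting")
surfaces = solve_surface_potentials(inputs)          # psi1, psi2, psi3 (statV)
profile = assemble_profile(inputs, surfaces)          # sampled psi(x)
```
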