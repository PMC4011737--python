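# Spinal ganglion neuron, resting state.
# Shared rows are transcriptions of the published shared-parameter table
# (Table 1); cell-specific rows follow the cell-specific table (Table 2).
# Rows marked "reconstructed" were masked in the source excerpt and carry
# literature-informed values chosen on the documented physical scale.

cell_name = ganglion
state = resting

# --- fundamental constants (Table 1) ---
temperature = 310 K
boltzmann_k = 1.380649e-16 erg/K
electron_charge = 4.8032047126e-10 statC

# --- geometry (Table 1) ---
glycocalyx_width = 2.5 nm
bilayer_thickness = 7.5 nm

# --- dielectrics (Table 1: bilayer 2, aqueous regions 81) ---
eps_extracellular = 81 1
eps_glycocalyx = 81 1
eps_bilayer = 2 1
eps_cytoplasm = 81 1

# --- ionic boundary concentrations (Table 1) ---
mono_conc_extracellular = 0.154 M
div_conc_extracellular = 0.002 M
mono_conc_s1 = 0.154 M
div_conc_s1 = 0.002 M
mono_conc_cytoplasm = 0.154 M
div_conc_cytoplasm = 0.0004 M

# --- potentials ---
psi_extracellular_bulk = 0 mV     # Table 1
psi_s1 = -9.30 mV                 # Helmholtz-Smoluchowski value (3 s.f.)
transmembrane_potential = -70 mV  # Table 2 resting row; reconstructed

# --- fixed charges (Table 2; reconstructed magnitudes) ---
rho_f_glycocalyx = -3.47e10 statC/cm3   # ~ -0.12 M monovalent-equivalent
rho_f_cytoplasm = -1.67e7 statC/cm3     # ~ -6e-5 M; baseline for ratio sweeps
sigma_s1 = 0 statC/cm2
sigma_s2 = -1000 statC/cm2
sigma_s3 = -80 statC/cm2

# --- electrokinetics (Table 1 viscosity; Table 2 mobility, reconstructed) ---
viscosity = 1 P
electrophoretic_mobility = -2.0e-4 cm2/statV/s
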