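"""Physical constants and frozen biochemical parameter tables.

All temperature-response constants live here so that every run of the model
is reproducible from the source tree alone. Values follow the widely used
Bernacchi-type in-vivo temperature responses for C3 leaves; capacities
(Vcmax, Jmax) use a peaked Arrhenius form.
"""

# universal gas constant, J mol-1 K-1
R_GAS = 8.314

# reference temperature for all 25 degC parameter values, K
T_REF = 298.15

# molar mass of water, g mol-1 (flux -> depth conversions)
MOLAR_MASS_WATER = 18.015

# ratio of stomatal conductance to water vapour vs CO2 (diffusivity ratio)
GSW_OVER_GSC = 1.57

# PAR content of shortwave: ~50% of SW is PAR at ~4.6 umol J-1
PAR_UMOL_PER_J_SW = 2.3

# canopy light extinction coefficient (spherical leaf-angle big leaf)
CANOPY_EXTINCTION = 0.5

# molar heat capacity of dry air, J mol-1 K-1
CP_AIR_MOLAR = 29.2

# latent heat of vaporisation of water, J mol-1
LAMBDA_VAP_MOLAR = 44.0e3

# default atmospheric pressure, kPa
P_ATM_DEFAULT = 101.325

# --- Farquhar biochemistry at 25 degC -------------------------------------
# Michaelis constants and the photorespiratory compensation point, with
# Arrhenius activation energies (J mol-1).
KC25 = 404.9          # umol mol-1
HA_KC = 79430.0
KO25 = 278.4          # mmol mol-1
HA_KO = 36380.0
GAMMA_STAR_25 = 42.75  # umol mol-1
HA_GAMMA_STAR = 37830.0
O2_PARTIAL = 210.0    # mmol mol-1, leaf-interior O2

# day respiration
HA_RD = 46390.0
RD25_FRAC_VCMAX = 0.015   # Rd25 = 0.015 * Vcmax25

# capacities: peaked Arrhenius (Ha, Hd in J mol-1; dS in J mol-1 K-1)
HA_VCMAX = 65330.0
HD_VCMAX = 200000.0
DS_VCMAX = 640.0
HA_JMAX = 43540.0
HD_JMAX = 200000.0
DS_JMAX = 640.0
JMAX25_OVER_VCMAX25 = 1.67

# electron transport: non-rectangular hyperbola of absorbed PAR
J_CURVATURE = 0.7       # theta
J_QUANTUM_YIELD = 0.26  # alpha, mol e- per mol absorbed PAR

# --- hydraulics defaults ---------------------------------------------------
KMAX_DEFAULT = 1.5        # mmol m-2 leaf s-1 MPa-1, cross-species default
KCRIT_FRACTION = 0.05     # hydraulic failure at 5% of k_max
VCMAX25_DEFAULT = 86.88   # umol m-2 s-1, cross-species eucalypt average
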