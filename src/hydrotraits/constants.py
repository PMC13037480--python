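"""Physical constants and default calibration coefficients.

All water potentials are MPa (<= 0), masses g, pressures kPa unless a
name says otherwise.
"""

#: Universal gas constant, J mol-1 K-1 (ideal-gas air-discharge calculation).
R_GAS = 8.314

#: Universal gas constant in MPa kg mol-1 K-1 (van't Hoff osmotic potential).
R_MPA = 8.3145e-3

#: Molar mass of water, g mol-1 (capacitance standardisation).
MW_WATER = 18.01

#: Millimolar mass of water, g mmol-1 (transpiration-rate conversion).
MMW_WATER = 1.8015e-2

#: Default osmometer calibration mapping full-turgor osmotic potential
#: (MPa) to the turgor loss point: psi_tlp = TLP_SLOPE * pi_o + TLP_INTERCEPT.
TLP_SLOPE = 0.832
TLP_INTERCEPT = -0.631

#: FvCB kinetic constants at 25 degC.
GAMMA_STAR_25 = 42.75  # CO2 compensation point without day respiration, umol mol-1
KC_25 = 404.9          # Michaelis constant for CO2, umol mol-1
KO_25 = 278.4          # Michaelis constant for O2, mmol mol-1
O2_MMOL = 210.0        # chloroplast O2 mole fraction, mmol mol-1

#: Standard ambient pressure, kPa.
P_AMBIENT = 101.3

#: Days used to annualise daily growth rates (a 365-day ramp of 10 mm
#: must report a peak rate of exactly 10 mm per year).
DAYS_PER_YEAR = 365.0
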