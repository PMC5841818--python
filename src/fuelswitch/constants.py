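"""Physical constants and tissue parameters shared across modules."""

#: gas constant, kJ/(mol*K)
R_KJ = 8.314462618e-3

#: absolute temperature of the canonical analysis (25 degC), K
T_KELVIN = 298.15

#: RT at 298.15 K, kJ/mol
RT = R_KJ * T_KELVIN

#: reference concentration for mass-action ratios, molar
REFERENCE_CONC = 1.0

#: skeletal-muscle water volume, L per kg wet muscle mass
WATER_VOLUME_L_PER_KG = 0.755

#: fraction of pure fat oxidation RQ used by the fuel-partition formula
RQ_FAT = 0.7
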