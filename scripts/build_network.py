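"""Regenerate the packaged canonical network definition file.

The JSON file under ``src/fuelswitch/data/network.json`` is the source of
truth consumed by :func:`fuelswitch.network.load_network`; this script is the
maintenance tool that wrote it.  It encodes the compartmentalized catabolic
network — glycolysis, the G3P shuttle, pyruvate handling, the TCA cycle,
palmitate activation/transport, the seven-round beta-oxidation spiral,
acyl-carnitine handling, oxidative phosphorylation and the bioenergetic
demand reactions — with standard transformed reaction free energies at
25 degC / pH 7 and literature-scale resting concentration bounds.

Run from the repository root:

    python scripts/build_network.py
"""
from __future__ import annotations

import json
from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "src" / "fuelswitch" / "data" / "network.json"

E = "extracellular"
C = "cytosol"
M = "mitochondrion"

# (id, name, compartment, carbon, default_conc, lb, ub)  [molar]
# carbon counts track catabolic skeleton carbons; carriers carry 0.
SPECIES = [
    # --- extracellular ---
    ("glc_e", "glucose (plasma)", E, 6, 5.0e-3, 3.0e-3, 8.0e-3),
    ("fa_e", "palmitate (plasma, albumin-bound free)", E, 16, 4.0e-4, 1.0e-4, 1.0e-3),
    ("o2_e", "dissolved O2 (capillary)", E, 0, 1.0e-4, 3.0e-5, 2.0e-4),
    ("co2_e", "dissolved CO2 (capillary)", E, 1, 1.2e-3, 5.0e-4, 2.0e-3),
    ("lac_e", "lactate (plasma)", E, 3, 1.0e-3, 3.0e-4, 3.0e-3),
    ("h2o_e", "water (extracellular)", E, 0, 1.0, 1.0, 1.0),
    # --- cytosol: glycolysis ---
    ("glc", "glucose", C, 6, 1.0e-3, 2.0e-4, 5.0e-3),
    ("g6p", "glucose 6-phosphate", C, 6, 4.0e-4, 1.0e-4, 2.0e-3),
    ("f6p", "fructose 6-phosphate", C, 6, 1.2e-4, 3.0e-5, 6.0e-4),
    ("fbp", "fructose 1,6-bisphosphate", C, 6, 8.0e-5, 1.0e-5, 5.0e-4),
    ("dhap", "dihydroxyacetone phosphate", C, 3, 5.0e-5, 1.0e-5, 3.0e-4),
    ("gap", "glyceraldehyde 3-phosphate", C, 3, 5.0e-6, 1.0e-6, 3.0e-5),
    ("bpg13", "1,3-bisphosphoglycerate", C, 3, 6.0e-7, 5.0e-8, 5.0e-6),
    ("pg3", "3-phosphoglycerate", C, 3, 5.0e-5, 1.0e-5, 3.0e-4),
    ("pg2", "2-phosphoglycerate", C, 3, 1.0e-5, 2.0e-6, 6.0e-5),
    ("pep", "phosphoenolpyruvate", C, 3, 2.0e-5, 4.0e-6, 1.0e-4),
    ("pyr", "pyruvate", C, 3, 8.0e-5, 2.0e-5, 5.0e-4),
    ("lac", "lactate", C, 3, 1.2e-3, 3.0e-4, 5.0e-3),
    ("g3p", "glycerol 3-phosphate", C, 3, 1.5e-4, 3.0e-5, 1.0e-3),
    # --- cytosol: cofactors / bioenergetics ---
    ("atp", "ATP", C, 0, 8.0e-3, 3.0e-3, 1.0e-2),
    ("adp", "ADP (free)", C, 0, 4.0e-5, 1.0e-5, 3.0e-4),
    ("amp", "AMP (free)", C, 0, 1.0e-6, 1.0e-7, 1.0e-4),
    ("pi", "inorganic phosphate", C, 0, 3.0e-3, 1.0e-3, 1.0e-2),
    ("ppi", "pyrophosphate", C, 0, 2.0e-6, 2.0e-7, 2.0e-5),
    ("nad", "NAD+ (cytosolic)", C, 0, 5.0e-4, 2.0e-4, 1.0e-3),
    ("nadh", "NADH (cytosolic, free)", C, 0, 6.0e-7, 1.0e-7, 1.0e-5),
    ("cr", "creatine", C, 0, 1.0e-2, 4.0e-3, 2.0e-2),
    ("pcr", "phosphocreatine", C, 0, 2.0e-2, 2.0e-3, 6.0e-2),
    ("coa", "coenzyme A (cytosolic)", C, 0, 1.0e-4, 2.0e-5, 5.0e-4),
    ("h2o", "water (cytosolic)", C, 0, 1.0, 1.0, 1.0),
    # --- cytosol: fatty-acid handling ---
    ("fa", "palmitate (intracellular)", C, 16, 1.0e-4, 2.0e-5, 5.0e-4),
    ("facoa", "palmitoyl-CoA (cytosolic)", C, 16, 4.0e-6, 5.0e-7, 4.0e-5),
    ("carn", "free carnitine (cytosolic)", C, 0, 3.0e-3, 5.0e-4, 8.0e-3),
    ("c16carn", "palmitoyl-carnitine (cytosolic)", C, 16, 2.0e-6, 1.0e-8, 1.0e-4),
    ("c14carn", "C14 acyl-carnitine (cytosolic)", C, 14, 6.0e-7, 1.0e-8, 1.0e-4),
    ("c8carn", "C8 acyl-carnitine (cytosolic)", C, 8, 3.0e-7, 1.0e-8, 1.0e-4),
    ("c4carn", "C4 acyl-carnitine (cytosolic)", C, 4, 4.0e-7, 1.0e-8, 1.0e-4),
    ("acarn", "acetyl-carnitine (cytosolic)", C, 2, 2.0e-4, 2.0e-5, 2.0e-3),
    # --- mitochondrion: core carriers ---
    ("pyr_m", "pyruvate (matrix)", M, 3, 6.0e-5, 1.0e-5, 4.0e-4),
    ("accoa_m", "acetyl-CoA (matrix)", M, 2, 1.0e-4, 2.0e-5, 1.0e-3),
    ("coa_m", "coenzyme A (matrix)", M, 0, 2.0e-3, 5.0e-4, 5.0e-3),
    ("nad_m", "NAD+ (matrix)", M, 0, 2.5e-3, 1.0e-3, 5.0e-3),
    ("nadh_m", "NADH (matrix)", M, 0, 1.0e-4, 2.0e-5, 1.0e-3),
    ("q_m", "ubiquinone", M, 0, 8.0e-4, 2.0e-4, 2.0e-3),
    ("qh2_m", "ubiquinol", M, 0, 2.0e-4, 5.0e-5, 1.0e-3),
    ("fad_m", "FAD (ACAD-bound pool)", M, 0, 1.0e-4, 2.0e-5, 5.0e-4),
    ("fadh2_m", "FADH2 (ACAD-bound pool)", M, 0, 1.0e-5, 1.0e-6, 1.0e-4),
    ("o2_m", "dissolved O2 (matrix)", M, 0, 3.0e-5, 1.0e-5, 1.0e-4),
    ("co2_m", "dissolved CO2 (matrix)", M, 1, 1.4e-3, 5.0e-4, 3.0e-3),
    ("h2o_m", "water (matrix)", M, 0, 1.0, 1.0, 1.0),
    ("atp_m", "ATP (matrix)", M, 0, 4.0e-3, 1.0e-3, 8.0e-3),
    ("adp_m", "ADP (matrix)", M, 0, 2.0e-3, 5.0e-4, 6.0e-3),
    ("pi_m", "inorganic phosphate (matrix)", M, 0, 4.0e-3, 1.0e-3, 1.2e-2),
    ("gtp_m", "GTP (matrix)", M, 0, 5.0e-4, 1.0e-4, 2.0e-3),
    ("gdp_m", "GDP (matrix)", M, 0, 5.0e-4, 1.0e-4, 2.0e-3),
    ("dpsi_m", "protonmotive pseudo-species (charge units)", M, 0, 1.0e3, 1.0, 1.0e4),
    # --- mitochondrion: TCA ---
    ("oaa_m", "oxaloacetate", M, 4, 1.0e-8, 1.0e-9, 1.0e-7),
    ("cit_m", "citrate", M, 6, 3.0e-4, 5.0e-5, 2.0e-3),
    ("icit_m", "isocitrate", M, 6, 3.0e-5, 5.0e-6, 2.0e-4),
    ("akg_m", "2-oxoglutarate", M, 5, 1.0e-4, 2.0e-5, 6.0e-4),
    ("succoa_m", "succinyl-CoA", M, 4, 5.0e-5, 1.0e-5, 5.0e-4),
    ("succ_m", "succinate", M, 4, 5.0e-4, 1.0e-4, 2.0e-3),
    ("fum_m", "fumarate", M, 4, 6.0e-5, 1.0e-5, 4.0e-4),
    ("mal_m", "malate", M, 4, 4.0e-4, 1.0e-4, 2.0e-3),
    # --- mitochondrion: carnitine pools ---
    ("carn_m", "free carnitine (matrix)", M, 0, 2.0e-3, 4.0e-4, 6.0e-3),
    ("c16carn_m", "palmitoyl-carnitine (matrix)", M, 16, 2.0e-6, 1.0e-8, 1.0e-4),
    ("c14carn_m", "C14 acyl-carnitine (matrix)", M, 14, 6.0e-7, 1.0e-8, 1.0e-4),
    ("c8carn_m", "C8 acyl-carnitine (matrix)", M, 8, 3.0e-7, 1.0e-8, 1.0e-4),
    ("c4carn_m", "C4 acyl-carnitine (matrix)", M, 4, 4.0e-7, 1.0e-8, 1.0e-4),
    ("acarn_m", "acetyl-carnitine (matrix)", M, 2, 2.0e-4, 2.0e-5, 2.0e-3),
]

# beta-oxidation spiral intermediates, C16 down to C4
for n in (16, 14, 12, 10, 8, 6, 4):
    SPECIES.extend(
        [
            (f"c{n}coa_m", f"C{n} acyl-CoA (matrix)", M, n, 2.0e-6, 2.0e-7, 2.0e-5),
            (f"c{n}enoyl_m", f"C{n} 2-enoyl-CoA (matrix)", M, n, 4.0e-7, 4.0e-8, 4.0e-6),
            (f"c{n}oh_m", f"C{n} 3-hydroxyacyl-CoA (matrix)", M, n, 4.0e-7, 4.0e-8, 4.0e-6),
            (f"c{n}keto_m", f"C{n} 3-ketoacyl-CoA (matrix)", M, n, 4.0e-8, 4.0e-9, 4.0e-7),
        ]
    )

RT_NOTE = "dG0_prime in kJ/mol at 298.15 K, pH 7"

# (id, name, stoichiometry, dG0_prime, is_boundary, pathway_tag)
REACTIONS = [
    # --- exchange (boundary) fluxes ---
    ("EX_GLC", "glucose supply (hepatic output)", {"glc_e": 1}, -30.0, True, "exchange"),
    ("EX_FA", "fatty-acid supply (adipose lipolysis)", {"fa_e": 1}, -30.0, True, "exchange"),
    ("EX_O2", "O2 uptake (lung/circulation)", {"o2_e": 1}, -30.0, True, "exchange"),
    ("EX_LAC", "lactate disposal (hepatic clearance)", {"lac_e": -1}, -30.0, True, "exchange"),
    ("EX_CO2", "CO2 output (ventilation)", {"co2_e": -1}, -30.0, True, "exchange"),
    ("EX_H2O", "metabolic water disposal", {"h2o_e": -1}, -30.0, True, "exchange"),
    # --- substrate / gas / water transport ---
    ("GLUT", "glucose transporter (GLUT4)", {"glc_e": -1, "glc": 1}, 0.0, False, "glycolysis"),
    ("FAT", "fatty-acid transporter (CD36/FAT)", {"fa_e": -1, "fa": 1}, 0.0, False, "fa_activation_transport"),
    ("LACT", "monocarboxylate lactate transporter", {"lac": -1, "lac_e": 1}, 0.0, False, "lactate"),
    ("O2T", "O2 diffusion (capillary to matrix)", {"o2_e": -1, "o2_m": 1}, 0.0, False, "oxphos"),
    ("CO2T", "CO2 diffusion (matrix to capillary)", {"co2_m": -1, "co2_e": 1}, 0.0, False, "oxphos"),
    # waters are clamped at unit activity, so osmotic disposal needs an
    # explicit (small) driving free energy
    ("H2OTM", "water exchange (matrix to cytosol)", {"h2o_m": -1, "h2o": 1}, -1.0, False, "oxphos"),
    ("H2OT", "water exchange (cytosol to plasma)", {"h2o": -1, "h2o_e": 1}, -1.0, False, "oxphos"),
    # --- glycolysis ---
    ("HK", "hexokinase", {"glc": -1, "atp": -1, "g6p": 1, "adp": 1}, -17.0, False, "glycolysis"),
    ("PGI", "phosphoglucose isomerase", {"g6p": -1, "f6p": 1}, 1.7, False, "glycolysis"),
    ("PFK", "phosphofructokinase", {"f6p": -1, "atp": -1, "fbp": 1, "adp": 1}, -14.2, False, "glycolysis"),
    ("ALD", "aldolase", {"fbp": -1, "dhap": 1, "gap": 1}, 23.8, False, "glycolysis"),
    ("TPI", "triose-phosphate isomerase", {"dhap": -1, "gap": 1}, 7.5, False, "glycolysis"),
    ("GAPDH", "glyceraldehyde-3-phosphate dehydrogenase",
     {"gap": -1, "nad": -1, "pi": -1, "bpg13": 1, "nadh": 1}, 6.3, False, "glycolysis"),
    ("PGK", "phosphoglycerate kinase", {"bpg13": -1, "adp": -1, "pg3": 1, "atp": 1}, -18.8, False, "glycolysis"),
    ("PGM", "phosphoglycerate mutase", {"pg3": -1, "pg2": 1}, 4.4, False, "glycolysis"),
    ("ENO", "enolase", {"pg2": -1, "pep": 1, "h2o": 1}, -3.2, False, "glycolysis"),
    ("PK", "pyruvate kinase", {"pep": -1, "adp": -1, "pyr": 1, "atp": 1}, -31.4, False, "glycolysis"),
    ("LDH", "lactate dehydrogenase", {"pyr": -1, "nadh": -1, "lac": 1, "nad": 1}, -25.1, False, "lactate"),
    # --- glycerol-3-phosphate shuttle ---
    ("GPD1", "cytosolic glycerol-3-phosphate dehydrogenase",
     {"dhap": -1, "nadh": -1, "g3p": 1, "nad": 1}, -25.1, False, "g3p_shuttle"),
    ("GPD2", "mitochondrial glycerol-3-phosphate dehydrogenase",
     {"g3p": -1, "q_m": -1, "dhap": 1, "qh2_m": 1}, -48.2, False, "g3p_shuttle"),
    # --- pyruvate handling ---
    ("MPC", "mitochondrial pyruvate carrier", {"pyr": -1, "pyr_m": 1}, 0.0, False, "pyruvate"),
    ("PDH", "pyruvate dehydrogenase complex",
     {"pyr_m": -1, "coa_m": -1, "nad_m": -1, "accoa_m": 1, "co2_m": 1, "nadh_m": 1}, -33.4, False, "pyruvate"),
    # --- TCA cycle ---
    ("CS", "citrate synthase", {"accoa_m": -1, "oaa_m": -1, "h2o_m": -1, "cit_m": 1, "coa_m": 1}, -31.5, False, "tca"),
    ("ACO", "aconitase", {"cit_m": -1, "icit_m": 1}, 6.3, False, "tca"),
    ("IDH", "isocitrate dehydrogenase (NAD+)",
     {"icit_m": -1, "nad_m": -1, "akg_m": 1, "co2_m": 1, "nadh_m": 1}, -8.4, False, "tca"),
    ("AKGDH", "2-oxoglutarate dehydrogenase complex",
     {"akg_m": -1, "coa_m": -1, "nad_m": -1, "succoa_m": 1, "co2_m": 1, "nadh_m": 1}, -33.5, False, "tca"),
    ("SCS", "succinyl-CoA synthetase (GTP)",
     {"succoa_m": -1, "gdp_m": -1, "pi_m": -1, "succ_m": 1, "gtp_m": 1, "coa_m": 1}, -2.9, False, "tca"),
    ("SDH", "succinate dehydrogenase", {"succ_m": -1, "q_m": -1, "fum_m": 1, "qh2_m": 1}, -5.8, False, "tca"),
    ("FUM", "fumarase", {"fum_m": -1, "h2o_m": -1, "mal_m": 1}, -3.8, False, "tca"),
    ("MDH", "malate dehydrogenase", {"mal_m": -1, "nad_m": -1, "oaa_m": 1, "nadh_m": 1}, 29.7, False, "tca"),
    # --- fatty-acid activation and carnitine shuttle ---
    ("FACS", "fatty acyl-CoA synthetase",
     {"fa": -1, "coa": -1, "atp": -1, "facoa": 1, "amp": 1, "ppi": 1}, -1.0, False, "fa_activation_transport"),
    ("CPT1", "carnitine palmitoyltransferase 1",
     {"facoa": -1, "carn": -1, "c16carn": 1, "coa": 1}, 0.0, False, "fa_activation_transport"),
    ("PCT", "carnitine/acyl-carnitine translocase (C16)",
     {"c16carn": -1, "carn_m": -1, "c16carn_m": 1, "carn": 1}, 0.0, False, "fa_activation_transport"),
    ("CPT2", "carnitine palmitoyltransferase 2",
     {"c16carn_m": -1, "coa_m": -1, "c16coa_m": 1, "carn_m": 1}, 0.0, False, "fa_activation_transport"),
    # --- carnitine pool handling ---
    ("CRAT", "carnitine acetyltransferase (matrix)",
     {"accoa_m": -1, "carn_m": -1, "acarn_m": 1, "coa_m": 1}, 0.0, False, "carnitine_handling"),
    ("ACT_C14", "carnitine acyltransferase (C14, matrix)",
     {"c14coa_m": -1, "carn_m": -1, "c14carn_m": 1, "coa_m": 1}, 0.0, False, "carnitine_handling"),
    ("ACT_C8", "carnitine octanoyltransferase (matrix)",
     {"c8coa_m": -1, "carn_m": -1, "c8carn_m": 1, "coa_m": 1}, 0.0, False, "carnitine_handling"),
    ("ACT_C4", "carnitine butyryltransferase (matrix)",
     {"c4coa_m": -1, "carn_m": -1, "c4carn_m": 1, "coa_m": 1}, 0.0, False, "carnitine_handling"),
    ("CACT_AC", "acetyl-carnitine translocase",
     {"acarn_m": -1, "carn": -1, "acarn": 1, "carn_m": 1}, 0.0, False, "carnitine_handling"),
    ("CACT_C14", "acyl-carnitine translocase (C14)",
     {"c14carn_m": -1, "carn": -1, "c14carn": 1, "carn_m": 1}, 0.0, False, "carnitine_handling"),
    ("CACT_C8", "acyl-carnitine translocase (C8)",
     {"c8carn_m": -1, "carn": -1, "c8carn": 1, "carn_m": 1}, 0.0, False, "carnitine_handling"),
    ("CACT_C4", "acyl-carnitine translocase (C4)",
     {"c4carn_m": -1, "carn": -1, "c4carn": 1, "carn_m": 1}, 0.0, False, "carnitine_handling"),
    # --- oxidative phosphorylation ---
    ("C1", "Complex 1 (NADH:Q oxidoreductase, 4 charges/2e-)",
     {"nadh_m": -1, "q_m": -1, "nad_m": 1, "qh2_m": 1, "dpsi_m": 4}, -73.3, False, "oxphos"),
    ("C34", "Complex 3+4 (QH2:O2 oxidoreductase, 6 charges/QH2)",
     {"qh2_m": -2, "o2_m": -1, "q_m": 2, "h2o_m": 2, "dpsi_m": 12}, -293.3, False, "oxphos"),
    ("ATPS", "ATP synthase (3 charges/ATP)",
     {"adp_m": -1, "pi_m": -1, "dpsi_m": -3, "atp_m": 1, "h2o_m": 1}, 31.0, False, "oxphos"),
    ("ANT", "adenine nucleotide translocator",
     {"atp_m": -1, "adp": -1, "dpsi_m": -1, "atp": 1, "adp_m": 1}, 0.0, False, "oxphos"),
    ("PIC", "phosphate carrier", {"pi": -1, "dpsi_m": -1, "pi_m": 1}, 0.0, False, "oxphos"),
    # --- bioenergetic demand and buffering ---
    ("ATPASE", "ATP hydrolysis (work demand)", {"atp": -1, "h2o": -1, "adp": 1, "pi": 1}, -31.0, False, "bioenergetics"),
    ("CK", "creatine kinase", {"pcr": -1, "adp": -1, "cr": 1, "atp": 1}, -12.5, False, "bioenergetics"),
    ("AK", "adenylate kinase", {"amp": -1, "atp": -1, "adp": 2}, 0.0, False, "bioenergetics"),
    ("NDK", "nucleoside diphosphate kinase (matrix)",
     {"gtp_m": -1, "adp_m": -1, "gdp_m": 1, "atp_m": 1}, 0.0, False, "bioenergetics"),
    ("PPIASE", "inorganic pyrophosphatase", {"ppi": -1, "h2o": -1, "pi": 2}, -19.2, False, "bioenergetics"),
]

ACAD_NAMES = {16: "VLCAD", 14: "LCAD", 12: "LCAD", 10: "MCAD", 8: "MCAD", 6: "MCAD", 4: "SCAD"}

# beta-oxidation spiral: 7 rounds x 4 steps + shared ETF:Q oxidoreductase
for n in (16, 14, 12, 10, 8, 6, 4):
    REACTIONS.append(
        (f"ACAD_C{n}", f"acyl-CoA dehydrogenase ({ACAD_NAMES[n]}, C{n})",
         {f"c{n}coa_m": -1, "fad_m": -1, f"c{n}enoyl_m": 1, "fadh2_m": 1}, -5.0, False, "beta_oxidation")
    )
    REACTIONS.append(
        (f"ECH_C{n}", f"enoyl-CoA hydratase (C{n})",
         {f"c{n}enoyl_m": -1, "h2o_m": -1, f"c{n}oh_m": 1}, -3.0, False, "beta_oxidation")
    )
    REACTIONS.append(
        (f"HACD_C{n}", f"3-hydroxyacyl-CoA dehydrogenase (C{n})",
         {f"c{n}oh_m": -1, "nad_m": -1, f"c{n}keto_m": 1, "nadh_m": 1}, 15.5, False, "beta_oxidation")
    )
    if n > 4:
        kat = {f"c{n}keto_m": -1, "coa_m": -1, f"c{n - 2}coa_m": 1, "accoa_m": 1}
    else:
        kat = {"c4keto_m": -1, "coa_m": -1, "accoa_m": 2}
    REACTIONS.append(
        (f"KAT_C{n}", f"3-ketoacyl-CoA thiolase (C{n})", kat, -25.0, False, "beta_oxidation")
    )
REACTIONS.append(
    ("ETF", "ETF:Q oxidoreductase", {"fadh2_m": -1, "q_m": -1, "fad_m": 1, "qh2_m": 1}, -15.4, False, "beta_oxidation")
)


def build() -> dict:
    doc = {
        "name": "whole-body glucose/palmitate catabolism",
        "note": RT_NOTE,
        "compartments": [
            {"id": "extracellular", "volume_fraction": 0.2},
            {"id": "cytosol", "volume_fraction": 0.75},
            {"id": "mitochondrion", "volume_fraction": 0.05},
        ],
        "species": [
            {
                "id": sid, "name": name, "compartment": comp, "carbon_count": carbon,
                "conc_default": conc, "conc_lower": lb, "conc_upper": ub,
            }
            for sid, name, comp, carbon, conc, lb, ub in SPECIES
        ],
        "reactions": [
            {
                "id": rid, "name": name, "stoichiometry": stoich, "dG0_prime": dg0,
                "is_boundary": boundary, "pathway_tag": tag,
            }
            for rid, name, stoich, dg0, boundary, tag in REACTIONS
        ],
    }
    return doc


def main() -> None:
    doc = build()
    assert len(doc["species"]) == 98, len(doc["species"])
    assert len(doc["reactions"]) == 87, len(doc["reactions"])
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(doc, indent=1) + "\n")
    print(f"wrote {OUT} ({len(doc['species'])} species, {len(doc['reactions'])} reactions)")


if __name__ == "__main__":
    main()
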