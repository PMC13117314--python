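"""Reference constants from the southeast-China crustacean OPE survey.

These are the published summary values of the underlying market-basket
surveillance study (freshwater shrimp n=239, marine crab n=84, marine
prawn n=210, sampled 2024-2025): the 22-congener catalog with chemical
classes, per-congener wet-weight concentration summaries, species-level
totals, the reference doses used for non-carcinogenic risk, the
age-group exposure parameters, and the published probabilistic-risk
medians. They serve as generator calibration targets and as the fixture
substrate for the deterministic risk arithmetic.

All concentrations are in ug/kg wet weight; RfD and EDI in ug/kg bw/day.
"""

from __future__ import annotations

# (full name, class) per congener, in catalog (table) order.
# Classes: chlorinated (6), alkyl (11), aryl (4), brominated (1).
CONGENERS: dict[str, tuple[str, str]] = {
    "BDCiPP": ("bis(1,3-dichloro-2-propyl) phosphate", "chlorinated"),
    "BBOEP": ("bis(2-butoxyethyl) phosphate", "alkyl"),
    "DoCP": ("di-o-cresyl phosphate", "alkyl"),
    "BCiPP": ("bis(chloroisopropyl) phosphate", "chlorinated"),
    "DPhP": ("diphenyl phosphate", "aryl"),
    "DnBP": ("di-n-butyl phosphate", "alkyl"),
    "TMPP": ("tricresyl phosphate", "aryl"),
    "TiBP": ("triisobutyl phosphate", "alkyl"),
    "TiPP": ("triisopropyl phosphate", "alkyl"),
    "TEP": ("triethyl phosphate", "alkyl"),
    "V6": ("tetrakis(2-chloroethyl) dichloroisopentyl diphosphate", "chlorinated"),
    "TEHP": ("tris(2-ethylhexyl) phosphate", "alkyl"),
    "EHDPP": ("2-ethylhexyl diphenyl phosphate", "aryl"),
    "TBOEP": ("tris(2-butoxyethyl) phosphate", "alkyl"),
    "TDBPP": ("tris(2,3-dibromopropyl) phosphate", "brominated"),
    "TMP": ("trimethyl phosphate", "alkyl"),
    "TPhP": ("triphenyl phosphate", "aryl"),
    "TCiPP": ("tris(chloropropyl) phosphate", "chlorinated"),
    "TnPP": ("tri-n-propyl phosphate", "alkyl"),
    "TCEP": ("tris(2-chloroethyl) phosphate", "chlorinated"),
    "TDCiPP": ("tris(1,3-dichloro-2-propyl) phosphate", "chlorinated"),
    "TnBP": ("tri-n-butyl phosphate", "alkyl"),
}

# Published all-sample mean and maximum concentration per congener
# (minimum and median are 0 for every congener: heavy left-censoring).
CONGENER_MEANS: dict[str, float] = {
    "BDCiPP": 0.015, "BBOEP": 0.013, "DoCP": 0.000, "BCiPP": 0.036,
    "DPhP": 0.111, "DnBP": 0.001, "TMPP": 0.007, "TiBP": 1.561,
    "TiPP": 0.000, "TEP": 1.089, "V6": 0.012, "TEHP": 0.375,
    "EHDPP": 0.129, "TBOEP": 0.054, "TDBPP": 0.000, "TMP": 0.088,
    "TPhP": 0.087, "TCiPP": 0.773, "TnPP": 0.005, "TCEP": 1.302,
    "TDCiPP": 0.129, "TnBP": 0.020,
}

CONGENER_MAXIMA: dict[str, float] = {
    "BDCiPP": 0.804, "BBOEP": 0.524, "DoCP": 0.0, "BCiPP": 0.477,
    "DPhP": 1.48, "DnBP": 0.067, "TMPP": 0.627, "TiBP": 48.2,
    "TiPP": 0.0, "TEP": 23.6, "V6": 0.476, "TEHP": 23.0,
    "EHDPP": 4.29, "TBOEP": 2.84, "TDBPP": 0.0, "TMP": 7.42,
    "TPhP": 1.39, "TCiPP": 15.8, "TnPP": 0.170, "TCEP": 61.2,
    "TDCiPP": 7.39, "TnBP": 0.814,
}

# Oral reference doses (US EPA derived), ug/kg bw/day; only 10 of the 22
# congeners have a published RfD and enter THQ/HI.
RFD: dict[str, float] = {
    "TMPP": 13.0, "TEP": 125.0, "TEHP": 35.0, "TBOEP": 15.0, "TMP": 10.0,
    "TPhP": 70.0, "TCiPP": 80.0, "TCEP": 22.0, "TDCiPP": 15.0, "TnBP": 24.0,
}

# Method LODs, ug/kg ww. The survey reports the range 0.2-0.9 with the
# lowest (0.21) for TMPP; the per-congener values are not published, so
# the catalog defaults to the midpoint 0.5 except TMPP.
DEFAULT_LOD: float = 0.5
LOD: dict[str, float] = {abbrev: DEFAULT_LOD for abbrev in CONGENERS}
LOD["TMPP"] = 0.21

# Species-level sample sizes and Sigma-OPEs (per-sample total) summaries.
SPECIES_SUMMARY: dict[str, dict[str, float]] = {
    "freshwater_shrimp": {"n": 239, "mean": 5.80, "minimum": 0.0, "median": 1.35, "maximum": 62.85},
    "marine_crab": {"n": 84, "mean": 1.25, "minimum": 0.0, "median": 0.00, "maximum": 6.41},
    "marine_prawn": {"n": 210, "mean": 6.52, "minimum": 0.0, "median": 2.20, "maximum": 56.13},
}
OVERALL_SUMMARY: dict[str, float] = {"mean": 5.74, "minimum": 0.0, "median": 1.49, "maximum": 62.85}

# Published species-specific detection frequencies (proportions).
DETECTION_RATES: dict[tuple[str, str], float] = {
    ("freshwater_shrimp", "TEP"): 0.5312,
    ("marine_prawn", "TEP"): 0.439,
    ("marine_crab", "TEP"): 0.1429,
    ("marine_prawn", "TBOEP"): 0.125,
}

# Regional Sigma-OPEs means (ug/kg ww) for the production areas with a
# published value; used for "survey-calibrated" region multipliers.
REGIONAL_MEANS: dict[str, float] = {
    "Zhoushan": 15.3, "Taizhou": 12.7, "Ningbo": 8.9, "Wenzhou": 7.8,
    "Quzhou": 1.2, "Lishui": 1.5,
}

# Age-group exposure parameters: daily crustacean intake (g/day) and
# body weight (kg) for the general southeast-China population.
EXPOSURE_GROUPS: dict[str, tuple[float, float]] = {
    "children": (11.85, 16.68),
    "teens": (24.23, 46.25),
    "adults": (33.32, 57.03),
}

# Published probabilistic risk table: per congener, the RfD and the
# Monte Carlo *median* EDI and THQ for each age group. These medians are
# inputs for internal-consistency arithmetic (THQ = EDI / RfD), not
# outputs this package claims to re-derive distributionally.
RISK_TABLE_MEDIANS: dict[str, dict[str, object]] = {
    "TMPP":   {"rfd": 13.0,  "children": (0.004, 0.00026), "teens": (0.003, 0.00021), "adults": (0.003, 0.00023)},
    "TEP":    {"rfd": 125.0, "children": (0.581, 0.00465), "teens": (0.449, 0.00359), "adults": (0.495, 0.00396)},
    "TEHP":   {"rfd": 35.0,  "children": (0.256, 0.00732), "teens": (0.188, 0.00537), "adults": (0.211, 0.00602)},
    "TBOEP":  {"rfd": 15.0,  "children": (0.03, 0.00203),  "teens": (0.023, 0.00154), "adults": (0.025, 0.00168)},
    "TMP":    {"rfd": 10.0,  "children": (0.05, 0.00508),  "teens": (0.039, 0.00386), "adults": (0.043, 0.00435)},
    "TPhP":   {"rfd": 70.0,  "children": (0.046, 0.00066), "teens": (0.035, 0.0005),  "adults": (0.040, 0.00058)},
    "TCiPP":  {"rfd": 80.0,  "children": (0.388, 0.00485), "teens": (0.298, 0.00372), "adults": (0.336, 0.0042)},
    "TCEP":   {"rfd": 22.0,  "children": (0.675, 0.03067), "teens": (0.523, 0.02378), "adults": (0.572, 0.026)},
    "TDCiPP": {"rfd": 15.0,  "children": (0.065, 0.00432), "teens": (0.051, 0.00338), "adults": (0.057, 0.00378)},
    "TnBP":   {"rfd": 24.0,  "children": (0.012, 0.0005),  "teens": (0.009, 0.00037), "adults": (0.01, 0.00042)},
}
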