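"""Controlled vocabulary and default parameter tables.

Everything in this module is a *default*: the derivative carbon-count table,
amino-acid composition tables, macronutrient compositions/offsets and charring
offsets are all overridable through run configuration.  Isotope source
templates used by :mod:`isodiet.synthetic_data` are explicitly synthetic —
they emulate the statistical structure of first-century Mediterranean
baselines (C3 cereals, terrestrial fauna, marine fish) without reproducing
any measured dataset.
"""

from __future__ import annotations

# Amino acids after acid hydrolysis of collagen/plant protein.  Asn/Asp and
# Gln/Glu are indistinguishable post-hydrolysis and appear only as Asx/Glx.
AA_VOCAB = (
    "Ala", "Gly", "Val", "Leu", "Ile", "Thr", "Ser", "Pro",
    "Asx", "Glx", "Phe", "Lys", "Tyr", "Hyp", "Met", "Nle",
)

#: analyte value used for bulk (whole-collagen / whole-grain) measurements
BULK = "bulk"

ELEMENTS = ("C", "N")
SEXES = ("male", "female", "unknown")

#: reference scale per element: delta values are ‰ vs these standards
REFERENCE_SCALE = {"C": "VPDB", "N": "AIR"}

#: Asn/Asp, Gln/Glu collapse applied at ingest (acid hydrolysis chemistry)
AA_ALIASES = {"Asp": "Asx", "Asn": "Asx", "Glu": "Glx", "Gln": "Glx"}

# ---------------------------------------------------------------------------
# Derivatization (N-acetyl-isopropyl esters)
# ---------------------------------------------------------------------------

#: carbon atoms in the underivatized amino acid
AA_CARBONS = {
    "Ala": 3, "Gly": 2, "Val": 5, "Leu": 6, "Ile": 6, "Thr": 4,
    "Ser": 3, "Pro": 5, "Asx": 4, "Glx": 5, "Phe": 9, "Lys": 6,
    "Tyr": 9, "Hyp": 5, "Met": 5, "Nle": 6,
}

# NAIP derivatization adds 2 C per acetylated amine/hydroxyl and 3 C per
# esterified carboxyl: 5 for mono-amino mono-carboxylic AAs, 8 for the two
# carboxyls of Asx/Glx, 7 for the two acetylation sites of Lys/Tyr.
NAIP_DERIVATIVE_CARBONS = {
    "Ala": 5, "Gly": 5, "Val": 5, "Leu": 5, "Ile": 5, "Thr": 5,
    "Ser": 5, "Pro": 5, "Asx": 8, "Glx": 8, "Phe": 5, "Lys": 7,
    "Tyr": 7, "Hyp": 5, "Met": 5, "Nle": 5,
}

# ---------------------------------------------------------------------------
# Amino-acid composition of source proteins (g AA / g protein).
# Collagen table: mammalian type-I collagen; fish: white-muscle protein;
# cereal: wheat/barley grain storage protein.  Only the AAs carrying model
# signals need to be accurate; tables are config-overridable.
# ---------------------------------------------------------------------------

AA_COMPOSITION_COLLAGEN = {
    "Gly": 0.331, "Pro": 0.122, "Hyp": 0.099, "Ala": 0.114,
    "Glx": 0.075, "Asx": 0.047, "Ser": 0.035, "Lys": 0.027,
    "Leu": 0.026, "Val": 0.022, "Thr": 0.018, "Phe": 0.013,
    "Ile": 0.011, "Met": 0.006, "Tyr": 0.004,
}

# terrestrial animal *foods* (muscle meat, eggs, dairy) — what consumers eat;
# the collagen table above describes the measured baseline tissue instead and
# would dilute every source-AA signal of this food group by 3-6x
AA_COMPOSITION_MEAT = {
    "Gly": 0.047, "Pro": 0.040, "Ala": 0.060, "Glx": 0.150,
    "Asx": 0.092, "Ser": 0.040, "Lys": 0.087, "Leu": 0.081,
    "Val": 0.050, "Thr": 0.044, "Phe": 0.040, "Ile": 0.046,
    "Met": 0.026, "Tyr": 0.035,
}

AA_COMPOSITION_FISH_MUSCLE = {
    "Gly": 0.047, "Pro": 0.035, "Ala": 0.060, "Glx": 0.149,
    "Asx": 0.102, "Ser": 0.045, "Lys": 0.092, "Leu": 0.081,
    "Val": 0.051, "Thr": 0.044, "Phe": 0.039, "Ile": 0.046,
    "Met": 0.029, "Tyr": 0.034,
}

AA_COMPOSITION_CEREAL_GRAIN = {
    "Gly": 0.040, "Pro": 0.105, "Ala": 0.037, "Glx": 0.250,
    "Asx": 0.052, "Ser": 0.047, "Lys": 0.028, "Leu": 0.068,
    "Val": 0.046, "Thr": 0.032, "Phe": 0.047, "Ile": 0.036,
    "Met": 0.016, "Tyr": 0.028,
}

# ---------------------------------------------------------------------------
# Macronutrient composition of sources (dry-weight fractions, sum to 1)
# and δ13C offsets of each macronutrient from the *measured* bulk value
# (faunal collagen for animal sources, whole grain for cereals), mean ± sd ‰.
# ---------------------------------------------------------------------------

MACRONUTRIENTS = {
    "cereals": {"protein": 0.12, "carbohydrate": 0.85, "lipid": 0.03},
    "terrestrial_animals": {"protein": 0.60, "carbohydrate": 0.00, "lipid": 0.40},
    "marine_fish": {"protein": 0.75, "carbohydrate": 0.00, "lipid": 0.25},
    "olive_oil": {"protein": 0.00, "carbohydrate": 0.00, "lipid": 1.00},
}

MACRONUTRIENT_D13C_OFFSETS = {
    # animal sources are measured on collagen: tissue protein ≈ collagen −2‰,
    # lipids strongly depleted
    "terrestrial_animals": {"protein": (-2.0, 0.5), "carbohydrate": (-2.0, 1.0),
                            "lipid": (-8.0, 1.0)},
    "marine_fish": {"protein": (-2.0, 0.5), "carbohydrate": (-2.0, 1.0),
                    "lipid": (-7.0, 1.0)},
    # cereals are measured on whole grain (carbohydrate-dominated bulk)
    "cereals": {"protein": (0.4, 0.5), "carbohydrate": (0.5, 0.5),
                "lipid": (-3.5, 1.0)},
    "olive_oil": {"protein": (0.0, 0.0), "carbohydrate": (0.0, 0.0),
                  "lipid": (0.0, 0.3)},
}

# ---------------------------------------------------------------------------
# Diet-to-consumer offsets (‰, mean ± sd) per routing class
# ---------------------------------------------------------------------------

ROUTING_OFFSETS = {
    # source AAs: negligible fractionation, modelled as 0 with a conservative sd
    "source_direct": (0.0, 0.5),
    # consumer Ala δ13C vs dietary carbohydrate carbon
    "glycolytic": (0.0, 1.5),
    # consumer Glx/Asx δ13C vs the total dietary carbon pool
    "carbon_pool": (2.0, 1.5),
    # consumer Glx δ15N vs bulk δ15N of dietary protein (transamination pool)
    "nitrogen_pool": (8.0, 1.0),
    # bulk collagen vs dietary protein (protein-routed bulk model)
    "bulk_protein": {"C": (4.8, 0.5), "N": (5.5, 0.5)},
    # bulk collagen vs whole-diet macronutrient mixture (scrambled bulk model)
    "bulk_scrambled": {"C": (4.8, 1.0), "N": (5.5, 0.5)},
}

#: charring correction applied to archaeological grain bulk values,
#: mean ± sd ‰ added by charring (subtracted during correction)
CHARRING_OFFSETS = {"C": (0.11, 0.10), "N": (0.31, 0.30)}

#: modern Mediterranean olive-oil δ13C and the Suess-effect correction used
#: when extending the whole-diet model with a lipid-only oil source (‰)
OLIVE_OIL_D13C = (-29.0, 0.8)
SUESS_CORRECTION = (1.9, 0.3)
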