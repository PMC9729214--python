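"""Trait codes, standard units, controlled vocabularies, and default mapping tables.

The pipeline curates six core quantitative traits of vascular plants plus the
auxiliary traits used only to fill gaps in them.  Every trait has one fixed
standard unit; all values flowing past the harmonization stage are expressed
in that unit.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Trait codes and standard units
# ---------------------------------------------------------------------------

#: Core traits reported in the species-mean table.
CORE_TRAITS = ("H", "SSD", "LA", "LMA", "Nmass", "SM")

#: Auxiliary traits carried through curation: LDMC feeds the SSD imputation,
#: SLA/Narea/SPORE_RADIUS/StDMC exist only as imputation sources.
AUX_TRAITS = ("LDMC", "SLA", "Narea", "SPORE_RADIUS", "StDMC")

ALL_TRAITS = CORE_TRAITS + AUX_TRAITS

#: Standard unit per trait code.
STANDARD_UNITS = {
    "H": "m",            # adult plant height
    "SSD": "mg/mm3",     # stem specific density
    "LA": "mm2",         # leaf lamina area
    "LMA": "g/m2",       # leaf mass per area
    "Nmass": "mg/g",     # leaf nitrogen per dry mass
    "SM": "mg",          # diaspore (seed or spore) mass
    "LDMC": "g/g",       # leaf dry matter content
    "SLA": "m2/g",       # specific leaf area (reciprocal of LMA)
    "Narea": "g/m2",     # leaf nitrogen per area
    "SPORE_RADIUS": "mm",
    "StDMC": "g/g",      # stem dry matter content
}

#: Leaf-level traits: the shade-grown-leaf exclusion applies to these only.
LEAF_TRAITS = frozenset({"LA", "LMA", "Nmass", "SLA", "Narea", "LDMC"})

# ---------------------------------------------------------------------------
# Unit conversion table: (trait_code, unit string) -> factor to standard unit
# ---------------------------------------------------------------------------

UNIT_FACTORS = {
    ("H", "m"): 1.0,
    ("H", "cm"): 0.01,
    ("H", "mm"): 0.001,
    ("H", "dm"): 0.1,
    ("SSD", "mg/mm3"): 1.0,
    ("SSD", "g/cm3"): 1.0,          # numerically identical densities
    ("SSD", "kg/m3"): 0.001,
    ("LA", "mm2"): 1.0,
    ("LA", "cm2"): 100.0,
    ("LA", "m2"): 1.0e6,
    ("LMA", "g/m2"): 1.0,
    ("LMA", "mg/mm2"): 1000.0,
    ("LMA", "kg/m2"): 1000.0,
    ("LMA", "mg/cm2"): 10.0,
    ("Nmass", "mg/g"): 1.0,
    ("Nmass", "%"): 10.0,           # 1% of dry mass = 10 mg/g
    ("Nmass", "g/g"): 1000.0,
    ("Nmass", "g/kg"): 1.0,
    ("SM", "mg"): 1.0,
    ("SM", "g"): 1000.0,
    ("SM", "ug"): 0.001,
    ("LDMC", "g/g"): 1.0,
    ("LDMC", "mg/g"): 0.001,
    ("LDMC", "%"): 0.01,
    ("SLA", "m2/g"): 1.0,
    ("SLA", "cm2/g"): 1.0e-4,
    ("SLA", "mm2/mg"): 1.0e-3,
    ("SLA", "m2/kg"): 1.0e-3,
    ("Narea", "g/m2"): 1.0,
    ("Narea", "mg/mm2"): 1000.0,
    ("SPORE_RADIUS", "mm"): 1.0,
    ("SPORE_RADIUS", "um"): 1.0e-3,
    ("StDMC", "g/g"): 1.0,
    ("StDMC", "mg/g"): 0.001,
}

# ---------------------------------------------------------------------------
# Trait term dialects: free-text term -> trait code
# ---------------------------------------------------------------------------

DEFAULT_TERM_MAP = {
    "H": "H", "height": "H", "plant height": "H", "vegetative plant height": "H",
    "maximum plant height": "H", "canopy height": "H",
    "SSD": "SSD", "stem specific density": "SSD", "wood density": "SSD",
    "stem density": "SSD", "stem dry mass per stem fresh volume": "SSD",
    "LA": "LA", "leaf area": "LA", "leaf lamina area": "LA",
    "leaf size": "LA", "lamina area": "LA",
    "LMA": "LMA", "leaf mass per area": "LMA",
    "leaf dry mass per area": "LMA", "leaf mass area": "LMA",
    "Nmass": "Nmass", "leaf nitrogen": "Nmass",
    "leaf nitrogen per mass": "Nmass", "leaf n": "Nmass",
    "leaf nitrogen content": "Nmass", "leaf n concentration": "Nmass",
    "SM": "SM", "seed mass": "SM", "seed weight": "SM",
    "diaspore mass": "SM", "seed dry mass": "SM",
    "LDMC": "LDMC", "leaf dry matter content": "LDMC",
    "SLA": "SLA", "specific leaf area": "SLA",
    "Narea": "Narea", "leaf nitrogen per area": "Narea",
    "leaf n per area": "Narea",
    "SPORE_RADIUS": "SPORE_RADIUS", "spore radius": "SPORE_RADIUS",
    "StDMC": "StDMC", "stem dry matter content": "StDMC",
}

# ---------------------------------------------------------------------------
# Metadata vocabularies (controlled values after harmonization)
# ---------------------------------------------------------------------------

MATURITY_VALUES = ("mature", "juvenile", "unknown")
HEALTH_VALUES = ("healthy", "not_healthy", "unknown")
GROWTH_CONDITION_VALUES = ("natural", "experimental", "unknown")
EXPOSURE_VALUES = ("sun", "shade", "unknown")

#: Free-text metadata synonyms -> controlled value, per metadata axis.
DEFAULT_METADATA_MAP = {
    "maturity": {
        "mature": "mature", "adult": "mature",
        "juvenile": "juvenile", "sapling": "juvenile", "seedling": "juvenile",
        "unknown": "unknown", "": "unknown",
    },
    "health": {
        "healthy": "healthy", "ok": "healthy",
        "not_healthy": "not_healthy", "unhealthy": "not_healthy",
        "damaged": "not_healthy", "diseased": "not_healthy",
        "unknown": "unknown", "": "unknown",
    },
    "growth_condition": {
        "natural": "natural", "field": "natural", "wild": "natural",
        "experimental": "experimental", "greenhouse": "experimental",
        "growth chamber": "experimental", "laboratory": "experimental",
        "unknown": "unknown", "": "unknown",
    },
    "exposure": {
        "sun": "sun", "full sun": "sun", "light exposed": "sun",
        "shade": "shade", "shaded": "shade", "understory": "shade",
        "unknown": "unknown", "": "unknown",
    },
}

# ---------------------------------------------------------------------------
# Higher-rank taxonomic groups and categorical-trait vocabularies
# ---------------------------------------------------------------------------

GROUPS = (
    "angiosperm_monocot",
    "angiosperm_eudicot_fabaceae",
    "angiosperm_other",
    "gymnosperm",
    "pteridophyte",
    "other",
)

CATEGORICAL_VOCABULARIES = {
    "woodiness": ("woody", "non-woody", "semi-woody"),
    "growth_form": (
        "bamboo graminoid", "climber", "fern", "herbaceous graminoid",
        "herbaceous non-graminoid", "herbaceous non-graminoid/shrub",
        "succulent", "shrub", "shrub/tree", "tree", "other",
    ),
    "succulence": (
        "leaf and stem succulent", "leaf rosette and stem succulent",
        "leaf rosette succulent", "leaf succulent", "stem succulent",
        "not succulent",
    ),
    "habitat_adaptation": (
        "aquatic", "aquatic/semiaquatic", "semiaquatic", "terrestrial",
    ),
    "nutrition_type": (
        "independent", "hemiparasitic", "holoparasitic", "parasitic",
        "carnivorous", "detritivorous",
    ),
    "leaf_type": (
        "broadleaved", "needleleaved", "scale-shaped",
        "scale-shaped/needleleaved", "photosynthetic stem",
    ),
}

CATEGORICAL_TRAITS = tuple(CATEGORICAL_VOCABULARIES)
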