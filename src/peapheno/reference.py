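"""Reference trait vocabulary and published condition means.

The 19-trait vocabulary combines 11 image-based traits (side-view RGB,
top-view spectral and chlorophyll-fluorescence imaging) with 8 manually
measured traits. Each trait belongs to one of three functional groups:
biomass-related, architectural, or physiological.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: All 19 traits in canonical order (image-based first, then manual).
TRAITS = [
    "DB", "CH", "SOL", "NPCI", "GLI", "NDVI", "PSRI", "TA", "SA", "PhE", "WUE",
    "FW", "DW", "PH", "TLA", "SLA", "LWR", "LAR", "RWC",
]

#: Functional group of each trait, used for correlation-network node colors.
TRAIT_CATEGORIES = {
    "FW": "biomass", "DW": "biomass", "DB": "biomass", "SA": "biomass",
    "TA": "biomass", "RWC": "biomass", "LWR": "biomass",
    "CH": "architectural", "SOL": "architectural", "PH": "architectural",
    "SLA": "architectural", "LAR": "architectural", "TLA": "architectural",
    "PhE": "physiological", "WUE": "physiological", "NDVI": "physiological",
    "NPCI": "physiological", "PSRI": "physiological", "GLI": "physiological",
}

#: Human-readable trait names.
TRAIT_NAMES = {
    "DB": "Digital biomass",
    "CH": "Convex hull area",
    "SOL": "Solidity",
    "NPCI": "Normalized pigment chlorophyll ratio index",
    "GLI": "Green leaf index",
    "NDVI": "Normalized difference vegetation index",
    "PSRI": "Plant senescence reflectance index",
    "TA": "Top area",
    "SA": "Side area",
    "PhE": "PSII photochemical efficiency",
    "WUE": "Water use efficiency",
    "FW": "Fresh weight",
    "DW": "Dry weight",
    "PH": "Plant height",
    "TLA": "Total leaf area",
    "SLA": "Specific leaf area",
    "LWR": "Leaf weight ratio",
    "LAR": "Leaf area ratio",
    "RWC": "Relative water content",
}

#: Accessions per species / subspecies group in the 180-accession panel.
SPECIES_GROUPS = {
    "P. fulvum": 6,
    "P. abyssinicum": 2,
    "P. sativum subsp. jomardii": 56,
    "P. sativum subsp. arvense": 47,
    "P. sativum subsp. sativum": 37,
    "P. sativum subsp. humile": 10,
    "P. sativum subsp. elatius": 3,
    "P. sativum Indian ecotype": 19,
}


def table1_means() -> pd.DataFrame:
    """Published per-condition trait means for the 180-accession panel.

    Returns a DataFrame indexed by trait with columns ``control_mean`` and
    ``drought_mean``. These are input data for sensitivity-index
    computations; sensitivity indices themselves are always recomputed.
    """
    with resources.files("peapheno.data").joinpath("table1_means.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("trait")
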