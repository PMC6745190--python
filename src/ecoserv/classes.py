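"""Canonical land-cover classes and ecosystem service functions.

Every matrix and table in the package follows the same fixed ordering, so
that transition matrices, coefficient tables and area vectors can be
combined without repeated label alignment.
"""

from __future__ import annotations

#: Canonical 7-class land-cover scheme, in the fixed column order used by all
#: tables and matrices in this package.
CLASSES: tuple[str, ...] = (
    "cropland",
    "forestland",
    "grassland",
    "wetland",
    "urban",
    "bare",
    "water",
)

#: Human-readable labels for report output.
CLASS_LABELS: dict[str, str] = {
    "cropland": "Cropland",
    "forestland": "Forestland",
    "grassland": "Grassland",
    "wetland": "Wetland",
    "urban": "Urban",
    "bare": "Bare land",
    "water": "Water bodies",
}

#: The nine ecosystem service functions of the benefit-transfer scheme.
FUNCTIONS: tuple[str, ...] = (
    "food_production",
    "raw_material",
    "gas_regulation",
    "climate_regulation",
    "water_regulation",
    "soil_formation",
    "waste_treatment",
    "biodiversity",
    "recreation",
)

FUNCTION_LABELS: dict[str, str] = {
    "food_production": "Food production",
    "raw_material": "Raw material",
    "gas_regulation": "Gas regulation",
    "climate_regulation": "Climate regulation",
    "water_regulation": "Water regulation",
    "soil_formation": "Soil formation and retention",
    "waste_treatment": "Waste treatment",
    "biodiversity": "Biodiversity",
    "recreation": "Recreation, cultural and tourism",
}

N_CLASSES = len(CLASSES)
N_FUNCTIONS = len(FUNCTIONS)

#: Internal integer code for nodata cells in class grids.
NODATA = -1


def class_index(name: str) -> int:
    """Index of a class in the canonical order; raises on unknown names."""
    try:
        return CLASSES.index(name)
    except ValueError:
        raise KeyError(f"unknown land-cover class {name!r}; expected one of {CLASSES}") from None
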