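from __future__ import annotations

import pytest

from aquanrf.model import (
    NUTRIENTS,
    DVReferenceTable,
    FoodItem,
    NutrientVector,
    builtin_profiles,
)


def make_vector(fill: float | None = 0.0, **amounts) -> NutrientVector:
    """Nutrient vector with every unspecified nutrient set to ``fill``."""
    values = {n: fill for n in NUTRIENTS}
    values.update(amounts)
    return NutrientVector(**values)


def make_item(
    item_id: str = "item-1",
    species_group: str = "mackerel",
    fill: float | None = 0.0,
    **amounts,
) -> FoodItem:
    return FoodItem(
        item_id=item_id,
        species_group=species_group,
        nutrients=make_vector(fill=fill, **amounts),
    )


@pytest.fixture(scope="session")
def dv() -> DVReferenceTable:
    return DVReferenceTable.default()


@pytest.fixture(scope="session")
def profiles():
    return builtin_profiles()


@pytest.fixture(scope="session")
def nrf62(profiles):
    return profiles["NRF6.2"]


@pytest.fixture(scope="session")
def nrf92(profiles):
    return profiles["NRF9.2"]


@pytest.fixture
def mackerel_like() -> FoodItem:
    """Small-pelagic group-mean vector (fatty, high selenium/vitamin D)."""
    return make_item(
        "mackerel-mean",
        "mackerel",
        protein=23.8,
        calcium=38.4,
        iron=1.24,
        potassium=433.0,
        magnesium=35.2,
        selenium=66.2,
        vitamin_a=4.80,
        vitamin_d=30.1,
        omega3=1.56,
        saturated_fat=3.0,
        sodium=90.0,
        total_fat=12.0,
        zinc=0.52,
        folate=2.13,
        vitamin_b12=7.81,
    )
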