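"""Domain types and fixed conventions for aquatic-food nutrient profiling.

All nutrient amounts are per 100 g edible portion, in the fixed units given
by :data:`NUTRIENT_UNITS`.  A missing amount is represented as ``None``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

__all__ = [
    "NUTRIENTS",
    "NUTRIENT_UNITS",
    "NUTRIENT_COLUMNS",
    "BROAD_GROUPS",
    "TAXON_GROUPS",
    "SPECIES_GROUPS",
    "STATES",
    "HABITATS",
    "SALINITIES",
    "PROVENANCE_TAGS",
    "TAXON_TO_BROAD",
    "SPECIES_TO_TAXON",
    "ZERO_NUTRIENTS",
    "NutrientVector",
    "FoodItem",
    "DVReferenceTable",
    "NutrientProfile",
    "PriceRecord",
    "ScoreResult",
    "TaxonomyError",
    "UnitMismatchError",
    "species_to_taxon",
    "default_dv_table",
    "builtin_profiles",
]

# ---------------------------------------------------------------------------
# Nutrient vocabulary and units
# ---------------------------------------------------------------------------

#: Modeled nutrients, in canonical order.
NUTRIENTS: tuple[str, ...] = (
    "protein",
    "total_fat",
    "saturated_fat",
    "omega3",
    "sodium",
    "iron",
    "zinc",
    "calcium",
    "potassium",
    "magnesium",
    "selenium",
    "folate",
    "vitamin_b12",
    "vitamin_a",
    "vitamin_d",
)

#: Fixed package-wide unit for each nutrient (per 100 g edible portion).
NUTRIENT_UNITS: dict[str, str] = {
    "protein": "g",
    "total_fat": "g",
    "saturated_fat": "g",
    "omega3": "g",
    "sodium": "mg",
    "iron": "mg",
    "zinc": "mg",
    "calcium": "mg",
    "potassium": "mg",
    "magnesium": "mg",
    "selenium": "ug",
    "folate": "ug",
    "vitamin_b12": "ug",
    "vitamin_a": "ug_rae",
    "vitamin_d": "ug",
}

#: CSV column name for each nutrient (unit-suffixed).
NUTRIENT_COLUMNS: dict[str, str] = {
    name: f"{name}_{unit}" for name, unit in NUTRIENT_UNITS.items()
}

#: Nutrients that may appear in a profile but are absent from aquatic-food
#: composition records; they contribute 0 %DV (fiber and vitamin C are
#: negligible in fish and shellfish).
ZERO_NUTRIENTS: frozenset[str] = frozenset({"fiber", "vitamin_c"})

# ---------------------------------------------------------------------------
# Taxonomy vocabulary
# ---------------------------------------------------------------------------

BROAD_GROUPS: tuple[str, ...] = ("crustacean", "finfish", "mollusk")

TAXON_GROUPS: tuple[str, ...] = (
    "small_pelagic",
    "cichlid",
    "demersal",
    "salmonid",
    "cod",
    "bivalve",
    "gastropod",
    "cephalopod",
    "crustacean",
)

TAXON_TO_BROAD: dict[str, str] = {
    "small_pelagic": "finfish",
    "cichlid": "finfish",
    "demersal": "finfish",
    "salmonid": "finfish",
    "cod": "finfish",
    "bivalve": "mollusk",
    "gastropod": "mollusk",
    "cephalopod": "mollusk",
    "crustacean": "crustacean",
}

# Frozen species -> taxon assignment.  Deliberately mirrors the source
# classification even where biologically debatable (sole filed under
# "cichlid"); do not "fix".
SPECIES_TO_TAXON: dict[str, str] = {
    "abalone": "gastropod",
    "bass": "demersal",
    "catfish": "demersal",
    "clam": "bivalve",
    "cod": "cod",
    "conch": "gastropod",
    "crab": "crustacean",
    "crayfish": "crustacean",
    "lobster": "crustacean",
    "mackerel": "small_pelagic",
    "mussel": "bivalve",
    "octopus": "cephalopod",
    "oyster": "bivalve",
    "pike": "demersal",
    "salmon": "salmonid",
    "scallop": "bivalve",
    "shrimp_prawn": "crustacean",
    "sole": "cichlid",
    "squid": "cephalopod",
    "tilapia": "cichlid",
    "trout": "salmonid",
}

SPECIES_GROUPS: tuple[str, ...] = tuple(sorted(SPECIES_TO_TAXON))

STATES: tuple[str, ...] = ("raw", "cooked", "preserved")
HABITATS: tuple[str, ...] = ("farmed", "wild", "unknown")
SALINITIES: tuple[str, ...] = ("freshwater", "saltwater", "unknown")

#: Per-nutrient provenance source tags.
PROVENANCE_TAGS: tuple[str, ...] = ("primary", "fallback_1", "fallback_2", "unresolved")


class TaxonomyError(ValueError):
    """Raised for labels outside the fixed taxonomy vocabulary."""


class UnitMismatchError(ValueError):
    """Raised when a declared unit disagrees with the package convention."""


def species_to_taxon(species_group: str) -> tuple[str, str]:
    """Map a species label to its ``(taxon_group, broad_group)`` pair.

    The lookup is total over the 21-species vocabulary and deterministic.

    Raises
    ------
    TaxonomyError
        If ``species_group`` is not one of the known labels.
    """
    try:
        taxon = SPECIES_TO_TAXON[species_group]
    except KeyError:
        raise TaxonomyError(
            f"unknown species_group {species_group!r}; expected one of: "
            + ", ".join(SPECIES_GROUPS)
        ) from None
    return taxon, TAXON_TO_BROAD[taxon]


# ---------------------------------------------------------------------------
# Nutrient vector
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class NutrientVector:
    """Amounts of the modeled nutrients per 100 g edible portion.

    ``None`` marks a missing value.  Units are fixed (:data:`NUTRIENT_UNITS`).
    """

    protein: float | None = None
    total_fat: float | None = None
    saturated_fat: float | None = None
    omega3: float | None = None
    sodium: float | None = None
    iron: float | None = None
    zinc: float | None = None
    calcium: float | None = None
    potassium: float | None = None
    magnesium: float | None = None
    selenium: float | None = None
    folate: float | None = None
    vitamin_b12: float | None = None
    vitamin_a: float | None = None
    vitamin_d: float | None = None

    def get(self, nutrient: str) -> float | None:
        if nutrient in ZERO_NUTRIENTS:
            return 0.0
        if nutrient not in NUTRIENT_UNITS:
            raise KeyError(f"unknown nutrient {nutrient!r}")
        return getattr(self, nutrient)

    def as_dict(self) -> dict[str, float | None]:
        return {n: getattr(self, n) for n in NUTRIENTS}

    def missing(self) -> tuple[str, ...]:
        """Names of nutrients currently missing."""
        return tuple(n for n in NUTRIENTS if getattr(self, n) is None)

    def validate(self) -> None:
        """Check non-negativity and fat-component consistency.

        Raises ``ValueError`` on violation.
        """
        for n in NUTRIENTS:
            v = getattr(self, n)
            if v is None:
                continue
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{n} must be a finite non-negative amount, got {v!r}")
        if self.total_fat is not None:
            for part in ("saturated_fat", "omega3"):
                v = getattr(self, part)
                # tolerate rounding noise at the last printed digit
                if v is not None and v > self.total_fat * (1 + 1e-9) + 1e-9:
                    raise ValueError(
                        f"{part} ({v}) exceeds total_fat ({self.total_fat})"
                    )


# ---------------------------------------------------------------------------
# Food item
# ---------------------------------------------------------------------------


def _default_provenance(nutrients: NutrientVector) -> dict[str, str]:
    return {
        n: ("unresolved" if getattr(nutrients, n) is None else "primary")
        for n in NUTRIENTS
    }


@dataclass(slots=True)
class FoodItem:
    """One composition record: identity, taxonomy, state, nutrients, provenance."""

    item_id: str
    species_group: str
    nutrients: NutrientVector
    state: str = "raw"
    habitat: str = "unknown"
    salinity: str = "unknown"
    taxon_group: str = ""
    broad_group: str = ""
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        taxon, broad = species_to_taxon(self.species_group)
        if not self.taxon_group:
            self.taxon_group = taxon
        elif self.taxon_group != taxon:
            raise TaxonomyError(
                f"item {self.item_id!r}: taxon_group {self.taxon_group!r} "
                f"inconsistent with species_group {self.species_group!r} "
                f"(expected {taxon!r})"
            )
        if not self.broad_group:
            self.broad_group = broad
        elif self.broad_group != broad:
            raise TaxonomyError(
                f"item {self.item_id!r}: broad_group {self.broad_group!r} "
                f"inconsistent with taxon_group {self.taxon_group!r} "
                f"(expected {broad!r})"
            )
        for label, vocab in (
            (self.state, STATES),
            (self.habitat, HABITATS),
            (self.salinity, SALINITIES),
        ):
            if label not in vocab:
                raise TaxonomyError(
                    f"item {self.item_id!r}: unknown label {label!r}; "
                    f"expected one of: {', '.join(vocab)}"
                )
        if not self.provenance:
            self.provenance = _default_provenance(self.nutrients)

    def copy(self) -> "FoodItem":
        return replace(
            self,
            nutrients=replace(self.nutrients),
            provenance=dict(self.provenance),
        )


# ---------------------------------------------------------------------------
# Daily-value reference table
# ---------------------------------------------------------------------------

# FDA daily values (2016 rule, ages >= 4).  Omega-3 has no FDA DV; 1.6 g/day
# (the adequate-intake level for ALA in adult men) is the shipped default and
# is config-overridable.
_DEFAULT_DV: dict[str, tuple[float, str]] = {
    "protein": (50.0, "g"),
    "total_fat": (78.0, "g"),
    "saturated_fat": (20.0, "g"),
    "omega3": (1.6, "g"),
    "sodium": (2300.0, "mg"),
    "iron": (18.0, "mg"),
    "zinc": (11.0, "mg"),
    "calcium": (1300.0, "mg"),
    "potassium": (4700.0, "mg"),
    "magnesium": (420.0, "mg"),
    "selenium": (55.0, "ug"),
    "folate": (400.0, "ug"),
    "vitamin_b12": (2.4, "ug"),
    "vitamin_a": (900.0, "ug_rae"),
    "vitamin_d": (20.0, "ug"),
}


class DVReferenceTable:
    """Nutrient -> (daily value, unit) map used as the %DV denominator.

    Complete over every :class:`NutrientVector` field; units must match the
    package-wide conventions exactly.
    """

    def __init__(self, values: Mapping[str, tuple[float, str]]):
        table = {}
        for name, (dv, unit) in values.items():
            if name not in NUTRIENT_UNITS:
                raise KeyError(f"unknown nutrient {name!r} in DV table")
            expected = NUTRIENT_UNITS[name]
            if unit != expected:
                raise UnitMismatchError(
                    f"DV for {name!r} declared in {unit!r} but the package "
                    f"convention is {expected!r}"
                )
            if not (isinstance(dv, (int, float)) and math.isfinite(dv) and dv > 0):
                raise ValueError(f"DV for {name!r} must be > 0, got {dv!r}")
            table[name] = (float(dv), unit)
        missing = [n for n in NUTRIENTS if n not in table]
        if missing:
            raise ValueError(
                "DV table incomplete; missing: " + ", ".join(missing)
            )
        self._table = table

    @classmethod
    def default(cls) -> "DVReferenceTable":
        return cls(_DEFAULT_DV)

    @classmethod
    def with_overrides(cls, overrides: Mapping[str, float]) -> "DVReferenceTable":
        """Default table with selected daily values replaced (units fixed)."""
        merged = dict(_DEFAULT_DV)
        for name, dv in overrides.items():
            if name not in merged:
                raise KeyError(f"unknown nutrient {name!r} in DV overrides")
            merged[name] = (float(dv), merged[name][1])
        return cls(merged)

    def dv(self, nutrient: str) -> float:
        return self._table[nutrient][0]

    def unit(self, nutrient: str) -> str:
        return self._table[nutrient][1]

    def __contains__(self, nutrient: str) -> bool:
        return nutrient in self._table

    def __len__(self) -> int:
        return len(self._table)

    def as_dict(self) -> dict[str, tuple[float, str]]:
        return dict(self._table)


def default_dv_table() -> DVReferenceTable:
    return DVReferenceTable.default()


# ---------------------------------------------------------------------------
# Nutrient profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NutrientProfile:
    """A named NRF variant: encourage list, limit list, capping policy.

    ``cap_encourage``/``cap_limit`` are %DV ceilings per nutrient; ``None``
    means uncapped.
    """

    name: str
    encourage: tuple[str, ...]
    limit: tuple[str, ...] = ("saturated_fat", "sodium")
    cap_encourage: float | None = 100.0
    cap_limit: float | None = 100.0

    def __post_init__(self) -> None:
        overlap = set(self.encourage) & set(self.limit)
        if overlap:
            raise ValueError(
                f"profile {self.name!r}: nutrients in both encourage and "
                f"limit lists: {sorted(overlap)}"
            )
        for n in (*self.encourage, *self.limit):
            if n not in NUTRIENT_UNITS and n not in ZERO_NUTRIENTS:
                raise KeyError(f"profile {self.name!r}: unknown nutrient {n!r}")

    def validate_against(self, dv: DVReferenceTable) -> None:
        for n in (*self.encourage, *self.limit):
            if n not in ZERO_NUTRIENTS and n not in dv:
                raise ValueError(
                    f"profile {self.name!r}: nutrient {n!r} has no daily value"
                )

    @property
    def n_encourage(self) -> int:
        return len(self.encourage)


#: Six priority micronutrients widely lacking in LMIC diets.
PROFILE_NRF6_2 = NutrientProfile(
    name="NRF6.2",
    encourage=("iron", "zinc", "calcium", "vitamin_a", "vitamin_b12", "folate"),
)

#: Aquatic-food variant: protein, selenium, minerals, vitamins A/D, omega-3.
PROFILE_NRF9_2 = NutrientProfile(
    name="NRF9.2",
    encourage=(
        "protein",
        "selenium",
        "calcium",
        "iron",
        "potassium",
        "magnesium",
        "vitamin_a",
        "vitamin_d",
        "omega3",
    ),
)

#: Classic general-food variant; fiber and vitamin C score zero for aquatic
#: items (negligible content), shipped for comparison only.
PROFILE_NRF9_2_CLASSIC = NutrientProfile(
    name="NRF9.2-classic",
    encourage=(
        "protein",
        "fiber",
        "calcium",
        "iron",
        "potassium",
        "magnesium",
        "vitamin_a",
        "vitamin_c",
        "vitamin_d",
    ),
)


def builtin_profiles() -> dict[str, NutrientProfile]:
    """Shipped profiles keyed by name; the aquatic NRF9.2 is the default."""
    return {
        p.name: p
        for p in (PROFILE_NRF6_2, PROFILE_NRF9_2, PROFILE_NRF9_2_CLASSIC)
    }


# ---------------------------------------------------------------------------
# Prices and scores
# ---------------------------------------------------------------------------

CURRENCIES: tuple[str, ...] = ("EUR", "USD")


@dataclass(slots=True)
class PriceRecord:
    """Price of the whole/landed product and its edible-portion yield.

    ``price_per_kg`` may be ``None`` for species with no available price.
    """

    species_group: str
    price_per_kg: float | None
    currency: str = "USD"
    yield_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.species_group not in SPECIES_TO_TAXON:
            raise TaxonomyError(
                f"unknown species_group {self.species_group!r} in price record"
            )
        if self.currency not in CURRENCIES:
            raise ValueError(
                f"unknown currency {self.currency!r}; expected one of {CURRENCIES}"
            )
        if self.price_per_kg is not None and not self.price_per_kg > 0:
            raise ValueError(
                f"price_per_kg must be > 0, got {self.price_per_kg!r}"
            )
        if self.yield_fraction is not None and not (0 < self.yield_fraction <= 1):
            raise ValueError(
                f"yield_fraction must be in (0, 1], got {self.yield_fraction!r}"
            )


@dataclass(slots=True)
class ScoreResult:
    """Per-item NRF score with its subscores and %DV breakdown."""

    item_id: str
    profile: str
    nr_subscore: float
    lim_subscore: float
    nrf: float
    dv_breakdown: dict[str, float] = field(default_factory=dict)


def validate_items(items: Iterable[FoodItem]) -> None:
    """Validate every item's nutrient vector; raises on first violation."""
    for item in items:
        try:
            item.nutrients.validate()
        except ValueError as exc:
            raise ValueError(f"item {item.item_id!r}: {exc}") from exc
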