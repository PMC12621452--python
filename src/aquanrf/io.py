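"""Readers and writers for composition tables, price tables, and configs.

Composition CSV schema (canonical): columns ``item_id``, ``species_group``,
``state``, ``habitat``, ``salinity``, ``broad_group``, ``taxon_group``, then
one unit-suffixed column per nutrient (``protein_g`` ... ``vitamin_d_ug``),
and an optional ``provenance`` column listing non-primary tags as
``nutrient:tag`` pairs joined by ``;``.  Empty nutrient cell = missing.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .model import (
    NUTRIENT_COLUMNS,
    NUTRIENT_UNITS,
    NUTRIENTS,
    DVReferenceTable,
    FoodItem,
    NutrientProfile,
    NutrientVector,
    PriceRecord,
    UnitMismatchError,
    builtin_profiles,
)

__all__ = [
    "SchemaError",
    "read_composition_table",
    "write_composition_table",
    "read_price_table",
    "write_price_table",
    "load_dv_table",
    "load_profiles",
]

MANDATORY_COLUMNS = ("item_id", "species_group", "broad_group")


class SchemaError(ValueError):
    """Raised when a CSV does not match the declared schema."""


# mass-unit conversion factors to grams; ug_rae converts like ug
_TO_G = {"g": 1.0, "mg": 1e-3, "ug": 1e-6, "mcg": 1e-6, "ug_rae": 1e-6}


def _unit_factor(from_unit: str, to_unit: str) -> float:
    try:
        return _TO_G[from_unit] / _TO_G[to_unit]
    except KeyError as exc:
        raise UnitMismatchError(f"unsupported unit {exc.args[0]!r}") from None


def _resolve_columns(schema: Mapping | None) -> dict[str, tuple[str, float]]:
    """Map nutrient -> (csv column, multiplicative factor to package units).

    ``schema`` may carry a ``columns`` mapping of nutrient name ->
    ``{column: str, unit: str}`` to override the canonical suffixed names.
    """
    resolved: dict[str, tuple[str, float]] = {}
    overrides = (schema or {}).get("columns", {})
    for nutrient in NUTRIENTS:
        if nutrient in overrides:
            spec = overrides[nutrient]
            column = spec.get("column", NUTRIENT_COLUMNS[nutrient])
            unit = spec.get("unit", NUTRIENT_UNITS[nutrient])
            factor = _unit_factor(unit, NUTRIENT_UNITS[nutrient])
        else:
            column, factor = NUTRIENT_COLUMNS[nutrient], 1.0
        resolved[nutrient] = (column, factor)
    return resolved


def _parse_provenance(cell: object) -> dict[str, str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return {}
    out = {}
    for pair in str(cell).split(";"):
        pair = pair.strip()
        if not pair:
            continue
        nutrient, _, tag = pair.partition(":")
        out[nutrient.strip()] = tag.strip()
    return out


def _format_provenance(item: FoodItem) -> str:
    parts = [
        f"{n}:{tag}"
        for n, tag in item.provenance.items()
        if tag not in ("primary", "unresolved")
    ]
    return ";".join(parts)


def read_composition_table(
    path: str | Path, schema: Mapping | None = None
) -> list[FoodItem]:
    """Read a composition CSV into :class:`FoodItem` records.

    Unparseable numeric cells become missing with provenance ``unresolved``;
    row count is preserved.  Missing mandatory columns or unknown taxonomy
    labels raise hard errors.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"composition table {path} lacks mandatory column {col!r}")
    columns = _resolve_columns(schema)
    items: list[FoodItem] = []
    for row in df.itertuples(index=False):
        record = row._asdict()
        amounts: dict[str, float | None] = {}
        for nutrient, (column, factor) in columns.items():
            raw = record.get(column, "")
            if raw is None or str(raw).strip() == "":
                amounts[nutrient] = None
                continue
            try:
                amounts[nutrient] = float(raw) * factor
            except ValueError:
                amounts[nutrient] = None
        vector = NutrientVector(**amounts)
        provenance = _default_then(vector, _parse_provenance(record.get("provenance")))
        items.append(
            FoodItem(
                item_id=str(record["item_id"]),
                species_group=str(record["species_group"]),
                state=str(record.get("state") or "raw"),
                habitat=str(record.get("habitat") or "unknown"),
                salinity=str(record.get("salinity") or "unknown"),
                taxon_group=str(record.get("taxon_group") or ""),
                broad_group=str(record.get("broad_group") or ""),
                nutrients=vector,
                provenance=provenance,
            )
        )
    return items


def _default_then(vector: NutrientVector, tags: dict[str, str]) -> dict[str, str]:
    provenance = {
        n: ("unresolved" if getattr(vector, n) is None else "primary")
        for n in NUTRIENTS
    }
    provenance.update(tags)
    return provenance


def write_composition_table(
    items: Iterable[FoodItem], path: str | Path, precision: int = 6
) -> None:
    """Write items in the canonical composition-CSV schema."""
    rows = []
    for item in items:
        row: dict[str, object] = {
            "item_id": item.item_id,
            "species_group": item.species_group,
            "state": item.state,
            "habitat": item.habitat,
            "salinity": item.salinity,
            "broad_group": item.broad_group,
            "taxon_group": item.taxon_group,
        }
        for nutrient in NUTRIENTS:
            value = getattr(item.nutrients, nutrient)
            row[NUTRIENT_COLUMNS[nutrient]] = (
                "" if value is None else f"{value:.{precision}g}"
            )
        row["provenance"] = _format_provenance(item)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Price tables
# ---------------------------------------------------------------------------


def read_price_table(path: str | Path) -> list[PriceRecord]:
    """Read a price CSV (species_group, price_per_kg, currency, yield_fraction)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("species_group", "price_per_kg"):
        if col not in df.columns:
            raise SchemaError(f"price table {path} lacks mandatory column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        price_raw = str(rec.get("price_per_kg", "")).strip()
        yield_raw = str(rec.get("yield_fraction", "")).strip()
        records.append(
            PriceRecord(
                species_group=str(rec["species_group"]),
                price_per_kg=float(price_raw) if price_raw else None,
                currency=str(rec.get("currency") or "USD"),
                yield_fraction=float(yield_raw) if yield_raw else None,
            )
        )
    return records


def write_price_table(records: Iterable[PriceRecord], path: str | Path) -> None:
    rows = [
        {
            "species_group": r.species_group,
            "price_per_kg": "" if r.price_per_kg is None else r.price_per_kg,
            "currency": r.currency,
            "yield_fraction": "" if r.yield_fraction is None else r.yield_fraction,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# DV / profile configuration
# ---------------------------------------------------------------------------


def _load_config_file(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text) or {}
    return yaml.safe_load(text) or {}


def load_dv_table(path: str | Path | None = None) -> DVReferenceTable:
    """Load a DV table from a YAML/JSON config, or the shipped defaults.

    The config's ``daily_values`` section maps nutrient -> number (unit fixed)
    or nutrient -> ``{value: number, unit: str}``; units, when given, must
    match the package convention exactly.
    """
    if path is None:
        return DVReferenceTable.default()
    config = _load_config_file(path)
    section = config.get("daily_values", config if "daily_values" not in config else {})
    overrides: dict[str, float] = {}
    for name, value in (section or {}).items():
        if isinstance(value, Mapping):
            unit = value.get("unit")
            if unit is not None and unit != NUTRIENT_UNITS.get(name):
                raise UnitMismatchError(
                    f"DV config declares {name!r} in {unit!r} but the package "
                    f"convention is {NUTRIENT_UNITS.get(name)!r}"
                )
            overrides[name] = float(value["value"])
        else:
            overrides[name] = float(value)
    return DVReferenceTable.with_overrides(overrides)


def load_profiles(path: str | Path | None = None) -> dict[str, NutrientProfile]:
    """Load named profiles from config, merged over the shipped ones.

    Config section ``profiles`` maps name -> ``{encourage: [...], limit:
    [...], cap_encourage: number, cap_limit: number | "uncapped"}``.
    """
    profiles = builtin_profiles()
    if path is None:
        return profiles
    config = _load_config_file(path)
    for name, spec in (config.get("profiles") or {}).items():
        cap_enc = spec.get("cap_encourage", 100.0)
        cap_lim = spec.get("cap_limit", 100.0)
        profiles[name] = NutrientProfile(
            name=name,
            encourage=tuple(spec["encourage"]),
            limit=tuple(spec.get("limit", ("saturated_fat", "sodium"))),
            cap_encourage=None if cap_enc in (None, "uncapped") else float(cap_enc),
            cap_limit=None if cap_lim in (None, "uncapped") else float(cap_lim),
        )
    return profiles
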