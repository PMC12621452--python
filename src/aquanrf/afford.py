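"""Edible-portion price processing and the NRF Affordability Index.

Prices per kg of whole/landed product are currency-converted, divided by the
edible-portion yield, and combined with group mean NRF scores and protein
content into cost-per-100 g-protein and NRF-affordability rankings.  Money
and indices are reported at 2 dp; internal arithmetic is unrounded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import PriceRecord, species_to_taxon
from .scoring import GroupScoreSummary

__all__ = [
    "DEFAULT_EUR_TO_USD",
    "AffordabilityRecord",
    "convert_currency",
    "edible_price",
    "cost_per_100g_protein",
    "affordability_index",
    "build_affordability_table",
    "affordability_frame",
]

logger = logging.getLogger(__name__)

#: EUR->USD exchange rate of the October-2024 price snapshot.
DEFAULT_EUR_TO_USD = 1.09


def convert_currency(
    price_per_kg: float, currency: str, rate_eur_to_usd: float = DEFAULT_EUR_TO_USD
) -> float:
    """Convert a per-kg price to USD; USD passes through unchanged."""
    if not rate_eur_to_usd > 0:
        raise ValueError(f"exchange rate must be > 0, got {rate_eur_to_usd!r}")
    if currency == "USD":
        return price_per_kg
    if currency == "EUR":
        return price_per_kg * rate_eur_to_usd
    raise ValueError(f"unknown currency {currency!r}")


def edible_price(price_usd_per_kg_whole: float, yield_fraction: float) -> float:
    """Price per kg of edible portion: whole-product price / yield."""
    if not (0 < yield_fraction <= 1):
        raise ValueError(f"yield_fraction must be in (0, 1], got {yield_fraction!r}")
    return price_usd_per_kg_whole / yield_fraction


def cost_per_100g_protein(
    price_usd_per_kg_edible: float, protein_g_per_100g: float
) -> float:
    """USD needed to buy 100 g of protein: (edible price per 100 g)/protein × 100."""
    if not protein_g_per_100g > 0:
        raise ValueError(f"protein must be > 0, got {protein_g_per_100g!r}")
    return 10.0 * price_usd_per_kg_edible / protein_g_per_100g


def affordability_index(mean_nrf: float, price_usd_per_kg_edible: float) -> float:
    """Mean NRF score per (USD per kg edible portion).

    A negative mean NRF yields a negative index.
    """
    if not price_usd_per_kg_edible > 0:
        raise ValueError(
            f"edible-portion price must be > 0, got {price_usd_per_kg_edible!r}"
        )
    return mean_nrf / price_usd_per_kg_edible


@dataclass(slots=True)
class AffordabilityRecord:
    """Affordability quantities for one species group; ``None`` marks N/A."""

    species_group: str
    taxon_group: str
    price_usd_per_kg_whole: float | None
    yield_fraction: float | None
    price_usd_per_kg_edible: float | None
    cost_usd_per_100g_protein: float | None
    nrf6_2_affordability: float | None
    nrf9_2_affordability: float | None


def _lookup(values: Mapping[str, float], species: str, taxon: str) -> float | None:
    if species in values:
        return values[species]
    return values.get(taxon)


def _summary_means(
    summaries: Iterable[GroupScoreSummary],
) -> dict[str, dict[str, float]]:
    by_metric: dict[str, dict[str, float]] = {}
    for s in summaries:
        by_metric.setdefault(s.metric, {})[s.group] = s.mean
    return by_metric


def build_affordability_table(
    prices: Sequence[PriceRecord],
    score_summaries: Iterable[GroupScoreSummary],
    protein_means: Mapping[str, float],
    rate_eur_to_usd: float = DEFAULT_EUR_TO_USD,
    nrf6_metric: str = "NRF6.2",
    nrf9_metric: str = "NRF9.2",
) -> list[AffordabilityRecord]:
    """One affordability record per priced species group, ranked.

    Score/protein summaries may be keyed by species group or by taxon group
    (a species falls back to its taxon's summary).  Species with no price are
    emitted with N/A markers; priced species with no matching score summary
    are logged and skipped.  Output is sorted by NRF9.2 affordability
    descending, N/A rows last.
    """
    means = _summary_means(score_summaries)
    nrf6_means = means.get(nrf6_metric, {})
    nrf9_means = means.get(nrf9_metric, {})
    records: list[AffordabilityRecord] = []
    for price in prices:
        taxon, _ = species_to_taxon(price.species_group)
        if price.price_per_kg is None or price.yield_fraction is None:
            records.append(
                AffordabilityRecord(
                    species_group=price.species_group,
                    taxon_group=taxon,
                    price_usd_per_kg_whole=None,
                    yield_fraction=price.yield_fraction,
                    price_usd_per_kg_edible=None,
                    cost_usd_per_100g_protein=None,
                    nrf6_2_affordability=None,
                    nrf9_2_affordability=None,
                )
            )
            continue
        nrf6 = _lookup(nrf6_means, price.species_group, taxon)
        nrf9 = _lookup(nrf9_means, price.species_group, taxon)
        protein = _lookup(protein_means, price.species_group, taxon)
        if nrf6 is None and nrf9 is None and protein is None:
            logger.warning(
                "no score or protein summary for priced species %r; skipped",
                price.species_group,
            )
            continue
        usd_whole = convert_currency(price.price_per_kg, price.currency, rate_eur_to_usd)
        usd_edible = edible_price(usd_whole, price.yield_fraction)
        records.append(
            AffordabilityRecord(
                species_group=price.species_group,
                taxon_group=taxon,
                price_usd_per_kg_whole=usd_whole,
                yield_fraction=price.yield_fraction,
                price_usd_per_kg_edible=usd_edible,
                cost_usd_per_100g_protein=(
                    None if protein is None else cost_per_100g_protein(usd_edible, protein)
                ),
                nrf6_2_affordability=(
                    None if nrf6 is None else affordability_index(nrf6, usd_edible)
                ),
                nrf9_2_affordability=(
                    None if nrf9 is None else affordability_index(nrf9, usd_edible)
                ),
            )
        )
    records.sort(
        key=lambda r: (
            r.nrf9_2_affordability is None,
            -(r.nrf9_2_affordability or 0.0),
            r.species_group,
        )
    )
    return records


def affordability_frame(
    records: Sequence[AffordabilityRecord], decimals: int = 2
) -> pd.DataFrame:
    """Report table with 2-dp money/index columns and rank columns."""
    columns = [
        "species_group",
        "taxon_group",
        "price_usd_per_kg",
        "yield_fraction",
        "price_usd_per_kg_edible",
        "cost_usd_per_100g_protein",
        "nrf6_2_affordability",
        "nrf9_2_affordability",
    ]
    df = pd.DataFrame(
        [
            {
                "species_group": r.species_group,
                "taxon_group": r.taxon_group,
                "price_usd_per_kg": r.price_usd_per_kg_whole,
                "yield_fraction": r.yield_fraction,
                "price_usd_per_kg_edible": r.price_usd_per_kg_edible,
                "cost_usd_per_100g_protein": r.cost_usd_per_100g_protein,
                "nrf6_2_affordability": r.nrf6_2_affordability,
                "nrf9_2_affordability": r.nrf9_2_affordability,
            }
            for r in records
        ],
        columns=columns,
    )
    for col in ("nrf6_2_affordability", "nrf9_2_affordability"):
        df[f"rank_{col}"] = df[col].rank(ascending=False, method="min")
    money_cols = [
        "price_usd_per_kg",
        "price_usd_per_kg_edible",
        "cost_usd_per_100g_protein",
        "nrf6_2_affordability",
        "nrf9_2_affordability",
    ]
    df[money_cols] = df[money_cols].round(decimals)
    return df
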