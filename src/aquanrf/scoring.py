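"""NRF scoring: %DV, NRn and LIM subscores, NRFn.2, and group summaries.

Scores are computed per item (mean of scores, never score of means) on a
per-100 g edible-portion basis.  %DV contributions are capped per nutrient
(default 100%); NRFn.2 = NRn − LIM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .model import (
    DVReferenceTable,
    FoodItem,
    NutrientProfile,
    ScoreResult,
    ZERO_NUTRIENTS,
)

__all__ = [
    "MissingNutrientError",
    "GroupScoreSummary",
    "percent_dv",
    "nr_subscore",
    "lim_subscore",
    "nrf_score",
    "score_dataset",
    "summarize_values",
]

logger = logging.getLogger(__name__)

MISSING_POLICIES = ("strict", "zero")


class MissingNutrientError(ValueError):
    """A nutrient required by the profile is missing under the strict policy."""


@dataclass(slots=True)
class GroupScoreSummary:
    """N, mean, sample SD (n−1), and SEM of one metric within one group."""

    group: str
    metric: str
    n: int
    mean: float
    sd: float
    sem: float


def percent_dv(amount: float, dv: float, cap: float | None = 100.0) -> float:
    """Percent of the daily value supplied by ``amount``, capped at ``cap``.

    ``cap=None`` disables capping.
    """
    if amount is None:
        raise MissingNutrientError(
            "missing amount; impute or apply a missing-value policy before scoring"
        )
    if not dv > 0:
        raise ValueError(f"daily value must be > 0, got {dv!r}")
    if amount < 0:
        raise ValueError(f"amount must be >= 0, got {amount!r}")
    pct = 100.0 * amount / dv
    return pct if cap is None else min(pct, cap)


def _resolve_amount(
    item: FoodItem, nutrient: str, missing_policy: str
) -> float:
    amount = item.nutrients.get(nutrient)
    if amount is None:
        if missing_policy == "zero":
            return 0.0
        raise MissingNutrientError(
            f"item {item.item_id!r}: nutrient {nutrient!r} is missing; "
            "impute first or use missing_policy='zero'"
        )
    return amount


def _subscore(
    item: FoodItem,
    nutrients: Sequence[str],
    cap: float | None,
    dv: DVReferenceTable,
    missing_policy: str,
    breakdown: dict[str, float] | None = None,
) -> float:
    total = 0.0
    for nutrient in nutrients:
        if nutrient in ZERO_NUTRIENTS:
            pct = 0.0
        else:
            amount = _resolve_amount(item, nutrient, missing_policy)
            pct = percent_dv(amount, dv.dv(nutrient), cap)
        if breakdown is not None:
            breakdown[nutrient] = pct
        total += pct
    return total


def nr_subscore(
    item: FoodItem,
    profile: NutrientProfile,
    dv: DVReferenceTable,
    missing_policy: str = "strict",
) -> float:
    """Sum of capped %DVs over the profile's nutrients to encourage."""
    return _subscore(item, profile.encourage, profile.cap_encourage, dv, missing_policy)


def lim_subscore(
    item: FoodItem,
    profile: NutrientProfile,
    dv: DVReferenceTable,
    missing_policy: str = "strict",
) -> float:
    """Sum of %DVs over the profile's nutrients to limit."""
    return _subscore(item, profile.limit, profile.cap_limit, dv, missing_policy)


def nrf_score(
    item: FoodItem,
    profile: NutrientProfile,
    dv: DVReferenceTable,
    missing_policy: str = "strict",
) -> ScoreResult:
    """NRFn.2 = NRn − LIM, with the per-nutrient %DV breakdown retained."""
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    profile.validate_against(dv)
    breakdown: dict[str, float] = {}
    nr = _subscore(
        item, profile.encourage, profile.cap_encourage, dv, missing_policy, breakdown
    )
    lim = _subscore(
        item, profile.limit, profile.cap_limit, dv, missing_policy, breakdown
    )
    return ScoreResult(
        item_id=item.item_id,
        profile=profile.name,
        nr_subscore=nr,
        lim_subscore=lim,
        nrf=nr - lim,
        dv_breakdown=breakdown,
    )


def summarize_values(values: Sequence[float]) -> tuple[int, float, float, float]:
    """(N, mean, sample SD with n−1 denominator, SEM=SD/√N)."""
    n = len(values)
    if n == 0:
        raise ValueError("cannot summarize an empty group")
    mean = sum(values) / n
    if n == 1:
        return 1, mean, float("nan"), float("nan")
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    sd = math.sqrt(var)
    return n, mean, sd, sd / math.sqrt(n)


def score_dataset(
    items: Iterable[FoodItem],
    profile: NutrientProfile,
    dv: DVReferenceTable,
    group_by: str | Callable[[FoodItem], str] = "broad_group",
    missing_policy: str = "strict",
) -> tuple[list[ScoreResult], list[GroupScoreSummary]]:
    """Score every item, then summarize scores within each group.

    ``group_by`` is a :class:`FoodItem` attribute name (``broad_group``,
    ``taxon_group``, ``species_group``, ``habitat``, ``state``) or a callable.
    Empty groups are omitted (with a logged warning for groups that appear in
    the data but yield no scorable item).
    """
    key = group_by if callable(group_by) else lambda it: getattr(it, group_by)
    results: list[ScoreResult] = []
    grouped: dict[str, list[float]] = {}
    for item in items:
        result = nrf_score(item, profile, dv, missing_policy)
        results.append(result)
        grouped.setdefault(key(item), []).append(result.nrf)
    summaries = []
    for group in sorted(grouped):
        values = grouped[group]
        if not values:
            logger.warning("group %r has no scorable items; summary omitted", group)
            continue
        n, mean, sd, sem = summarize_values(values)
        summaries.append(
            GroupScoreSummary(
                group=group, metric=profile.name, n=n, mean=mean, sd=sd, sem=sem
            )
        )
    return results, summaries
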