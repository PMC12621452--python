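"""Hierarchical lookup imputation from ordered fallback composition tables.

Missing nutrient values are filled per nutrient from the first fallback
source whose matched donor item carries the value; provenance records the
filling source.  Matching is (species_group, state) exact first, then
species_group with state relaxed, never cross-species.  No statistical
imputation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .model import NUTRIENTS, FoodItem

__all__ = [
    "FallbackSource",
    "MatchResult",
    "ImputationReport",
    "match_candidate",
    "impute_dataset",
]


def _completeness(item: FoodItem) -> int:
    return sum(1 for n in NUTRIENTS if getattr(item.nutrients, n) is not None)


def _best_donor(candidates: Sequence[FoodItem]) -> FoodItem:
    # most non-missing fields wins; ties broken by lexicographic item_id
    return min(candidates, key=lambda it: (-_completeness(it), it.item_id))


@dataclass
class FallbackSource:
    """One fallback composition table with a priority rank (1 = first)."""

    name: str
    priority: int
    items: list[FoodItem]
    _by_species_state: dict[tuple[str, str], list[FoodItem]] = field(
        init=False, repr=False, default_factory=dict
    )
    _by_species: dict[str, list[FoodItem]] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.priority < 1:
            raise ValueError(f"priority must be >= 1, got {self.priority}")
        for item in self.items:
            self._by_species_state.setdefault(
                (item.species_group, item.state), []
            ).append(item)
            self._by_species.setdefault(item.species_group, []).append(item)


@dataclass(slots=True)
class MatchResult:
    donor: FoodItem
    state_relaxed: bool


def match_candidate(item: FoodItem, source: FallbackSource) -> MatchResult | None:
    """Find the donor for ``item`` in ``source``, or ``None``.

    Exact (species_group, state) match is preferred; a species-only match is
    returned flagged ``state_relaxed``.  Absence is a valid result.
    """
    exact = source._by_species_state.get((item.species_group, item.state))
    if exact:
        return MatchResult(donor=_best_donor(exact), state_relaxed=False)
    relaxed = source._by_species.get(item.species_group)
    if relaxed:
        return MatchResult(donor=_best_donor(relaxed), state_relaxed=True)
    return None


@dataclass
class ImputationReport:
    """Fill counts per (nutrient, source) and remaining unresolved cells."""

    fills: dict[tuple[str, str], int] = field(default_factory=dict)
    unresolved: list[tuple[str, str]] = field(default_factory=list)  # (item_id, nutrient)
    state_relaxed_items: set[str] = field(default_factory=set)

    def record_fill(self, nutrient: str, source: str) -> None:
        key = (nutrient, source)
        self.fills[key] = self.fills.get(key, 0) + 1

    @property
    def total_fills(self) -> int:
        return sum(self.fills.values())

    def to_frame(self) -> pd.DataFrame:
        unresolved_by_nutrient: dict[str, int] = {}
        for _, nutrient in self.unresolved:
            unresolved_by_nutrient[nutrient] = unresolved_by_nutrient.get(nutrient, 0) + 1
        rows = [
            {"nutrient": n, "source": s, "fills": c, "unresolved": ""}
            for (n, s), c in sorted(self.fills.items())
        ]
        rows += [
            {"nutrient": n, "source": "", "fills": "", "unresolved": c}
            for n, c in sorted(unresolved_by_nutrient.items())
        ]
        return pd.DataFrame(rows, columns=["nutrient", "source", "fills", "unresolved"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _validate_sources(sources: Sequence[FallbackSource]) -> list[FallbackSource]:
    ordered = sorted(sources, key=lambda s: s.priority)
    priorities = [s.priority for s in ordered]
    if priorities != list(range(1, len(ordered) + 1)):
        raise ValueError(
            f"fallback priorities must be unique and contiguous from 1, got {priorities}"
        )
    return ordered


def impute_dataset(
    items: Iterable[FoodItem], sources: Sequence[FallbackSource]
) -> tuple[list[FoodItem], ImputationReport]:
    """Fill missing nutrients from the fallback cascade.

    Non-missing primary values are never overwritten.  Each missing field is
    filled from the first source (by priority) whose matched donor has it
    non-missing; provenance is set to ``fallback_<priority>``.  Fields missing
    everywhere stay missing with provenance ``unresolved``.  Idempotent.
    """
    ordered = _validate_sources(sources)
    report = ImputationReport()
    out: list[FoodItem] = []
    for item in items:
        filled = item.copy()
        missing = filled.nutrients.missing()
        if not missing:
            out.append(filled)
            continue
        matches = []
        for source in ordered:
            match = match_candidate(filled, source)
            if match is not None:
                matches.append((source, match))
                if match.state_relaxed:
                    report.state_relaxed_items.add(filled.item_id)
        for nutrient in missing:
            for source, match in matches:
                value = getattr(match.donor.nutrients, nutrient)
                if value is not None:
                    setattr(filled.nutrients, nutrient, value)
                    tag = f"fallback_{source.priority}"
                    filled.provenance[nutrient] = tag
                    report.record_fill(nutrient, source.name)
                    break
            else:
                report.unresolved.append((filled.item_id, nutrient))
        out.append(filled)
    return out, report
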