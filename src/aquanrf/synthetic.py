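"""Synthetic composition datasets and price tables from group-moment configs.

Each group draws nutrient amounts independently per item from a configured
family (zero-truncated normal by default, log-normal selectable for
high-CV nutrients), assigns species labels round-robin within its taxon
group so price joins are exercised, and applies requested missingness after
drawing.  Identical seeds give identical output.

Truncation note: the truncated-normal family is parametrized by the *parent*
mean/SD, so the realized mean exceeds the configured one when SD/mean is
large; :func:`expected_moments` returns the truncation-adjusted values that
moment-recovery checks should use.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import stats as sps

from .impute import FallbackSource
from .model import (
    NUTRIENTS,
    SPECIES_TO_TAXON,
    TAXON_GROUPS,
    FoodItem,
    NutrientVector,
    PriceRecord,
)

__all__ = [
    "NutrientMoment",
    "GroupMomentSpec",
    "PriceRow",
    "GeneratorConfig",
    "load_generator_config",
    "default_config_path",
    "farmed_wild_config_path",
    "expected_moments",
    "sample_group",
    "generate_dataset",
    "generate_price_table",
    "generate_reference_source",
]

_DATA_DIR = Path(__file__).parent / "data"

FAMILIES = ("truncnorm", "lognormal")


class NutrientMoment(BaseModel):
    """Target (mean, SD) for one nutrient, with family and missingness."""

    mean: float = Field(ge=0)
    sd: float = Field(ge=0)
    family: Literal["truncnorm", "lognormal"] = "truncnorm"
    missing_rate: float = Field(default=0.0, ge=0.0, lt=1.0)


class GroupMomentSpec(BaseModel):
    """One synthetic group: label, size, mixtures, per-nutrient moments."""

    label: str
    taxon_group: str
    n: int = Field(ge=1)
    habitat: dict[str, float] = Field(default_factory=lambda: {"unknown": 1.0})
    state: dict[str, float] = Field(default_factory=lambda: {"raw": 1.0})
    salinity: dict[str, float] = Field(default_factory=lambda: {"unknown": 1.0})
    nutrients: dict[str, NutrientMoment]

    @field_validator("taxon_group")
    @classmethod
    def _known_taxon(cls, v: str) -> str:
        if v not in TAXON_GROUPS:
            raise ValueError(f"unknown taxon_group {v!r}")
        return v

    @field_validator("nutrients")
    @classmethod
    def _known_nutrients(cls, v: Mapping[str, NutrientMoment]):
        unknown = set(v) - set(NUTRIENTS)
        if unknown:
            raise ValueError(f"unknown nutrients {sorted(unknown)}")
        return v

    @model_validator(mode="after")
    def _mixtures_sum_to_one(self):
        for name in ("habitat", "state", "salinity"):
            weights = getattr(self, name)
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{name} mixture weights sum to {total}, not 1")
        return self

    @property
    def species_cycle(self) -> tuple[str, ...]:
        return tuple(
            sorted(s for s, t in SPECIES_TO_TAXON.items() if t == self.taxon_group)
        )


class PriceRow(BaseModel):
    species_group: str
    price_per_kg: float | None = Field(default=None, gt=0)
    currency: Literal["EUR", "USD"] = "USD"
    yield_fraction: float | None = Field(default=None, gt=0, le=1)


class GeneratorConfig(BaseModel):
    """Declarative generator input: group moments, prices, seed."""

    seed: int
    groups: list[GroupMomentSpec]
    prices: list[PriceRow] = Field(default_factory=list)

    @model_validator(mode="after")
    def _unique_labels(self):
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        return self


def default_config_path() -> Path:
    """Shipped config transcribing the published group moments and prices."""
    return _DATA_DIR / "group_moments.yaml"


def farmed_wild_config_path() -> Path:
    """Shipped two-group farmed/wild finfish contrast config."""
    return _DATA_DIR / "farmed_wild_moments.yaml"


def load_generator_config(path: str | Path | None = None) -> GeneratorConfig:
    raw = yaml.safe_load(Path(path or default_config_path()).read_text())
    return GeneratorConfig.model_validate(raw)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def expected_moments(moment: NutrientMoment) -> tuple[float, float]:
    """(mean, SD) actually targeted by the draw, adjusting for truncation.

    For the log-normal family the configured moments are matched exactly; for
    the zero-truncated normal they are the truncated-distribution moments of
    the parent N(mean, sd).
    """
    if moment.sd == 0:
        return moment.mean, 0.0
    if moment.family == "lognormal":
        return moment.mean, moment.sd
    a = (0.0 - moment.mean) / moment.sd
    mean, var = sps.truncnorm.stats(a, np.inf, loc=moment.mean, scale=moment.sd)
    return float(mean), float(np.sqrt(var))


def truncation_bias(moment: NutrientMoment) -> float:
    """Relative upward bias of the realized mean caused by truncation at 0."""
    if moment.mean == 0:
        return 0.0
    adjusted, _ = expected_moments(moment)
    return adjusted / moment.mean - 1.0


def _draw(moment: NutrientMoment, n: int, rng: np.random.Generator) -> np.ndarray:
    if moment.sd == 0:
        return np.full(n, moment.mean)
    if moment.family == "truncnorm":
        a = (0.0 - moment.mean) / moment.sd
        return sps.truncnorm.rvs(
            a, np.inf, loc=moment.mean, scale=moment.sd, size=n, random_state=rng
        )
    # log-normal matching the configured mean and SD exactly
    m, s = moment.mean, moment.sd
    if m <= 0:
        raise ValueError("lognormal family requires mean > 0")
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def _choose(
    weights: Mapping[str, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    labels = sorted(weights)
    p = np.array([weights[k] for k in labels], dtype=float)
    return rng.choice(labels, size=n, p=p / p.sum())


def sample_group(
    spec: GroupMomentSpec, rng: np.random.Generator, n: int | None = None
) -> pd.DataFrame:
    """Draw ``n`` (default ``spec.n``) items for one group as a DataFrame.

    Saturated fat and omega-3 are clipped to total fat when all three are
    drawn, to keep vectors physically consistent; this slightly biases those
    two means downward in fatty groups (see tests for tolerances).
    """
    n = spec.n if n is None else n
    columns: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for nutrient in NUTRIENTS:
        moment = spec.nutrients.get(nutrient)
        if moment is None:
            columns[nutrient] = np.full(n, np.nan)
            continue
        values = _draw(moment, n, rng)
        if moment.missing_rate > 0:
            masks[nutrient] = rng.random(n) < moment.missing_rate
        columns[nutrient] = values
    if "total_fat" in spec.nutrients:
        for part in ("saturated_fat", "omega3"):
            if part in spec.nutrients:
                columns[part] = np.minimum(columns[part], columns["total_fat"])
    for nutrient, mask in masks.items():
        columns[nutrient] = columns[nutrient].copy()
        columns[nutrient][mask] = np.nan
    df = pd.DataFrame(columns)
    species = spec.species_cycle
    df["species_group"] = [species[i % len(species)] for i in range(n)]
    df["state"] = _choose(spec.state, n, rng)
    df["habitat"] = _choose(spec.habitat, n, rng)
    df["salinity"] = _choose(spec.salinity, n, rng)
    df["group_label"] = spec.label
    return df


def _frame_to_items(df: pd.DataFrame, id_prefix: str) -> list[FoodItem]:
    items = []
    nutrient_values = {n: df[n].to_numpy() for n in NUTRIENTS}
    for i in range(len(df)):
        amounts = {
            n: (None if np.isnan(v[i]) else float(v[i]))
            for n, v in nutrient_values.items()
        }
        items.append(
            FoodItem(
                item_id=f"{id_prefix}-{i:06d}",
                species_group=df["species_group"].iat[i],
                state=df["state"].iat[i],
                habitat=df["habitat"].iat[i],
                salinity=df["salinity"].iat[i],
                nutrients=NutrientVector(**amounts),
            )
        )
    return items


def generate_dataset(
    config: GeneratorConfig, seed: int | None = None
) -> list[FoodItem]:
    """Generate exactly ``spec.n`` items per configured group.

    ``seed`` overrides the config's seed.  Same seed, same output.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    items: list[FoodItem] = []
    for spec in config.groups:
        df = sample_group(spec, rng)
        items.extend(_frame_to_items(df, id_prefix=spec.label))
    return items


def generate_price_table(config: GeneratorConfig) -> list[PriceRecord]:
    """Deterministic transcription of the config's price rows."""
    return [
        PriceRecord(
            species_group=row.species_group,
            price_per_kg=row.price_per_kg,
            currency=row.currency,
            yield_fraction=row.yield_fraction,
        )
        for row in config.prices
    ]


def generate_reference_source(
    config: GeneratorConfig, name: str = "reference_means", priority: int = 1
) -> FallbackSource:
    """A complete deterministic donor table built from the configured means.

    One donor item per (species_group, state) covered by each group's
    mixtures, with every configured nutrient set to its group mean; usable as
    a fallback source so the end-to-end pipeline has no unresolved cells.
    """
    donors: list[FoodItem] = []
    seen: set[tuple[str, str]] = set()
    for spec in config.groups:
        amounts = {n: m.mean for n, m in spec.nutrients.items()}
        total_fat = amounts.get("total_fat")
        if total_fat is not None:
            for part in ("saturated_fat", "omega3"):
                if part in amounts:
                    amounts[part] = min(amounts[part], total_fat)
        for species in spec.species_cycle:
            for state in sorted(spec.state):
                key = (species, state)
                if key in seen:
                    continue
                seen.add(key)
                donors.append(
                    FoodItem(
                        item_id=f"{name}-{species}-{state}",
                        species_group=species,
                        state=state,
                        nutrients=NutrientVector(**amounts),
                    )
                )
    return FallbackSource(name=name, priority=priority, items=donors)
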