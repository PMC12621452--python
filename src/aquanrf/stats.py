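"""Group comparisons: one-way ANOVA, Tukey HSD with compact letter display,
and the two-group wild-versus-farmed contrast.

The decomposition is classical (pooled within-group variance); Tukey adjusted
p-values come from the studentized-range distribution with the Tukey–Kramer
correction for unequal group sizes.  Letters follow the insert-and-absorb
algorithm, processing groups by descending mean (ties by label).
"""

from __future__ import annotations

import itertools
import math
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import NUTRIENTS, FoodItem

__all__ = [
    "AnovaResult",
    "TukeyPair",
    "TukeyResult",
    "WildFarmedComparison",
    "one_way_anova",
    "tukey_hsd",
    "compact_letters",
    "compare_wild_farmed",
    "extract_metric",
]


@dataclass(slots=True)
class AnovaResult:
    metric: str
    groups: tuple[str, ...]
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float


@dataclass(slots=True)
class TukeyPair:
    group_a: str
    group_b: str
    mean_difference: float  # mean_a − mean_b
    p_adjusted: float
    significant: bool


@dataclass(slots=True)
class TukeyResult:
    metric: str
    alpha: float
    pairs: list[TukeyPair]
    letters: dict[str, str]

    def pair(self, a: str, b: str) -> TukeyPair:
        for p in self.pairs:
            if {p.group_a, p.group_b} == {a, b}:
                return p
        raise KeyError(f"no pair ({a!r}, {b!r})")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_a": p.group_a,
                    "group_b": p.group_b,
                    "mean_difference": p.mean_difference,
                    "p_adjusted": p.p_adjusted,
                    "significant": p.significant,
                }
                for p in self.pairs
            ]
        )


def _check_samples(samples: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {}
    for label, values in samples.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
        arrays[label] = arr
    return arrays


def one_way_anova(
    samples: Mapping[str, Sequence[float]], metric: str = ""
) -> AnovaResult:
    """Classical one-way ANOVA (SSB/SSW decomposition, F-distribution p)."""
    arrays = _check_samples(samples)
    all_values = np.concatenate(list(arrays.values()))
    grand_mean = all_values.mean()
    k = len(arrays)
    n_total = all_values.size
    ssb = sum(a.size * (a.mean() - grand_mean) ** 2 for a in arrays.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_between = k - 1
    df_within = n_total - k
    msb = ssb / df_between
    msw = ssw / df_within
    if msw == 0.0:
        f_stat = 0.0 if msb == 0.0 else math.inf
        p = 1.0 if msb == 0.0 else 0.0
    else:
        f_stat = msb / msw
        p = float(sps.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        metric=metric,
        groups=tuple(arrays),
        f_statistic=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        ss_between=float(ssb),
        ss_within=float(ssw),
    )


def compact_letters(
    groups_by_mean: Sequence[str], significant_pairs: Iterable[tuple[str, str]]
) -> dict[str, str]:
    """Assign compact-display letters by insert-and-absorb.

    ``groups_by_mean`` must already be ordered (descending mean, ties by
    label).  Groups sharing a letter are not significantly different.
    """
    sig = {frozenset(p) for p in significant_pairs}
    columns: list[set[str]] = [set(groups_by_mean)]
    for a, b in sorted(sig, key=lambda fs: sorted(fs)):
        pair = tuple(sorted(frozenset((a, b))))
        for col in list(columns):
            if pair[0] in col and pair[1] in col:
                left = col - {pair[0]}
                right = col - {pair[1]}
                columns.remove(col)
                for new in (left, right):
                    # absorb: drop duplicates and subsets of existing columns
                    if not any(new <= other for other in columns):
                        columns = [c for c in columns if not c < new]
                        columns.append(new)
    order = {g: i for i, g in enumerate(groups_by_mean)}
    columns.sort(key=lambda col: min(order[g] for g in col))
    alphabet = string.ascii_lowercase
    letters: dict[str, list[str]] = {g: [] for g in groups_by_mean}
    for i, col in enumerate(columns):
        letter = alphabet[i % 26] * (1 + i // 26)
        for g in col:
            letters[g].append(letter)
    return {g: "".join(sorted(ls)) for g, ls in letters.items()}


def tukey_hsd(
    samples: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    metric: str = "",
) -> TukeyResult:
    """All-pairs Tukey(–Kramer) HSD with compact letter display.

    Uses the studentized-range distribution with the pooled within-group
    variance from the one-way ANOVA.
    """
    arrays = _check_samples(samples)
    anova = one_way_anova(samples, metric=metric)
    msw = anova.ss_within / anova.df_within
    k = len(arrays)
    pairs: list[TukeyPair] = []
    for a, b in itertools.combinations(arrays, 2):
        xa, xb = arrays[a], arrays[b]
        diff = float(xa.mean() - xb.mean())
        se = math.sqrt(msw / 2.0 * (1.0 / xa.size + 1.0 / xb.size))
        if se == 0.0:
            p_adj = 1.0 if diff == 0.0 else 0.0
        else:
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, anova.df_within))
            p_adj = min(max(p_adj, 0.0), 1.0)
        pairs.append(
            TukeyPair(
                group_a=a,
                group_b=b,
                mean_difference=diff,
                p_adjusted=p_adj,
                significant=p_adj < alpha,
            )
        )
    ordered = sorted(arrays, key=lambda g: (-arrays[g].mean(), g))
    letters = compact_letters(
        ordered, [(p.group_a, p.group_b) for p in pairs if p.significant]
    )
    return TukeyResult(metric=metric, alpha=alpha, pairs=pairs, letters=letters)


# ---------------------------------------------------------------------------
# Wild versus farmed
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class WildFarmedComparison:
    """Pooled-variance two-sample comparison of one metric, wild vs farmed."""

    metric: str
    n_farmed: int
    n_wild: int
    mean_farmed: float
    mean_wild: float
    sd_farmed: float
    sd_wild: float
    mean_difference: float  # wild − farmed
    t_statistic: float
    df: int
    p_value: float
    ratio_metrics: dict[str, float] = field(default_factory=dict)


def extract_metric(item: FoodItem, metric: str) -> float | None:
    """Per-item metric value: a nutrient name or ``omega3_total_fat_ratio``."""
    if metric == "omega3_total_fat_ratio":
        omega3 = item.nutrients.omega3
        fat = item.nutrients.total_fat
        if omega3 is None or fat is None or fat == 0:
            return None
        return omega3 / fat
    if metric in NUTRIENTS:
        return item.nutrients.get(metric)
    raise KeyError(f"unknown metric {metric!r}")


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    nx, ny = x.size, y.size
    df = nx + ny - 2
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / df
    if sp2 == 0.0:
        return (0.0, df, 1.0) if x.mean() == y.mean() else (math.inf, df, 0.0)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), df, p


def compare_wild_farmed(
    items: Iterable[FoodItem], metric: str
) -> WildFarmedComparison:
    """Two-group pooled-variance t comparison of wild vs farmed items.

    Equivalent to a 2-group one-way ANOVA (F = t²).  Also reports the
    omega-3 : total-fat ratio of group means for each habitat.
    """
    items = list(items)
    by_habitat: dict[str, list[FoodItem]] = {"farmed": [], "wild": []}
    for item in items:
        if item.habitat in by_habitat:
            by_habitat[item.habitat].append(item)
    for habitat, members in by_habitat.items():
        if len(members) < 2:
            raise ValueError(f"habitat group {habitat!r} absent or too small")

    def values(members: list[FoodItem]) -> np.ndarray:
        vals = [extract_metric(it, metric) for it in members]
        return np.asarray([v for v in vals if v is not None], dtype=float)

    farmed = values(by_habitat["farmed"])
    wild = values(by_habitat["wild"])
    if farmed.size < 2 or wild.size < 2:
        raise ValueError(f"metric {metric!r}: too few non-missing values per habitat")
    t, df, p = _pooled_t(wild, farmed)

    ratios: dict[str, float] = {}
    for habitat, members in by_habitat.items():
        omega3 = values_of(members, "omega3")
        fat = values_of(members, "total_fat")
        if omega3.size and fat.size and fat.mean() != 0:
            ratios[f"omega3_total_fat_ratio_{habitat}"] = float(
                omega3.mean() / fat.mean()
            )
    return WildFarmedComparison(
        metric=metric,
        n_farmed=int(farmed.size),
        n_wild=int(wild.size),
        mean_farmed=float(farmed.mean()),
        mean_wild=float(wild.mean()),
        sd_farmed=float(farmed.std(ddof=1)),
        sd_wild=float(wild.std(ddof=1)),
        mean_difference=float(wild.mean() - farmed.mean()),
        t_statistic=t,
        df=df,
        p_value=p,
        ratio_metrics=ratios,
    )


def values_of(members: Sequence[FoodItem], nutrient: str) -> np.ndarray:
    vals = [it.nutrients.get(nutrient) for it in members]
    return np.asarray([v for v in vals if v is not None], dtype=float)


def summary_strings(
    samples: Mapping[str, Sequence[float]], tukey: TukeyResult, decimals: int = 2
) -> dict[str, str]:
    """Report-style ``mean^letters (SD)`` strings per group."""
    out = {}
    for group, values in samples.items():
        arr = np.asarray(list(values), dtype=float)
        out[group] = (
            f"{arr.mean():.{decimals}f}^{tukey.letters[group]}"
            f" ({arr.std(ddof=1):.{decimals}f})"
        )
    return out
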