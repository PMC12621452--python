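"""Published group-level summary statistics shipped with the package.

These are the printed group means/SDs/Ns for the NRF6.2 and NRF9.2 scores
and for protein, usable as inputs to the affordability stage (the published
affordability table was computed from group mean scores, not re-derivable
from item-level data).
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .scoring import GroupScoreSummary

__all__ = ["reference_scores_path", "load_reference_summaries", "reference_protein_means"]

_CSV = Path(__file__).parent / "data" / "reference_group_scores.csv"


def reference_scores_path() -> Path:
    return _CSV


def load_reference_summaries(
    metrics: tuple[str, ...] = ("NRF6.2", "NRF9.2"),
) -> list[GroupScoreSummary]:
    """Published per-group score summaries as :class:`GroupScoreSummary`.

    SEM is recomputed as SD/√N where the SD is published, otherwise taken
    from the published SEM column.
    """
    df = pd.read_csv(_CSV)
    out = []
    for row in df.itertuples(index=False):
        if row.metric not in metrics:
            continue
        n = int(row.n)
        sd = float(row.sd) if not pd.isna(row.sd) else float("nan")
        sem = (
            sd / math.sqrt(n)
            if not math.isnan(sd)
            else (float(row.sem_published) if not pd.isna(row.sem_published) else float("nan"))
        )
        out.append(
            GroupScoreSummary(
                group=str(row.group),
                metric=str(row.metric),
                n=n,
                mean=float(row.mean),
                sd=sd,
                sem=sem,
            )
        )
    return out


def reference_protein_means() -> dict[str, float]:
    """Published mean protein (g/100 g) by taxon group."""
    df = pd.read_csv(_CSV)
    sub = df[df["metric"] == "protein"]
    return {str(r.group): float(r.mean) for r in sub.itertuples(index=False)}
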