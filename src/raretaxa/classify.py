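"""Abundance-based rarity classification of OTUs.

Every OTU is assigned to exactly one of six categories from the minimum (m)
and maximum (M) of its relative abundance across samples, with an abundant
cutoff of 1% and a rare cutoff of 0.01% by default:

==========  =============================================================
AAT         always abundant: m >= abundant_cut
CAT         conditionally abundant: m >= rare_cut and M >= abundant_cut
MT          moderate: rare_cut <= m and M < abundant_cut
CRAT        conditionally rare and abundant: m < rare_cut, M >= abundant_cut
CRT         conditionally rare: m < rare_cut, rare_cut <= M < abundant_cut
ART         always rare: M < rare_cut
==========  =============================================================

The comparison aggregates are AT = AAT u CAT (abundant taxa), RT = ART u CRT
(rare taxa), with MT and CRAT kept separate.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io import OtuTable

CATEGORIES = ["AAT", "CAT", "MT", "CRAT", "CRT", "ART"]
AGGREGATES = ["AT", "RT", "MT", "CRAT"]

_CATEGORY_TO_AGGREGATE = {
    "AAT": "AT", "CAT": "AT", "ART": "RT", "CRT": "RT", "MT": "MT", "CRAT": "CRAT",
}


@dataclass
class RarityClassification:
    """Per-OTU category and aggregate labels plus the thresholds used."""

    category: pd.Series  # OTU -> one of CATEGORIES
    abundant_cut: float
    rare_cut: float

    @property
    def aggregate(self) -> pd.Series:
        return self.category.map(_CATEGORY_TO_AGGREGATE)

    def members(self, aggregate: str) -> list[str]:
        if aggregate not in AGGREGATES:
            raise ValueError(f"unknown aggregate {aggregate!r}; expected one of {AGGREGATES}")
        agg = self.aggregate
        return list(agg.index[agg == aggregate])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"otu_id": self.category.index, "category": self.category.values,
             "aggregate": self.aggregate.values}
        )


def classify_otus(
    rel: pd.DataFrame,
    abundant_cut: float = 0.01,
    rare_cut: float = 0.0001,
) -> RarityClassification:
    """Classify OTUs from a relative-abundance table (samples x OTUs).

    Thresholds are proportions: 0.01 = 1%, 0.0001 = 0.01%.  Abundant is a
    closed bound (>= cut), rare an open one (< cut).
    """
    if rel.shape[0] == 0 or rel.shape[1] == 0:
        raise ValueError("cannot classify an empty table")
    if not rare_cut < abundant_cut:
        raise ValueError("rare_cut must be below abundant_cut")
    m = rel.min(axis=0).to_numpy()
    M = rel.max(axis=0).to_numpy()
    cat = np.where(
        m >= rare_cut,
        np.where(m >= abundant_cut, "AAT",
                 np.where(M >= abundant_cut, "CAT", "MT")),
        np.where(M >= abundant_cut, "CRAT",
                 np.where(M >= rare_cut, "CRT", "ART")),
    )
    return RarityClassification(
        pd.Series(cat, index=rel.columns, name="category"),
        abundant_cut=abundant_cut, rare_cut=rare_cut,
    )


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to two decimals."""
    if total == 0:
        return 0.0
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def summarize(classification: RarityClassification) -> pd.DataFrame:
    """Category/aggregate counts and percentages of total OTUs.

    Returns a frame indexed by label (six categories then four aggregates)
    with ``count`` and ``percent`` columns; percentages are 100 x count/total
    rounded half-up to 2 decimals, so rows and percentage cells reproduce a
    classification summary table directly.
    """
    total = len(classification.category)
    counts = classification.category.value_counts()
    agg_counts = classification.aggregate.value_counts()
    rows = []
    for label in CATEGORIES:
        c = int(counts.get(label, 0))
        rows.append((label, "category", c, _pct(c, total)))
    for label in AGGREGATES:
        c = int(agg_counts.get(label, 0))
        rows.append((label, "aggregate", c, _pct(c, total)))
    out = pd.DataFrame(rows, columns=["label", "level", "count", "percent"])
    return out.set_index("label")


def summarize_counts(counts_by_label: dict[str, int]) -> pd.DataFrame:
    """Percentage summary from pre-tabulated label counts.

    Useful for checking the arithmetic of published summary tables: the
    total is the sum of the given counts and each percentage is
    100 x count/total rounded half-up to 2 decimals.
    """
    total = sum(counts_by_label.values())
    rows = [(lab, c, _pct(c, total)) for lab, c in counts_by_label.items()]
    out = pd.DataFrame(rows, columns=["label", "count", "percent"])
    return out.set_index("label")


def subcommunity_table(
    table: OtuTable, classification: RarityClassification, aggregate: str
) -> OtuTable:
    """Column-subset of ``table`` containing only OTUs of one aggregate
    (AT, RT, MT or CRAT); all samples are retained."""
    members = classification.members(aggregate)
    return table.subset_otus(members)
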