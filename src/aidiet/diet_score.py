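"""Anti-inflammatory diet score from food-frequency questionnaire responses.

The score counts, over 11 anti-inflammatory items, how many a subject consumes
at a "high" level. Eight items are recorded on a seven-point frequency scale
(never ... daily) and three are yes/no culinary habits. The score therefore
ranges 0-11; higher means better adherence to an anti-inflammatory diet.

Published tercile cut-points (from the controls' distribution of the original
study) are low: score <= 5, medium: 6-7, high: >= 8.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyCategory",
    "FFQRecord",
    "DietScore",
    "ScoreCutpoints",
    "Tercile",
    "FREQUENCY_ITEMS",
    "BINARY_ITEMS",
    "SCORED_ITEMS",
    "ITEM_MIN_LEVEL",
    "PUBLISHED_CUTPOINTS",
    "item_indicator",
    "compute_score",
    "categorize_score",
    "control_tercile_cutpoints",
    "score_dataframe",
]


class FrequencyCategory(enum.IntEnum):
    """Seven-point consumption frequency scale."""

    NEVER = 0
    LESS_THAN_MONTHLY = 1
    LESS_THAN_WEEKLY = 2
    WEEKLY_1_2 = 3
    WEEKLY_3_4 = 4
    WEEKLY_5_7 = 5
    DAILY = 6


class Tercile(str, enum.Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


#: Frequency-scale items and the minimum scale level that counts as "high"
#: consumption: green leafy vegetables and salad at >= 3 times/week, citrus
#: fruits and other vegetables at >= 5 times/week, fruits in general and
#: coffee daily or more, nuts and n-3-rich fish weekly and more.
ITEM_MIN_LEVEL: dict[str, int] = {
    "green_leafy_vegetables": int(FrequencyCategory.WEEKLY_3_4),
    "salad": int(FrequencyCategory.WEEKLY_3_4),
    "vegetables_general": int(FrequencyCategory.WEEKLY_5_7),
    "citrus_fruits": int(FrequencyCategory.WEEKLY_5_7),
    "fruits_general": int(FrequencyCategory.DAILY),
    "coffee": int(FrequencyCategory.DAILY),
    "nuts": int(FrequencyCategory.WEEKLY_1_2),
    "fish_n3": int(FrequencyCategory.WEEKLY_1_2),
}

FREQUENCY_ITEMS: tuple[str, ...] = tuple(ITEM_MIN_LEVEL)
BINARY_ITEMS: tuple[str, ...] = ("olive_oil_exclusive", "fresh_rosemary", "fresh_salvia")
SCORED_ITEMS: tuple[str, ...] = FREQUENCY_ITEMS + BINARY_ITEMS

#: Column names used in subject CSV files, in scored-item order.
CSV_COLUMNS: dict[str, str] = {
    "green_leafy_vegetables": "green_leafy",
    "salad": "salad",
    "vegetables_general": "veg_general",
    "citrus_fruits": "citrus",
    "fruits_general": "fruits",
    "nuts": "nuts",
    "coffee": "coffee",
    "fish_n3": "fish_n3",
    "olive_oil_exclusive": "olive_oil",
    "fresh_rosemary": "rosemary",
    "fresh_salvia": "salvia",
}


@dataclass(frozen=True)
class ScoreCutpoints:
    """Upper bounds of the low and medium score categories."""

    low_max: int
    medium_max: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not self.low_max < self.medium_max:
            raise ValueError(
                f"cut-points must satisfy low_max < medium_max, got "
                f"({self.low_max}, {self.medium_max})"
            )


#: Cut-points of the original study: low <= 5, medium 6-7, high >= 8.
PUBLISHED_CUTPOINTS = ScoreCutpoints(low_max=5, medium_max=7)


@dataclass(frozen=True)
class FFQRecord:
    """One subject's responses for the 11 scored items.

    Frequency items hold a level 0-6 (or None for missing); binary habits
    hold True/False (or None). Foods outside the 11 anti-inflammatory items
    score 0 by definition and are not stored.
    """

    green_leafy_vegetables: int | None = None
    salad: int | None = None
    vegetables_general: int | None = None
    citrus_fruits: int | None = None
    fruits_general: int | None = None
    nuts: int | None = None
    coffee: int | None = None
    fish_n3: int | None = None
    olive_oil_exclusive: bool | None = None
    fresh_rosemary: bool | None = None
    fresh_salvia: bool | None = None

    def __post_init__(self) -> None:
        for item in FREQUENCY_ITEMS:
            v = getattr(self, item)
            if v is not None and int(v) not in range(7):
                raise ValueError(f"{item}: frequency level must be in 0..6, got {v!r}")

    def response(self, item: str):
        if item not in SCORED_ITEMS:
            raise KeyError(f"unknown scored item: {item!r}")
        return getattr(self, item)


@dataclass(frozen=True)
class DietScore:
    score: int
    tercile: Tercile
    n_missing_items: int = 0


def item_indicator(item: str, response) -> int:
    """1 if *response* meets the item's high-consumption threshold, else 0.

    Raises KeyError for an unknown item and TypeError when the response kind
    does not match the item kind (frequency level vs yes/no).
    """
    if item in ITEM_MIN_LEVEL:
        if isinstance(response, bool):
            raise TypeError(f"{item} expects a frequency level 0..6, got a yes/no value")
        level = int(response)
        if level not in range(7):
            raise ValueError(f"{item}: frequency level must be in 0..6, got {response!r}")
        return int(level >= ITEM_MIN_LEVEL[item])
    if item in BINARY_ITEMS:
        if not isinstance(response, (bool, np.bool_)) and response not in (0, 1):
            raise TypeError(f"{item} expects yes/no, got {response!r}")
        return int(bool(response))
    raise KeyError(f"unknown scored item: {item!r}")


def compute_score(
    record: FFQRecord,
    missing_policy: str = "count_as_low",
    cutpoints: ScoreCutpoints = PUBLISHED_CUTPOINTS,
) -> DietScore:
    """Sum the 11 item indicators and attach the tercile category.

    missing_policy="count_as_low" scores a missing item 0 and counts it in
    ``n_missing_items``; "strict" raises on any missing item.
    """
    if missing_policy not in ("count_as_low", "strict"):
        raise ValueError(f"unknown missing_policy: {missing_policy!r}")
    total = 0
    n_missing = 0
    for item in SCORED_ITEMS:
        response = record.response(item)
        if response is None or (isinstance(response, float) and np.isnan(response)):
            if missing_policy == "strict":
                raise ValueError(f"missing response for item {item!r} under strict policy")
            n_missing += 1
            continue
        total += item_indicator(item, response)
    return DietScore(
        score=total,
        tercile=categorize_score(total, cutpoints),
        n_missing_items=n_missing,
    )


def categorize_score(score: int, cutpoints: ScoreCutpoints = PUBLISHED_CUTPOINTS) -> Tercile:
    """Map a score 0-11 onto the low/medium/high category."""
    s = int(score)
    if not 0 <= s <= 11:
        raise ValueError(f"score must be in 0..11, got {score!r}")
    if s <= cutpoints.low_max:
        return Tercile.LOW
    if s <= cutpoints.medium_max:
        return Tercile.MEDIUM
    return Tercile.HIGH


def control_tercile_cutpoints(control_scores: Sequence[int]) -> ScoreCutpoints:
    """Empirical tercile cut-points of the controls' score distribution.

    low_max is the smallest integer whose empirical CDF reaches 1/3 and
    medium_max the smallest reaching 2/3; categorize_score's <= rule then
    assigns boundary ties. If the two coincide (no usable variation) the
    result is flagged degenerate.
    """
    scores = np.asarray(list(control_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("control_scores must be non-empty")
    if np.any((scores < 0) | (scores > 11)):
        raise ValueError("control scores must lie in 0..11")
    n = scores.size
    cdf = np.array([(scores <= s).sum() / n for s in range(12)])
    low_max = int(np.argmax(cdf >= 1 / 3))
    medium_max = int(np.argmax(cdf >= 2 / 3))
    if low_max >= medium_max:
        return ScoreCutpoints(low_max=low_max, medium_max=low_max, degenerate=True)
    return ScoreCutpoints(low_max=low_max, medium_max=medium_max)


def score_dataframe(
    df: pd.DataFrame,
    missing_policy: str = "count_as_low",
    cutpoints: ScoreCutpoints = PUBLISHED_CUTPOINTS,
) -> pd.DataFrame:
    """Score every row of a subject table.

    Expects the CSV column names (``green_leafy,salad,veg_general,citrus,
    fruits,nuts,coffee,fish_n3`` coded 0-6 and ``olive_oil,rosemary,salvia``
    coded 0/1; empty = missing) and returns a copy with ``diet_score``,
    ``diet_tercile`` and ``diet_n_missing`` columns appended.
    """
    if missing_policy not in ("count_as_low", "strict"):
        raise ValueError(f"unknown missing_policy: {missing_policy!r}")
    missing_cols = [c for c in CSV_COLUMNS.values() if c not in df.columns]
    if missing_cols:
        raise KeyError(f"subject table lacks FFQ columns: {missing_cols}")
    out = df.copy()
    total = np.zeros(len(df), dtype=int)
    n_missing = np.zeros(len(df), dtype=int)
    for item, col in CSV_COLUMNS.items():
        values = pd.to_numeric(df[col], errors="raise")
        missing = values.isna().to_numpy()
        if missing.any() and missing_policy == "strict":
            raise ValueError(f"missing response for item {item!r} under strict policy")
        n_missing += missing.astype(int)
        filled = values.fillna(0).to_numpy()
        if item in BINARY_ITEMS:
            if not np.isin(filled, (0, 1)).all():
                raise ValueError(f"{item}: yes/no column must be coded 0/1")
            hit = filled == 1
        else:
            if np.any((filled < 0) | (filled > 6)):
                raise ValueError(f"{item}: frequency levels must be in 0..6")
            hit = filled >= ITEM_MIN_LEVEL[item]
        total += np.where(missing, 0, hit.astype(int))
    out["diet_score"] = total
    out["diet_tercile"] = pd.Categorical(
        [categorize_score(s, cutpoints).value for s in total],
        categories=["low", "medium", "high"],
    )
    out["diet_n_missing"] = n_missing
    return out
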