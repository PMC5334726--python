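"""Health-instrument scoring and nature-dose encoding.

Five self-report health measures are scored here:

* depression — the 7 depression items of the DASS-21, each rated 0..3,
  summed and doubled (the short-form convention), then dichotomised at a
  severity cutoff ("mild or worse");
* self-rated general health — a single 5-point ordinal item, passed through
  unchanged;
* social cohesion — three subscales (trust, reciprocal exchange, community
  cohesion) each averaged over 0..4 items and the three means summed, giving
  a 0–12 scale;
* exercise days — a 0..7 count, passed through unchanged;
* nature relatedness — Likert items with reverse-keyed items reflected about
  the scale midpoint, then averaged.

The three nature-dose variables are encoded from survey categories to a
numeric scale using category mid-points: frequency of garden visits in
visits/week, total garden time in minutes/week, and neighbourhood vegetation
cover in percent (computed elsewhere, see :mod:`naturedose.vegetation`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "DepressionScore",
    "CohesionScore",
    "NatureRelatednessScore",
    "FREQUENCY_CATEGORIES",
    "FREQUENCY_ENCODING",
    "DURATION_CATEGORIES",
    "DURATION_ENCODING",
    "DASS_MILD_CUTOFF",
    "score_depression_binary",
    "score_social_cohesion",
    "score_nature_relatedness",
    "encode_frequency",
    "encode_duration_midpoint",
]

#: Doubled-score DASS depression threshold for "mild or worse".  The
#: conventional banding puts normal at 0–9 and mild at 10–13, so the binary
#: indicator trips at a doubled score of 10.  Configurable per call.
DASS_MILD_CUTOFF = 10

#: Garden-visit frequency categories, in increasing order, and their
#: visits/week mid-point encodings.
FREQUENCY_CATEGORIES = (
    "never",
    "<once",
    "once",
    "2-3 days",
    "4-5 days",
    "6-7 days",
)
FREQUENCY_ENCODING: Mapping[str, float] = {
    "never": 0.0,
    "<once": 0.5,
    "once": 1.0,
    "2-3 days": 2.5,
    "4-5 days": 4.5,
    "6-7 days": 6.5,
}

#: Weekly garden-time categories and their minutes/week mid-points.  The open
#: top category has no mid-point; the default value 570 min extends the top
#: bound (540 = 9 h) by half the preceding category's width (60 min).
DURATION_CATEGORIES = (
    "no time",
    "1-30 min",
    ">30 min-1 h",
    ">1-3 h",
    ">3-5 h",
    ">5-7 h",
    ">7-9 h",
    "9+ h",
)
DURATION_ENCODING: Mapping[str, float] = {
    "no time": 0.0,
    "1-30 min": 15.5,
    ">30 min-1 h": 45.0,
    ">1-3 h": 120.0,
    ">3-5 h": 240.0,
    ">5-7 h": 360.0,
    ">7-9 h": 480.0,
    "9+ h": 570.0,
}


@dataclass(frozen=True)
class DepressionScore:
    """Doubled DASS depression subscale sum and its binary severity flag."""

    raw_subscale_sum: int
    binary: int

    def __post_init__(self) -> None:
        if self.binary not in (0, 1):
            raise ValueError(f"binary must be 0 or 1, got {self.binary}")
        if self.raw_subscale_sum % 2 or not 0 <= self.raw_subscale_sum <= 42:
            raise ValueError(
                f"raw doubled score must be even and in [0, 42], got {self.raw_subscale_sum}"
            )


@dataclass(frozen=True)
class CohesionScore:
    """Three subscale means (each 0–4) and their 0–12 sum."""

    subscale_means: tuple[float, float, float]
    total: float


@dataclass(frozen=True)
class NatureRelatednessScore:
    """Mean of (reverse-keyed where flagged) nature-relatedness items."""

    value: float


def score_depression_binary(
    items: Sequence[int], cutoff: int = DASS_MILD_CUTOFF
) -> DepressionScore:
    """Score the 7 DASS depression items into a binary depression indicator.

    Parameters
    ----------
    items
        Exactly 7 integer responses, each in 0..3.
    cutoff
        Doubled-score threshold at or above which the binary flag is 1.

    Returns
    -------
    DepressionScore
        ``raw_subscale_sum`` is twice the item sum (range 0–42);
        ``binary`` is 1 iff the doubled sum is >= ``cutoff``.
    """
    if len(items) != 7:
        raise ValueError(f"expected 7 depression items, got {len(items)}")
    for v in items:
        if not (isinstance(v, (int,)) or float(v).is_integer()) or not 0 <= v <= 3:
            raise ValueError(f"depression items must be integers in 0..3, got {v!r}")
    raw = 2 * int(sum(items))
    return DepressionScore(raw_subscale_sum=raw, binary=int(raw >= cutoff))


def score_social_cohesion(
    subscale_item_lists: Sequence[Sequence[float]],
) -> CohesionScore:
    """Sum of per-subscale item means for the three cohesion subscales.

    Each subscale's items are rated 0..4; the subscale score is the item
    mean and the total is the sum of the three means (0–12).
    """
    if len(subscale_item_lists) != 3:
        raise ValueError(
            f"expected 3 cohesion subscales, got {len(subscale_item_lists)}"
        )
    means = []
    for idx, items in enumerate(subscale_item_lists):
        if len(items) == 0:
            raise ValueError(f"cohesion subscale {idx} has no items")
        for v in items:
            if not 0 <= v <= 4:
                raise ValueError(f"cohesion items must lie in 0..4, got {v!r}")
        means.append(sum(items) / len(items))
    return CohesionScore(subscale_means=tuple(means), total=sum(means))


def score_nature_relatedness(
    items: Sequence[float],
    reverse_flags: Sequence[bool],
    scale_min: float = 1.0,
    scale_max: float = 5.0,
) -> NatureRelatednessScore:
    """Mean nature-relatedness score with reverse-keyed items reflected.

    Reverse-flagged items are reflected about the scale midpoint
    (``scale_min + scale_max - item``) before averaging, so a higher score
    always indicates a stronger orientation towards nature.
    """
    if len(items) != len(reverse_flags):
        raise ValueError(
            f"{len(items)} items but {len(reverse_flags)} reverse flags"
        )
    if not items:
        raise ValueError("no nature-relatedness items supplied")
    for v in items:
        if not scale_min <= v <= scale_max:
            raise ValueError(
                f"item {v!r} outside scale [{scale_min}, {scale_max}]"
            )
    adjusted = [
        (scale_min + scale_max - v) if flip else float(v)
        for v, flip in zip(items, reverse_flags)
    ]
    return NatureRelatednessScore(value=sum(adjusted) / len(adjusted))


def encode_frequency(
    category: str, table: Mapping[str, float] = FREQUENCY_ENCODING
) -> float:
    """Encode a garden-visit frequency category as visits/week (mid-point)."""
    try:
        return table[category]
    except KeyError:
        raise ValueError(
            f"unknown frequency category {category!r}; expected one of {sorted(table)}"
        ) from None


def encode_duration_midpoint(
    category: str, table: Mapping[str, float] = DURATION_ENCODING
) -> float:
    """Encode a weekly garden-time category as minutes/week (mid-point)."""
    try:
        return table[category]
    except KeyError:
        raise ValueError(
            f"unknown duration category {category!r}; expected one of {sorted(table)}"
        ) from None
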