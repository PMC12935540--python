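"""Dietary macronutrient balance of rotation outputs.

Calorie shares use the standard Atwater energy densities — carbohydrate and
protein 4 kcal per gram, fat 9 kcal per gram — applied to the macronutrient
output masses (the factors cancel units, so any consistent mass unit works).
Shares are compared against the recommended adult intake ranges of 45-65%
of calories from carbohydrates, 10-35% from proteins and 20-35% from fats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Atwater energy densities, kcal per gram of macronutrient.
ATWATER = {"carbohydrate": 4.0, "protein": 4.0, "fat": 9.0}


@dataclass(frozen=True)
class DietShare:
    """Fractions of total calories from each macronutrient (sum to 1)."""

    carb_share: float
    protein_share: float
    fat_share: float

    def as_dict(self) -> dict:
        return {
            "carbohydrate": self.carb_share,
            "protein": self.protein_share,
            "fat": self.fat_share,
        }


@dataclass(frozen=True)
class RecommendedRange:
    """Closed-interval recommended calorie-share ranges per macronutrient."""

    carb: tuple = (0.45, 0.65)
    protein: tuple = (0.10, 0.35)
    fat: tuple = (0.20, 0.35)

    def __post_init__(self):
        for lo, hi in (self.carb, self.protein, self.fat):
            if lo > hi:
                raise ValueError("range lower bound exceeds upper bound")


RECOMMENDED = RecommendedRange()


def calorie_shares(carb_out: float, protein_out: float, fat_out: float) -> DietShare:
    """Calorie shares of macronutrient output masses via Atwater factors."""
    masses = {"carbohydrate": carb_out, "protein": protein_out, "fat": fat_out}
    if any(m < 0 for m in masses.values()):
        raise ValueError("macronutrient outputs must be >= 0")
    energy = {n: m * ATWATER[n] for n, m in masses.items()}
    total = sum(energy.values())
    if total <= 0:
        raise ValueError("cannot compute calorie shares of an all-zero output")
    return DietShare(
        carb_share=energy["carbohydrate"] / total,
        protein_share=energy["protein"] / total,
        fat_share=energy["fat"] / total,
    )


def compare_recommendation(
    share: DietShare, ranges: RecommendedRange = RECOMMENDED
) -> dict:
    """Per-macronutrient verdict: "within", "below" or "above" the range.

    Containment is on closed intervals: a share exactly on a bound is within.
    """

    def verdict(value, bounds):
        lo, hi = bounds
        if value < lo:
            return "below"
        if value > hi:
            return "above"
        return "within"

    return {
        "carbohydrate": verdict(share.carb_share, ranges.carb),
        "protein": verdict(share.protein_share, ranges.protein),
        "fat": verdict(share.fat_share, ranges.fat),
    }


def percent_change(new_value: float, reference_value: float) -> int:
    """Integer percent change of ``new_value`` relative to ``reference_value``.

    Rounded half away from zero, matching how integer percents are usually
    reported.  ``reference_value`` must be positive.
    """
    if reference_value <= 0:
        raise ValueError("reference_value must be > 0")
    x = 100.0 * (new_value - reference_value) / reference_value
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))
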