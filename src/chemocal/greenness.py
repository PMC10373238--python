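"""Analytical eco-scale greenness scoring.

The analytical eco-scale starts from an ideal score of 100 and subtracts
penalty points assigned to each procedure parameter deviating from green
ideals (reagent amounts and hazards, energy, occupational exposure, waste).
Scores above 75 rate "excellent", 50-75 "acceptable", below 50 "inadequate".
Penalty itemization is user-supplied configuration; the example items below
reconstruct plausible totals for a UV spectrophotometric assay with ethanol
as solvent and are documentation, not measured data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = ["PenaltyItem", "EcoScaleAssessment", "eco_scale", "EXAMPLE_PENALTIES"]


@dataclass(frozen=True)
class PenaltyItem:
    label: str
    points: int

    def __post_init__(self) -> None:
        if not isinstance(self.points, int) or isinstance(self.points, bool):
            raise ValueError(f"penalty points must be integers, got {self.points!r}")
        if self.points < 0:
            raise ValueError(f"penalty points must be >= 0, got {self.points}")


@dataclass
class EcoScaleAssessment:
    items: list[PenaltyItem]
    total_penalty: int
    score: int
    category: str


def _categorize(score: int) -> str:
    if score > 75:
        return "excellent"
    if score >= 50:
        return "acceptable"
    return "inadequate"


def eco_scale(
    penalties: Sequence[PenaltyItem] | Mapping[str, int],
) -> EcoScaleAssessment:
    """Score = 100 - sum of penalty points, with the standard categories."""
    if isinstance(penalties, Mapping):
        items = [PenaltyItem(str(k), int(v)) for k, v in penalties.items()]
        for (k, v), item in zip(penalties.items(), items):
            if v != item.points or (isinstance(v, float) and not float(v).is_integer()):
                raise ValueError(f"penalty {k!r} must be a non-negative integer")
    else:
        items = list(penalties)
    for item in items:
        if item.points < 0:
            raise ValueError(f"penalty {item.label!r} is negative")
    total = sum(item.points for item in items)
    score = 100 - total
    return EcoScaleAssessment(
        items=items, total_penalty=total, score=score, category=_categorize(score)
    )


# Example itemizations (documentation): plausible reconstructions of
# UV-assay penalty totals 21 / 19 / 22 for the three calibration workflows.
EXAMPLE_PENALTIES: dict[str, dict[str, int]] = {
    "cls": {
        "ethanol >10 mL (amount 2 x hazard 2)": 8,
        "acetonitrile <10 mL (plasma prep)": 4,
        "occupational hazard": 3,
        "waste 1-10 mL untreated": 6,
    },
    "pcr": {
        "ethanol >10 mL (amount 2 x hazard 2)": 8,
        "acetonitrile <10 mL (plasma prep)": 4,
        "occupational hazard": 1,
        "waste 1-10 mL untreated": 6,
    },
    "pls": {
        "ethanol >10 mL (amount 2 x hazard 2)": 8,
        "acetonitrile <10 mL (plasma prep)": 4,
        "occupational hazard": 3,
        "waste 1-10 mL untreated": 6,
        "energy (software workstation)": 1,
    },
}
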