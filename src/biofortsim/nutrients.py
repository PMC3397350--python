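"""Per-subject nutrient computation from recall-style food quantities.

Daily zinc and energy are simple density sums over a composition table:
``intake = sum(grams/100 * density_per_100g)``. The rice contribution is
isolated because the biofortification simulator scales exactly that term.
The module also exposes the phytate:zinc molar ratio used to characterise
rice varieties (higher ratios inhibit zinc absorption).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import UndefinedRatioError, UnknownFoodError, ValidationError
from .model import RICE_ITEM, FoodCompositionEntry

#: Molar mass of phytic acid (C6H18O24P6), g/mol.
PHYTIC_ACID_MOLAR_MASS = 660.04

#: Molar mass of zinc, g/mol.
ZINC_MOLAR_MASS = 65.38


@dataclass(frozen=True)
class RecallLine:
    """One (subject, food) daily quantity — a 3-day mean from 24-h recalls."""

    subject_id: str
    food_item: str
    grams_per_day: float

    def __post_init__(self) -> None:
        if self.grams_per_day < 0:
            raise ValidationError(
                f"recall line ({self.subject_id}, {self.food_item}): "
                "grams_per_day must be non-negative"
            )


@dataclass(frozen=True)
class SubjectIntakes:
    subject_id: str
    zinc_total_mg_day: float
    zinc_rice_mg_day: float
    energy_kcal_day: float


def _density_maps(
    composition: Iterable[FoodCompositionEntry],
) -> tuple[Mapping[str, float], Mapping[str, float]]:
    zinc = {e.food_item: e.zinc_mg_per_100g for e in composition}
    energy = {e.food_item: e.energy_kcal_per_100g for e in composition}
    return zinc, energy


def compute_intakes(
    lines: Sequence[RecallLine],
    composition: Iterable[FoodCompositionEntry],
) -> list[SubjectIntakes]:
    """Sum recall lines against a composition table, per subject.

    Every food item must be present in the composition table; unknown items
    raise :class:`UnknownFoodError` listing all offenders rather than being
    silently dropped. Subjects appear in first-occurrence order; an empty
    line list yields an empty result.
    """
    zinc_density, energy_density = _density_maps(composition)
    unknown = [l.food_item for l in lines if l.food_item not in zinc_density]
    if unknown:
        raise UnknownFoodError(unknown)

    order: list[str] = []
    totals: dict[str, dict[str, float]] = {}
    for line in lines:
        if line.subject_id not in totals:
            order.append(line.subject_id)
            totals[line.subject_id] = {"zinc": 0.0, "rice": 0.0, "energy": 0.0}
        acc = totals[line.subject_id]
        hundred_g = line.grams_per_day / 100.0
        zinc = hundred_g * zinc_density[line.food_item]
        acc["zinc"] += zinc
        acc["energy"] += hundred_g * energy_density[line.food_item]
        if line.food_item == RICE_ITEM:
            acc["rice"] += zinc
    return [
        SubjectIntakes(sid, t["zinc"], t["rice"], t["energy"])
        for sid, t in ((s, totals[s]) for s in order)
    ]


def intakes_to_frame(intakes: Iterable[SubjectIntakes]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": i.subject_id,
                "zinc_total_mg_day": i.zinc_total_mg_day,
                "zinc_rice_mg_day": i.zinc_rice_mg_day,
                "energy_kcal_day": i.energy_kcal_day,
            }
            for i in intakes
        ]
    )


def phytate_zinc_molar_ratio(
    phytate_mg_per_100g: float, zinc_mg_per_100g: float
) -> float:
    """Moles of phytic acid per mole of zinc in a food.

    Computed as ``(phytate/660.04) / (zinc/65.38)`` with molar masses in
    g/mol; both densities must be per the same 100 g basis. Zero zinc makes
    the ratio undefined. Note: a mean of per-variety ratios is not the
    ratio of mean densities — callers averaging across varieties must pick
    the aggregation they mean.
    """
    if zinc_mg_per_100g <= 0:
        raise UndefinedRatioError("phytate:zinc ratio undefined for zero zinc")
    if phytate_mg_per_100g < 0:
        raise ValidationError("phytate density must be non-negative")
    return (phytate_mg_per_100g / PHYTIC_ACID_MOLAR_MASS) / (
        zinc_mg_per_100g / ZINC_MOLAR_MASS
    )
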