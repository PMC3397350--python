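"""Core domain types and file I/O for the zinc-biofortification pipeline.

The unit of analysis is the :class:`Subject`: one adult survey participant
with demographics, 3-day-mean daily intakes (energy, total zinc, zinc from
rice, rice grams) and weekly food-frequency-questionnaire (FFQ) intakes for
a canonical list of 25 food items. Cohorts are stored as plain CSV with one
header row; units are embedded in column names (``*_mg_day``, ``*_g_day``,
``ffq_g_wk__<food>``) to prevent unit confusion.

Two reference fixtures ship with the package:

* ``factor_loadings.json`` — the rotated factor-loading matrix of the four
  adult dietary patterns (traditional, macho, sweet tooth, healthy), with
  items retained only at ``|loading| >= 0.20``;
* ``dri_zinc_china.json`` — Chinese DRI zinc values (RNI, tolerable upper
  intake level) plus IZiNCG mixed-diet absorption fractions and
  absorbed-zinc inadequacy thresholds.

The canonical food list is the union of the loading-table items plus
cheese (which loads below threshold on every pattern). The original
questionnaire merged 33 foods into 25 items; the published table does not
enumerate the merged list, so this vocabulary is a documented assumption.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

#: Reserved food-item name identifying rice in compositions and recall lines.
RICE_ITEM = "rice"

#: Zinc density of normal (non-biofortified) polished rice, mg per 100 g.
NORMAL_RICE_ZINC_MG_PER_100G = 1.7

#: Canonical 25-item FFQ vocabulary: loading-table union plus cheese.
CANONICAL_FOODS: tuple[str, ...] = (
    "rice",
    "wheat_flour",
    "fresh_vegetables",
    "root_vegetable",
    "pickled_vegetables",
    "pork",
    "beef_lamb",
    "poultry",
    "liver",
    "fish",
    "eggs",
    "tofu",
    "whole_grains",
    "fruits",
    "juice",
    "milk",
    "yoghurt",
    "milk_powder",
    "cake",
    "nuts",
    "beer",
    "alcohol",
    "beverage",
    "deep_fried_products",
    "cheese",
)

SEXES = ("male", "female")
REGIONS = ("north", "south")
RESIDENCES = ("urban", "rural")
SES_LEVELS = ("low", "medium", "high")
EDUCATION_LEVELS = ("primary", "junior", "high")

PATTERNS = ("traditional", "macho", "sweet_tooth", "healthy")

FFQ_PREFIX = "ffq_g_wk__"

_SCALAR_COLUMNS = [
    "id",
    "sex",
    "age_years",
    "region",
    "residence",
    "ses",
    "education",
    "energy_kcal_day",
    "zinc_total_mg_day",
    "zinc_rice_mg_day",
    "rice_g_day",
]


@dataclass
class Subject:
    """One adult survey participant with derived daily intakes.

    Invariants enforced on construction: zinc from rice never exceeds total
    zinc; rice grams are zero exactly when zinc from rice is zero; age is at
    least 20 (the study population is adults aged 20 and above).
    """

    id: str
    sex: str
    age_years: int
    region: str
    residence: str
    ses: str
    education: str
    energy_kcal_day: float
    zinc_total_mg_day: float
    zinc_rice_mg_day: float
    rice_g_day: float
    ffq_weekly_g: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"subject {self.id}: sex must be one of {SEXES}")
        if self.region not in REGIONS:
            raise ValidationError(f"subject {self.id}: region must be one of {REGIONS}")
        if self.residence not in RESIDENCES:
            raise ValidationError(
                f"subject {self.id}: residence must be one of {RESIDENCES}"
            )
        if self.ses not in SES_LEVELS:
            raise ValidationError(f"subject {self.id}: ses must be one of {SES_LEVELS}")
        if self.education not in EDUCATION_LEVELS:
            raise ValidationError(
                f"subject {self.id}: education must be one of {EDUCATION_LEVELS}"
            )
        if self.age_years < 20:
            raise ValidationError(
                f"subject {self.id}: age_years must be >= 20 (adult study population)"
            )
        for name in ("energy_kcal_day", "zinc_total_mg_day", "zinc_rice_mg_day", "rice_g_day"):
            if getattr(self, name) < 0:
                raise ValidationError(f"subject {self.id}: {name} must be non-negative")
        if self.zinc_rice_mg_day > self.zinc_total_mg_day:
            raise ValidationError(
                f"subject {self.id}: zinc_rice_mg_day ({self.zinc_rice_mg_day}) "
                f"exceeds zinc_total_mg_day ({self.zinc_total_mg_day})"
            )
        if (self.rice_g_day == 0) != (self.zinc_rice_mg_day == 0):
            raise ValidationError(
                f"subject {self.id}: rice_g_day and zinc_rice_mg_day must be "
                "zero together (a rice consumer has positive zinc from rice)"
            )
        for food, grams in self.ffq_weekly_g.items():
            if grams < 0:
                raise ValidationError(
                    f"subject {self.id}: FFQ intake of {food} must be non-negative"
                )


@dataclass(frozen=True)
class FoodCompositionEntry:
    """Zinc and energy density of one food item, per 100 g edible portion."""

    food_item: str
    zinc_mg_per_100g: float
    energy_kcal_per_100g: float

    def __post_init__(self) -> None:
        if self.zinc_mg_per_100g < 0:
            raise ValidationError(f"{self.food_item}: zinc density must be >= 0")
        if self.energy_kcal_per_100g < 0:
            raise ValidationError(f"{self.food_item}: energy density must be >= 0")


@dataclass(frozen=True)
class Scenario:
    """A biofortification scenario: rice at a given zinc concentration.

    ``rice_zinc_mg_per_100g`` is the concentration in the scenario rice
    (c_new); ``baseline_rice_zinc_mg_per_100g`` is the concentration the
    observed intakes were computed with (c_old, normal rice = 1.7 mg/100 g).
    """

    name: str
    rice_zinc_mg_per_100g: float
    baseline_rice_zinc_mg_per_100g: float = NORMAL_RICE_ZINC_MG_PER_100G

    def __post_init__(self) -> None:
        if self.rice_zinc_mg_per_100g <= 0:
            raise ValidationError(f"scenario {self.name}: rice zinc must be > 0")
        if self.baseline_rice_zinc_mg_per_100g <= 0:
            raise ValidationError(f"scenario {self.name}: baseline rice zinc must be > 0")

    @property
    def concentration_ratio(self) -> float:
        return self.rice_zinc_mg_per_100g / self.baseline_rice_zinc_mg_per_100g


#: The published scenario set: normal rice plus the two breeding targets.
DEFAULT_SCENARIOS: tuple[Scenario, ...] = (
    Scenario("normal", 1.7),
    Scenario("intermediate", 2.7),
    Scenario("high", 3.8),
)


class FactorLoadingMatrix:
    """Food-item x dietary-pattern loading matrix, thresholded at |0.20|.

    A loading is the correlation-like weight of a food on a latent pattern;
    items with |loading| below ``inclusion_threshold`` are excluded from
    pattern scores and must not be stored.
    """

    def __init__(
        self,
        patterns: Sequence[str],
        loadings: Mapping[tuple[str, str], float],
        inclusion_threshold: float = 0.20,
    ) -> None:
        self.patterns = tuple(patterns)
        self.inclusion_threshold = float(inclusion_threshold)
        self.loadings: dict[tuple[str, str], float] = {}
        for (food, pattern), value in loadings.items():
            if pattern not in self.patterns:
                raise ValidationError(f"unknown pattern {pattern!r}")
            if not -1.0 <= value <= 1.0:
                raise ValidationError(
                    f"loading({food}, {pattern}) = {value} outside [-1, 1]"
                )
            if abs(value) < self.inclusion_threshold:
                raise ValidationError(
                    f"loading({food}, {pattern}) = {value} below the "
                    f"|{self.inclusion_threshold}| inclusion threshold"
                )
            self.loadings[(food, pattern)] = float(value)

    def loading(self, food: str, pattern: str) -> float:
        """Return the retained loading, or 0.0 if the item is excluded."""
        return self.loadings.get((food, pattern), 0.0)

    def foods_for(self, pattern: str) -> list[str]:
        """Food items with a retained loading on ``pattern``."""
        return [f for (f, p) in self.loadings if p == pattern]

    def foods(self) -> list[str]:
        """All food items appearing on at least one pattern."""
        return sorted({f for (f, _p) in self.loadings})

    def __len__(self) -> int:
        return len(self.loadings)


class DriTable:
    """Age/sex-specific zinc reference values and absorption parameters.

    RNI strata for males switch at age 50 (18-49 vs >=50) while the UL
    strata switch after 50 (20-50 vs >50); the one-year mismatch is in the
    published reference rules and is preserved deliberately.
    """

    def __init__(
        self,
        rni_rules: Mapping[str, Sequence[Mapping]],
        insufficiency_fraction: tuple[int, int],
        ul_rules: Mapping[str, Sequence[Mapping]],
        absorption_fraction: Mapping[str, float],
        absorbed_inadequacy_mg_day: Mapping[str, float],
    ) -> None:
        for sex in SEXES:
            for table, label in ((rni_rules, "rni_mg_day"), (ul_rules, "ul_mg_day")):
                if sex not in table:
                    raise SchemaError(f"DRI table: missing {sex} stratum in {label}")
            for table, label in (
                (absorption_fraction, "absorption_fraction"),
                (absorbed_inadequacy_mg_day, "absorbed_inadequacy_mg_day"),
            ):
                if sex not in table:
                    raise SchemaError(f"DRI table: missing {sex} stratum in {label}")
        self._rni = {s: list(rni_rules[s]) for s in SEXES}
        self._ul = {s: list(ul_rules[s]) for s in SEXES}
        num, den = insufficiency_fraction
        if num <= 0 or den <= 0:
            raise ValidationError("insufficiency fraction must be positive")
        self.insufficiency_numerator = int(num)
        self.insufficiency_denominator = int(den)
        self.absorption_fraction = {s: float(absorption_fraction[s]) for s in SEXES}
        self.absorbed_inadequacy_mg_day = {
            s: float(absorbed_inadequacy_mg_day[s]) for s in SEXES
        }
        for mapping in (
            self.absorption_fraction,
            self.absorbed_inadequacy_mg_day,
        ):
            if any(v <= 0 for v in mapping.values()):
                raise ValidationError("DRI parameters must be strictly positive")
        for rules in list(self._rni.values()) + list(self._ul.values()):
            if any(r["value"] <= 0 for r in rules):
                raise ValidationError("DRI reference values must be strictly positive")

    @staticmethod
    def _lookup(rules: Sequence[Mapping], sex: str, age: int, label: str) -> float:
        for rule in rules:
            lo = rule.get("age_min") or 0
            hi = rule.get("age_max")
            if age >= lo and (hi is None or age <= hi):
                return float(rule["value"])
        raise SchemaError(f"DRI table: no {label} rule covers {sex} age {age}")

    def rni(self, sex: str, age_years: int) -> float:
        """Recommended nutrient intake for zinc, mg/day."""
        self._check(sex, age_years)
        return self._lookup(self._rni[sex], sex, age_years, "RNI")

    def ul(self, sex: str, age_years: int) -> float:
        """Tolerable upper intake level for zinc, mg/day."""
        self._check(sex, age_years)
        return self._lookup(self._ul[sex], sex, age_years, "UL")

    def insufficiency_cutoff(self, sex: str, age_years: int) -> float:
        """The insufficiency cutoff: 2/3 of the age/sex RNI, mg/day."""
        return (
            self.rni(sex, age_years)
            * self.insufficiency_numerator
            / self.insufficiency_denominator
        )

    @staticmethod
    def _check(sex: str, age_years: int) -> None:
        if sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}")
        if age_years < 20:
            raise ValidationError("age outside the adult study population (>= 20)")


# ---------------------------------------------------------------------------
# Fixture loaders
# ---------------------------------------------------------------------------


def _packaged(name: str):
    return resources.files("biofortsim.data") / name


def load_loadings(path: str | Path | None = None) -> FactorLoadingMatrix:
    """Load a factor-loading matrix from JSON (packaged fixture by default)."""
    source = Path(path) if path is not None else _packaged("factor_loadings.json")
    raw = json.loads(source.read_text(encoding="utf-8"))
    try:
        patterns = raw["patterns"]
        threshold = raw.get("inclusion_threshold", 0.20)
        table = raw["loadings"]
    except KeyError as exc:
        raise SchemaError(f"loading fixture: missing key {exc}") from exc
    loadings = {
        (food, pattern): value
        for pattern, foods in table.items()
        for food, value in foods.items()
    }
    return FactorLoadingMatrix(patterns, loadings, threshold)


def load_dri(path: str | Path | None = None) -> DriTable:
    """Load a DRI table from JSON (packaged Chinese-DRI fixture by default)."""
    source = Path(path) if path is not None else _packaged("dri_zinc_china.json")
    raw = json.loads(source.read_text(encoding="utf-8"))
    try:
        frac = raw["insufficiency_fraction"]
        return DriTable(
            rni_rules=raw["rni_mg_day"],
            insufficiency_fraction=(frac["numerator"], frac["denominator"]),
            ul_rules=raw["ul_mg_day"],
            absorption_fraction=raw["absorption_fraction"],
            absorbed_inadequacy_mg_day=raw["absorbed_inadequacy_mg_day"],
        )
    except KeyError as exc:
        raise SchemaError(f"DRI fixture: missing key {exc}") from exc


def load_composition(path: str | Path | None = None) -> list[FoodCompositionEntry]:
    """Load a food-composition table (zinc and energy densities per 100 g).

    The packaged default is a synthetic stand-in assembled for the canonical
    25-item vocabulary: the rice entry carries the published normal-rice
    zinc density of 1.7 mg/100 g, the remaining densities are typical
    food-composition-table values. Pass a path to use a real table.
    """
    source = Path(path) if path is not None else _packaged("food_composition_synthetic.csv")
    frame = pd.read_csv(io.StringIO(source.read_text(encoding="utf-8")))
    required = {"food_item", "zinc_mg_per_100g", "energy_kcal_per_100g"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"composition table: missing columns {sorted(missing)}")
    return [
        FoodCompositionEntry(
            str(row.food_item),
            float(row.zinc_mg_per_100g),
            float(row.energy_kcal_per_100g),
        )
        for row in frame.itertuples()
    ]


# ---------------------------------------------------------------------------
# Cohort CSV I/O
# ---------------------------------------------------------------------------


def cohort_columns(foods: Sequence[str] = CANONICAL_FOODS) -> list[str]:
    """The cohort CSV column order: scalar fields then prefixed FFQ columns."""
    return _SCALAR_COLUMNS + [FFQ_PREFIX + f for f in foods]


def read_cohort(path: str | Path) -> list[Subject]:
    """Read a cohort CSV into validated :class:`Subject` records.

    Raises :class:`SchemaError` naming any missing column and
    :class:`ValidationError` citing the offending row id on invariant
    violations. Row order is preserved.
    """
    frame = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    expected = cohort_columns()
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise SchemaError(f"cohort CSV: missing columns {missing}")
    subjects: list[Subject] = []
    for row in frame.itertuples(index=False):
        record = row._asdict()
        ffq = {
            food: float(record[FFQ_PREFIX + food]) for food in CANONICAL_FOODS
        }
        subjects.append(
            Subject(
                id=str(record["id"]),
                sex=str(record["sex"]),
                age_years=int(record["age_years"]),
                region=str(record["region"]),
                residence=str(record["residence"]),
                ses=str(record["ses"]),
                education=str(record["education"]),
                energy_kcal_day=float(record["energy_kcal_day"]),
                zinc_total_mg_day=float(record["zinc_total_mg_day"]),
                zinc_rice_mg_day=float(record["zinc_rice_mg_day"]),
                rice_g_day=float(record["rice_g_day"]),
                ffq_weekly_g=ffq,
            )
        )
    return subjects


def cohort_to_frame(subjects: Iterable[Subject]) -> pd.DataFrame:
    """Flatten subjects into a DataFrame with the cohort CSV schema."""
    rows = []
    for s in subjects:
        row = {c: getattr(s, c) for c in _SCALAR_COLUMNS}
        for food in CANONICAL_FOODS:
            row[FFQ_PREFIX + food] = s.ffq_weekly_g.get(food, 0.0)
        rows.append(row)
    return pd.DataFrame(rows, columns=cohort_columns())


def write_cohort(subjects: Iterable[Subject], path: str | Path) -> None:
    """Write a cohort CSV (UTF-8, comma-separated, full float precision).

    Floats are written in Python's shortest round-trip representation, so
    ``write_cohort`` followed by :func:`read_cohort` reproduces the cohort
    exactly and identical cohorts produce byte-identical files.
    """
    columns = cohort_columns()
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(columns)
        for s in subjects:
            row = [getattr(s, c) for c in _SCALAR_COLUMNS]
            row += [s.ffq_weekly_g.get(f, 0.0) for f in CANONICAL_FOODS]
            writer.writerow(row)
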