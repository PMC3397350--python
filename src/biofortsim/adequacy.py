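"""Zinc intake adequacy classification.

Three rule systems, all age/sex specific, per the Chinese DRIs and IZiNCG:

* insufficiency — intake strictly below 2/3 of the RNI
  (10.0 mg/day for males 18-49, 23/3 ~= 7.667 mg/day otherwise);
* excess — intake strictly above the tolerable upper intake level
  (45 mg/day males 20-50, 37 mg/day otherwise);
* absorbed-zinc inadequacy — absorbed zinc (0.26 x intake for men,
  0.34 x intake for women, mixed diet) strictly below 2.69 / 1.86 mg/day.

Intake insufficiency and absorbed inadequacy are separate published rule
systems and do not coincide at their boundaries (0.26 x 10.0 = 2.60 <
2.69), so a subject can be adequate on one rule and inadequate on the
other; this is deliberate, not a bug.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError
from .model import DriTable, Subject


@dataclass(frozen=True)
class AdequacyResult:
    """Per-subject classification under one intake."""

    subject_id: str
    intake_mg_day: float
    cutoff_mg_day: float
    insufficient: bool
    excess: bool
    absorbed_mg_day: float
    absorbed_inadequate: bool


@dataclass(frozen=True)
class Prevalence:
    """A percentage with its exact (Clopper-Pearson) 95% interval."""

    pct: float
    count: int
    n: int
    ci_low_pct: float
    ci_high_pct: float


@dataclass(frozen=True)
class PrevalenceSummary:
    insufficiency: Prevalence
    excess: Prevalence
    absorbed_inadequacy: Prevalence


def insufficiency_cutoff(sex: str, age_years: int, dri: DriTable) -> float:
    """2/3 of the age/sex-specific RNI, mg/day."""
    return dri.insufficiency_cutoff(sex, age_years)


def absorbed_zinc(intake_mg_day: float, sex: str, dri: DriTable) -> float:
    """Absorbed zinc: sex-specific fractional absorption times intake."""
    if intake_mg_day < 0:
        raise ValidationError("intake must be non-negative")
    return dri.absorption_fraction[sex] * intake_mg_day


def classify(
    intake_mg_day: float,
    sex: str,
    age_years: int,
    dri: DriTable,
    subject_id: str = "",
) -> AdequacyResult:
    """Classify one intake under all three rule systems.

    Inequalities are strict on both sides: insufficient means intake
    *below* the cutoff, excess means intake *above* the UL.
    """
    if intake_mg_day < 0:
        raise ValidationError("intake must be non-negative")
    cutoff = dri.insufficiency_cutoff(sex, age_years)
    ul = dri.ul(sex, age_years)
    absorbed = absorbed_zinc(intake_mg_day, sex, dri)
    return AdequacyResult(
        subject_id=subject_id,
        intake_mg_day=float(intake_mg_day),
        cutoff_mg_day=cutoff,
        insufficient=intake_mg_day < cutoff,
        excess=intake_mg_day > ul,
        absorbed_mg_day=absorbed,
        absorbed_inadequate=absorbed < dri.absorbed_inadequacy_mg_day[sex],
    )


def classify_cohort(
    intakes_mg_day: Sequence[float],
    cohort: Sequence[Subject],
    dri: DriTable,
) -> list[AdequacyResult]:
    """Classify every subject at the given (possibly scenario) intakes."""
    if len(intakes_mg_day) != len(cohort):
        raise ValidationError("intakes and cohort lengths differ")
    return [
        classify(float(x), s.sex, s.age_years, dri, subject_id=s.id)
        for x, s in zip(intakes_mg_day, cohort)
    ]


def _prevalence_of(flags: np.ndarray) -> Prevalence:
    n = flags.size
    count = int(flags.sum())
    low, high = proportion_confint(count, n, alpha=0.05, method="beta")
    return Prevalence(
        pct=100.0 * count / n,
        count=count,
        n=n,
        ci_low_pct=100.0 * float(low),
        ci_high_pct=100.0 * float(high),
    )


def prevalence(results: Iterable[AdequacyResult]) -> PrevalenceSummary:
    """Population prevalences (%) with exact binomial 95% intervals."""
    results = list(results)
    if not results:
        raise ValidationError("prevalence requires a non-empty result list")
    insufficient = np.array([r.insufficient for r in results])
    excess = np.array([r.excess for r in results])
    absorbed = np.array([r.absorbed_inadequate for r in results])
    return PrevalenceSummary(
        insufficiency=_prevalence_of(insufficient),
        excess=_prevalence_of(excess),
        absorbed_inadequacy=_prevalence_of(absorbed),
    )
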