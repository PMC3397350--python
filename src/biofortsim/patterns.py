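"""Dietary-pattern scores and quartile assignment.

A subject's score on a pattern is the loading-weighted sum of standardized
weekly FFQ intakes over the foods retained for that pattern
(``S_ik = sum_j L_jk * z_ij`` with ``|L_jk| >= 0.20``). Standardization is
cohort-wide per food (sample SD, n-1 denominator), so scores are invariant
to adding a constant to any food's raw intake. Quartiles are rank-based
population fourths: Q1 holds the lowest scores, Q4 the highest, group sizes
differ by at most one, and ties keep original input order (stable sort) so
results are reproducible bit for bit.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import FFQ_PREFIX, FactorLoadingMatrix, Subject

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


def ffq_frame(cohort: Iterable[Subject]) -> pd.DataFrame:
    """Weekly FFQ grams as a subjects x foods DataFrame (index = subject id)."""
    rows = {s.id: s.ffq_weekly_g for s in cohort}
    frame = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    frame.index.name = "subject_id"
    return frame


def standardize_ffq(cohort: Iterable[Subject] | pd.DataFrame) -> pd.DataFrame:
    """Cohort-wide z-scores of weekly intake, per food item.

    Uses the sample SD (n-1 denominator). A zero-variance food cannot be
    standardized; its z-scores are set to 0 for every subject and a warning
    is emitted, which matches dropping the food from every pattern score.
    """
    frame = cohort if isinstance(cohort, pd.DataFrame) else ffq_frame(cohort)
    if len(frame) < 2:
        raise ValidationError("standardization requires at least 2 subjects")
    means = frame.mean(axis=0)
    sds = frame.std(axis=0, ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        warnings.warn(
            f"zero-variance food items set to z=0: {constant}", stacklevel=2
        )
    safe_sds = sds.replace(0.0, np.nan)
    z = (frame - means) / safe_sds
    return z.fillna(0.0)


def score_patterns(
    z: pd.DataFrame, loadings: FactorLoadingMatrix
) -> pd.DataFrame:
    """Pattern scores: loading-weighted sums of standardized intakes.

    ``z`` must cover every food with a retained loading; a missing food is
    an error rather than an implicit zero.
    """
    missing = [f for f in loadings.foods() if f not in z.columns]
    if missing:
        raise ValidationError(
            f"standardized intakes missing foods with retained loadings: {missing}"
        )
    scores = pd.DataFrame(0.0, index=z.index, columns=list(loadings.patterns))
    for (food, pattern), weight in loadings.loadings.items():
        scores[pattern] += weight * z[food]
    return scores


def assign_quartiles(scores: Sequence[float] | pd.Series) -> list[str]:
    """Rank-based quartile labels Q1 (lowest) .. Q4 (highest).

    Subjects are sorted ascending by score with a stable sort (ties keep
    input order) and split at ranks ceil(n/4), ceil(n/2), ceil(3n/4), so
    group sizes differ by at most one.
    """
    values = np.asarray(scores, dtype=float)
    n = len(values)
    if n < 4:
        raise ValidationError("quartile assignment requires at least 4 subjects")
    order = np.argsort(values, kind="stable")
    cuts = (math.ceil(n / 4), math.ceil(n / 2), math.ceil(3 * n / 4))
    labels = np.empty(n, dtype=object)
    for rank, idx in enumerate(order):
        if rank < cuts[0]:
            labels[idx] = "Q1"
        elif rank < cuts[1]:
            labels[idx] = "Q2"
        elif rank < cuts[2]:
            labels[idx] = "Q3"
        else:
            labels[idx] = "Q4"
    return labels.tolist()


def score_cohort(
    cohort: Iterable[Subject], loadings: FactorLoadingMatrix
) -> pd.DataFrame:
    """Convenience: FFQ -> z-scores -> pattern scores -> quartiles.

    Returns a DataFrame indexed by subject id with one ``<pattern>`` score
    column and one ``<pattern>_quartile`` label column per pattern.
    """
    subjects = list(cohort)
    z = standardize_ffq(subjects)
    scores = score_patterns(z, loadings)
    for pattern in loadings.patterns:
        scores[pattern + "_quartile"] = assign_quartiles(scores[pattern])
    return scores


def strip_prefix(columns: Iterable[str]) -> list[str]:
    """Map cohort-CSV FFQ column names back to food names."""
    return [c[len(FFQ_PREFIX):] if c.startswith(FFQ_PREFIX) else c for c in columns]
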