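"""Result-table assembly: population scenario summaries and
quartile-stratified reports, with paired-comparison and trend statistics.

Two report shapes are produced:

* :func:`scenario_summary` — one column per rice-zinc concentration with
  mean +/- SD zinc from rice, rice's share of total zinc (both the mean of
  per-subject shares and the ratio of means), prevalence of insufficient
  and excess intake, mean +/- SD absorbed zinc and absorbed-inadequacy
  prevalence; each biofortified column is compared with baseline by a
  paired t-test (intakes) and a chi-square test (prevalences).
* :func:`quartile_report` — per dietary pattern, Q1..Q4 rows of mean (SD)
  energy, rice grams and zinc intake per scenario plus insufficiency
  prevalence, with trend statistics down the quartiles: covariate-adjusted
  OLS on the quartile index for continuous outcomes and a Cochran-Armitage
  score test for prevalences.

The original survey analysis additionally adjusted for household
clustering; synthetic cohorts have no household structure, so that term is
dropped and the simplification is stated in the rendered report header.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .adequacy import classify_cohort, prevalence
from .biofort import apply_scenario, rice_share_of_total
from .errors import ValidationError
from .model import DriTable, FactorLoadingMatrix, Scenario, Subject
from .patterns import QUARTILE_LABELS, assign_quartiles, score_patterns, standardize_ffq

HOUSEHOLD_NOTE = (
    "Trend regressions adjust for age, sex, region, residence, SES, "
    "education and energy intake; no household-clustering adjustment is "
    "applied (synthetic cohorts carry no household structure)."
)

#: Reference levels absorbed into the intercept of trend regressions.
REFERENCE_LEVELS = {
    "sex": "male",
    "region": "north",
    "residence": "urban",
    "ses": "low",
    "education": "primary",
}


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def paired_t(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """Classical paired t-test on the differences x - y, two-sided.

    Identical vectors give t = 0, p = 1 exactly; a nonzero constant
    difference (zero variance but nonzero mean) has no finite t and is an
    error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("paired_t needs two equal-length vectors, n >= 2")
    d = x - y
    if np.all(d == 0):
        return {"t": 0.0, "df": float(x.size - 1), "p": 1.0}
    if np.std(d, ddof=1) == 0:
        raise ValidationError("differences have zero variance but nonzero mean")
    res = stats.ttest_rel(x, y)
    return {"t": float(res.statistic), "df": float(x.size - 1), "p": float(res.pvalue)}


def chisq_2xk(counts) -> dict[str, float]:
    """Pearson chi-square test on a 2 x k contingency table (no continuity
    correction), df = k - 1. Zero expected cells are an error."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValidationError("chisq_2xk expects a 2 x k table")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise ValidationError("chi-square undefined: zero expected cell count")
    res = stats.chi2_contingency(table, correction=False)
    return {
        "statistic": float(res.statistic),
        "df": float(res.dof),
        "p": float(res.pvalue),
    }


def cochran_armitage_trend(
    cases: Sequence[float],
    totals: Sequence[float],
    scores: Sequence[float] | None = None,
) -> dict[str, float]:
    """Cochran-Armitage score test for a linear trend in proportions.

    ``cases[i]`` of ``totals[i]`` are positive in group i; ``scores``
    default to 1..k. Two-sided p from the normal reference distribution.
    """
    r = np.asarray(cases, dtype=float)
    m = np.asarray(totals, dtype=float)
    if r.shape != m.shape or np.any(r > m) or np.any(m <= 0):
        raise ValidationError("invalid case/total vectors for trend test")
    s = np.arange(1, r.size + 1, dtype=float) if scores is None else np.asarray(scores, float)
    n = m.sum()
    pbar = r.sum() / n
    if pbar in (0.0, 1.0):
        raise ValidationError("trend test undefined: all-positive or all-negative")
    t_stat = float(np.sum(s * (r - m * pbar)))
    var = pbar * (1 - pbar) * (np.sum(m * s**2) - np.sum(m * s) ** 2 / n)
    z = t_stat / np.sqrt(var)
    return {"z": float(z), "p": float(2 * stats.norm.sf(abs(z)))}


def covariates_from_cohort(cohort: Sequence[Subject]) -> pd.DataFrame:
    """The standard adjustment set as a DataFrame (one row per subject)."""
    return pd.DataFrame(
        {
            "age": [s.age_years for s in cohort],
            "sex": [s.sex for s in cohort],
            "region": [s.region for s in cohort],
            "residence": [s.residence for s in cohort],
            "ses": [s.ses for s in cohort],
            "education": [s.education for s in cohort],
            "energy": [s.energy_kcal_day for s in cohort],
        }
    )


def _design_matrix(
    quartile_index: np.ndarray, covariates: pd.DataFrame | None
) -> pd.DataFrame:
    design = pd.DataFrame({"const": 1.0, "quartile": quartile_index.astype(float)})
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        for col in covariates.columns:
            series = covariates[col]
            if series.dtype.kind in "ifu":
                design[col] = series.astype(float)
            else:
                ref = REFERENCE_LEVELS.get(col, sorted(series.unique())[0])
                for level in sorted(series.unique()):
                    if level == ref:
                        continue
                    design[f"{col}[{level}]"] = (series == level).astype(float)
    return design


def trend_regression(
    outcome: Sequence[float],
    quartile_index: Sequence[int],
    covariates: pd.DataFrame | None = None,
) -> dict[str, float]:
    """OLS of an outcome on the quartile index (1..4) with covariates.

    Categorical covariates are one-hot encoded against fixed reference
    levels (male / north / urban / low SES / primary education). The
    returned slope is the mean outcome change per quartile step; p is the
    two-sided t-test on that slope. A rank-deficient design is an error
    naming the aliased columns.
    """
    y = np.asarray(outcome, dtype=float)
    q = np.asarray(quartile_index, dtype=int)
    if not np.all((q >= 1) & (q <= 4)):
        raise ValidationError("quartile_index values must lie in 1..4")
    design = _design_matrix(q, covariates)
    if len(y) <= design.shape[1]:
        raise ValidationError("n must exceed the number of parameters")
    X = design.to_numpy()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, Rm = np.linalg.qr(X)
        diag = np.abs(np.diag(Rm))
        aliased = [design.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValidationError(f"rank-deficient design; aliased columns: {aliased}")
    fit = sm.OLS(y, design).fit()
    return {
        "slope": float(fit.params["quartile"]),
        "p": float(fit.pvalues["quartile"]),
        "se": float(fit.bse["quartile"]),
    }


# ---------------------------------------------------------------------------
# Population scenario summary
# ---------------------------------------------------------------------------


@dataclass
class ScenarioSummary:
    """Population summary per scenario plus baseline comparisons."""

    table: pd.DataFrame  # rows: metrics; columns: scenario names
    comparisons: pd.DataFrame  # per non-baseline scenario: t/chi2 stats
    baseline: str
    note: str = HOUSEHOLD_NOTE


def scenario_summary(
    cohort: Sequence[Subject],
    scenarios: Sequence[Scenario],
    dri: DriTable,
) -> ScenarioSummary:
    """Assemble the per-scenario population table.

    The first scenario is the baseline for paired t-tests on total zinc
    and chi-square tests on the two prevalence rows.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValidationError("cohort is empty")
    if not scenarios:
        raise ValidationError("at least one scenario (the baseline) required")

    columns: dict[str, dict[str, float]] = {}
    per_scenario = {}
    for scenario in scenarios:
        intakes = apply_scenario(cohort, scenario)
        share = rice_share_of_total(intakes)
        results = classify_cohort(intakes.zinc_total_new_mg_day, cohort, dri)
        prev = prevalence(results)
        absorbed = np.array([r.absorbed_mg_day for r in results])
        per_scenario[scenario.name] = (intakes, results)
        columns[scenario.name] = {
            "rice_zinc_concentration_mg_100g": scenario.rice_zinc_mg_per_100g,
            "zinc_from_rice_mean_mg_day": float(intakes.zinc_rice_new_mg_day.mean()),
            "zinc_from_rice_sd_mg_day": float(
                intakes.zinc_rice_new_mg_day.std(ddof=1)
            ),
            "zinc_total_mean_mg_day": float(intakes.zinc_total_new_mg_day.mean()),
            "zinc_total_sd_mg_day": float(intakes.zinc_total_new_mg_day.std(ddof=1)),
            "rice_share_mean_of_shares_pct": share.mean_of_shares_pct,
            "rice_share_ratio_of_means_pct": share.ratio_of_means_pct,
            "insufficiency_pct": prev.insufficiency.pct,
            "excess_pct": prev.excess.pct,
            "absorbed_zinc_mean_mg_day": float(absorbed.mean()),
            "absorbed_zinc_sd_mg_day": float(absorbed.std(ddof=1)),
            "absorbed_inadequacy_pct": prev.absorbed_inadequacy.pct,
        }

    baseline = scenarios[0].name
    base_intakes, base_results = per_scenario[baseline]
    comp_rows = []
    n = len(cohort)
    for scenario in scenarios[1:]:
        intakes, results = per_scenario[scenario.name]
        t_res = paired_t(
            intakes.zinc_total_new_mg_day, base_intakes.zinc_total_new_mg_day
        )
        row = {"scenario": scenario.name, "t_vs_baseline": t_res["t"],
               "t_p": t_res["p"]}
        for label, flag in (
            ("insufficiency", "insufficient"),
            ("absorbed_inadequacy", "absorbed_inadequate"),
        ):
            k_base = sum(getattr(r, flag) for r in base_results)
            k_new = sum(getattr(r, flag) for r in results)
            if 0 < k_base + k_new < 2 * n:
                chi = chisq_2xk([[k_base, n - k_base], [k_new, n - k_new]])
                row[f"{label}_chi2"] = chi["statistic"]
                row[f"{label}_chi2_p"] = chi["p"]
            else:  # degenerate: nothing to compare
                row[f"{label}_chi2"] = np.nan
                row[f"{label}_chi2_p"] = np.nan
        comp_rows.append(row)
    comparisons = pd.DataFrame(comp_rows).set_index("scenario") if comp_rows else (
        pd.DataFrame()
    )
    table = pd.DataFrame(columns)
    return ScenarioSummary(table=table, comparisons=comparisons, baseline=baseline)


# ---------------------------------------------------------------------------
# Quartile-stratified report
# ---------------------------------------------------------------------------


@dataclass
class QuartileReport:
    """Per-pattern quartile breakdown with trend statistics."""

    pattern: str
    table: pd.DataFrame  # rows Q1..Q4
    trend_p: dict[str, float]
    note: str = HOUSEHOLD_NOTE


def quartile_report(
    cohort: Sequence[Subject],
    loadings: FactorLoadingMatrix,
    scenarios: Sequence[Scenario],
    dri: DriTable,
    pattern: str,
) -> QuartileReport:
    """Quartile-stratified intakes and prevalences for one dietary pattern.

    Continuous trend columns use covariate-adjusted OLS on the quartile
    index (energy as outcome drops the energy covariate); prevalence trend
    columns use the Cochran-Armitage score test.
    """
    cohort = list(cohort)
    if pattern not in loadings.patterns:
        raise ValidationError(f"unknown pattern {pattern!r}")
    z = standardize_ffq(cohort)
    scores = score_patterns(z, loadings)[pattern]
    quartiles = np.array(assign_quartiles(scores))
    q_index = np.array([QUARTILE_LABELS.index(q) + 1 for q in quartiles])

    energy = np.array([s.energy_kcal_day for s in cohort])
    rice = np.array([s.rice_g_day for s in cohort])
    covs = covariates_from_cohort(cohort)

    rows = {}
    for label in QUARTILE_LABELS:
        mask = quartiles == label
        rows[label] = {
            "n": int(mask.sum()),
            "energy_kcal_mean": float(energy[mask].mean()),
            "energy_kcal_sd": float(energy[mask].std(ddof=1)),
            "rice_g_mean": float(rice[mask].mean()),
            "rice_g_sd": float(rice[mask].std(ddof=1)),
        }

    trend_p: dict[str, float] = {}
    trend_p["energy_kcal"] = trend_regression(
        energy, q_index, covs.drop(columns=["energy"])
    )["p"]
    trend_p["rice_g"] = trend_regression(rice, q_index, covs)["p"]

    for scenario in scenarios:
        intakes = apply_scenario(cohort, scenario)
        totals = intakes.zinc_total_new_mg_day
        results = classify_cohort(totals, cohort, dri)
        insufficient = np.array([r.insufficient for r in results])
        cases, sizes = [], []
        for label in QUARTILE_LABELS:
            mask = quartiles == label
            rows[label][f"zinc_mean_mg_day[{scenario.name}]"] = float(
                totals[mask].mean()
            )
            rows[label][f"zinc_sd_mg_day[{scenario.name}]"] = float(
                totals[mask].std(ddof=1)
            )
            rows[label][f"insufficiency_pct[{scenario.name}]"] = float(
                100.0 * insufficient[mask].mean()
            )
            cases.append(int(insufficient[mask].sum()))
            sizes.append(int(mask.sum()))
        trend_p[f"zinc_mg_day[{scenario.name}]"] = trend_regression(
            totals, q_index, covs
        )["p"]
        total_cases = sum(cases)
        if 0 < total_cases < sum(sizes):
            trend_p[f"insufficiency[{scenario.name}]"] = cochran_armitage_trend(
                cases, sizes
            )["p"]
        else:
            trend_p[f"insufficiency[{scenario.name}]"] = np.nan

    table = pd.DataFrame.from_dict(rows, orient="index").loc[list(QUARTILE_LABELS)]
    return QuartileReport(pattern=pattern, table=table, trend_p=trend_p)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _fmt(x: float, decimals: int = 1) -> str:
    return f"{x:.{decimals}f}"


def render_scenario_markdown(summary: ScenarioSummary) -> str:
    """Markdown rendering: means to 1 decimal with SD, percentages to 1 dp."""
    t = summary.table
    lines = ["# Population zinc intake by rice-zinc scenario", "", summary.note, ""]
    header = "| Quantity | " + " | ".join(t.columns) + " |"
    sep = "|" + "---|" * (len(t.columns) + 1)
    lines += [header, sep]

    def row(label, values):
        lines.append("| " + label + " | " + " | ".join(values) + " |")

    row("Zinc concentration in rice (mg/100 g)",
        [_fmt(t.loc["rice_zinc_concentration_mg_100g", c]) for c in t.columns])
    row("Zinc intake from rice (mg/day)",
        [f"{_fmt(t.loc['zinc_from_rice_mean_mg_day', c])} ± "
         f"{_fmt(t.loc['zinc_from_rice_sd_mg_day', c])}" for c in t.columns])
    row("% of total zinc intake (mean of shares)",
        [_fmt(t.loc["rice_share_mean_of_shares_pct", c]) for c in t.columns])
    row("% of total zinc intake (ratio of means)",
        [_fmt(t.loc["rice_share_ratio_of_means_pct", c]) for c in t.columns])
    row("% insufficiency of zinc intake",
        [_fmt(t.loc["insufficiency_pct", c]) for c in t.columns])
    row("% excess zinc intake",
        [_fmt(t.loc["excess_pct", c], 2) for c in t.columns])
    row("Absorbed zinc (mg/day)",
        [f"{_fmt(t.loc['absorbed_zinc_mean_mg_day', c])} ± "
         f"{_fmt(t.loc['absorbed_zinc_sd_mg_day', c])}" for c in t.columns])
    row("% absorbed zinc inadequacy",
        [_fmt(t.loc["absorbed_inadequacy_pct", c]) for c in t.columns])
    if len(summary.comparisons):
        lines += ["", "Comparisons vs baseline (" + summary.baseline + "):", ""]
        lines.append("```")
        lines.append(summary.comparisons.to_string())
        lines.append("```")
    return "\n".join(lines) + "\n"


def render_quartile_markdown(report: QuartileReport) -> str:
    lines = [
        f"# Quartile breakdown — {report.pattern} pattern",
        "",
        report.note,
        "",
        "```",
        report.table.round(2).to_string(),
        "```",
        "",
        "P for trend:",
        "",
    ]
    for key, p in report.trend_p.items():
        lines.append(f"- {key}: p = {p:.3g}")
    return "\n".join(lines) + "\n"
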