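# Methods

## Scope and data model

The package models one question: how would the distribution of dietary
zinc intake in an adult, rice-staple survey population change if normal
rice (1.7 mg zinc/100 g, raw polished) were replaced by biofortified rice
at a higher zinc density, and how does the change differ across dietary
patterns? The unit of analysis is a survey participant with 3-day-mean
daily intakes (energy, total zinc, zinc from rice, rice grams) and weekly
FFQ intakes over a canonical 25-item food list. Cohorts are plain CSV
with units in the column names; reference inputs (factor loadings, DRI
rules) are JSON fixtures packaged with the code.

The canonical food list is the union of the items carrying a retained
factor loading plus cheese, which loads below the |0.20| threshold on
every pattern. The original questionnaire merged 33 foods into 25 items
but the merged list was never published in full, so this vocabulary is an
assumption, documented here and in the fixture.

## Substitution model

Substitution scales each subject's *observed* zinc-from-rice by the
concentration ratio c_new/c_old rather than recomputing grams × density.
The two are not equivalent on real survey data: reported rice grams and
reported zinc-from-rice are typically inconsistent by a raw/cooked weight
conversion (the survey this emulates implies an effective density of
~1.64 mg/100 g against a nominal 1.7 at the reported grams). Scaling the
observed zinc term makes the substitution exact under whatever weight
convention produced the intakes, and gives three exact identities used as
tests: the per-subject increment of total zinc equals the increment of
rice zinc; increments are linear in (c_new − c_old); and the SD of rice
zinc scales by exactly c_new/c_old. Rice non-consumers are unchanged.
Scenarios are data (name + concentration), so dose–response sweeps beyond
the two published breeding targets (2.7 and 3.8 mg/100 g) are free.

A consequence worth knowing: the paired t statistic comparing any
scenario with baseline is identical across concentrations, because the
difference vector is proportional to the subjects' rice-zinc vector and
the t statistic is scale-invariant. The chi-square prevalence comparisons
do discriminate between scenarios.

## Adequacy rules

Insufficiency: intake strictly below 2/3 of the age/sex RNI
(15 mg/day for men 18–49, 11.5 otherwise; cutoffs 10.0 and 23/3). The
fraction is stored as the integer pair (2, 3) so the male cutoff computes
to exactly 10.0 in floating point. Excess: intake strictly above the UL
(45 mg/day for men 20–50, 37 otherwise). The RNI switches stratum at age
50 while the UL switches after 50; that one-year mismatch is in the
published rules and is preserved rather than harmonized. Absorbed zinc is
0.26 × intake (men) / 0.34 × intake (women), inadequate below 2.69 / 1.86
mg/day; these thresholds deliberately do not coincide with the intake
cutoffs (0.26 × 10.0 = 2.60 < 2.69), so the two classifications can
disagree near their boundaries. Prevalences carry exact Clopper–Pearson
95% intervals.

The share of total zinc contributed by rice is reported under both
aggregations — mean of per-subject shares and ratio of means — because
population summaries are quoted both ways and the two differ; neither is
privileged.

## Pattern scores and quartiles

Weekly FFQ intakes are standardized per food over the whole cohort
(sample SD, n−1 denominator; a zero-variance food is set to z = 0 with a
warning). Scores are loading-weighted sums over retained items only.
Quartiles are rank-based fourths: stable ascending sort, splits at ranks
⌈n/4⌉, ⌈n/2⌉, ⌈3n/4⌉, ties kept in input order. This was chosen over
interpolated percentile cut-points because it guarantees group sizes
differing by at most one (2819 → 705/705/705/704) and is reproducible bit
for bit. Standardization is applied to g/week as collected, before any
per-100 g conversion.

## Synthetic cohort generator

The generator is the package's stand-in for the unavailable survey
records; its defaults encode the published sample structure and are not
tuned per analysis.

* Demographics: sex Bernoulli(0.460); five age bands with the published
  margins (ages uniform within band, 60+ capped at 84); region, urban
  residence, SES and education drawn from the published margins (SES and
  education renormalised to sum to one, as the published margins leave a
  small unclassified remainder).
* Latent patterns: four independent standard-normal factors per subject,
  the natural analogue of an orthogonal factor decomposition.
* Rice: 5% non-consumers; positive intakes gamma-distributed
  (right-skewed, as intake data are) with positive-part mean 263.3 g/day —
  chosen so the overall mean including zeros is ≈250.1 — and SD 145.8,
  capped at 1500 g/day. The gamma variate is sampled through a Gaussian
  copula with correlation +0.5 to the traditional factor and −0.3 to the
  sweet-tooth factor, preserving the marginal exactly while giving the
  pattern–rice associations their observed signs (the survey itself never
  reported these correlations; their magnitudes are a modelling choice).
  Note the zero-inflated mixture has overall SD ≈153 g/day, slightly
  above the positive-part 145.8.
* Zinc: zinc-from-rice is grams × 1.7/100 exactly; non-rice zinc is a
  zero-truncated normal with mean 7.75 and SD 2.6 mg/day, derived
  analytically so total zinc ≈ 12.0 ± 3.7 and confirmed by the shipped
  pilot-run script (`scripts/calibrate_generator.py`); it is coupled at
  +0.3 to the macho (animal-food) factor so that pattern associates
  positively with zinc.
* Energy: normal around 2400 kcal/day (SD 550) with a 120 kcal/mg
  regression on total zinc, floored at 600 kcal.
* FFQ: w_ij = max(0, μ_j + s·Σ_k L_jk f_ik + ε_ij) with the packaged
  loading matrix, signal scale s = 120 g/week, noise SD 100 g/week and
  per-food baselines μ_j plausible for the region. The scales were fixed
  once by pilot runs so that computed pattern scores recover the
  generating factors with correlation ≳0.8 at the full survey size.

One `numpy` Generator seeded from a single integer drives every draw in a
fixed order, so a seed determines the cohort byte-for-byte. The latent
factors are retained as a sidecar (JSON) purely for parameter-recovery
validation.

What the generator does **not** emulate: household clustering and the
multistage sampling design; demographic cross-tabulations beyond the
margins; day-to-day recall variance and misreporting; any real
correlation structure among FFQ foods beyond the four factors; individual
phytate intake. Passing tests therefore demonstrate that the pipeline's
arithmetic and classifications are correct and that its qualitative
conclusions (monotone prevalence decline, pattern-dependent benefit) are
robust across seeds — not that the synthetic prevalences equal the
survey's. In particular the generated baseline insufficiency (~15–16%) is
only required to bracket the survey's figure, and scenario prevalences
(e.g. ~9% and ~6%) sit somewhat above the survey's 6.5% and 4.4% because
the synthetic rice distribution does not reproduce the survey's exact
joint distribution of rice and non-rice zinc.

## Statistics

Paired t, Pearson chi-square (no continuity correction) and OLS trend
regressions are delegated to scipy/statsmodels; the test suite
cross-checks each against independent textbook computations
(mean/SD formula, Σ(O−E)²/E, normal-equation solves). The
Cochran–Armitage trend test is implemented directly (score statistic with
variance p̄(1−p̄)·S_ss) and cross-checked against the linear-by-linear
ordinal association test via the exact identity z²·(N−1)/N = z²_LBL.
Trend regressions use quartile index 1–4 as the exposure, adjusting for
age, sex, region, residence, SES, education and energy (categoricals
one-hot against fixed reference levels: male/north/urban/low/primary).
Household adjustment is dropped — synthetic cohorts have no households —
and every rendered report states this. Which trend test the original
prevalence columns used was never specified; Cochran–Armitage is used
here and documented. A rank-deficient design raises an error naming the
aliased columns rather than silently pseudo-inverting.

## Numerical and I/O choices

* Cohort CSVs are written with Python's shortest round-trip float
  representation and read back with pandas' `round_trip` parser, so
  write→read is an exact identity and equal cohorts produce identical
  bytes.
* Molar masses: phytic acid 660.04 g/mol, zinc 65.38 g/mol (documented
  constants; the ratio (290/660.04)/(3.8/65.38) = 7.6 to one decimal).
* Strict inequalities at every adequacy boundary ("below", "higher
  than"); ties at a cutoff classify as adequate.
* Degenerate inputs: zero-variance paired differences give p = 1 only in
  the all-zero case and are otherwise an error; chi-square with a zero
  expected cell, prevalence of an empty cohort, quartiles of n < 4, and
  shares of a zero-total subject are all explicit errors or exclusions
  with warnings, never silent.

## Problem sizes

Tests and the acceptance checks run the full pipeline at the survey size
(n = 2819, a few seeds) plus smaller cohorts (n = 80–1000) for
structural and recovery checks; the null-calibration check of the trend
test uses 500 simulated regressions at n = 60. These sizes make every
check exact or tightly bounded while keeping the whole suite fast.

## Known limitations

* The substitution holds phytate (hence the absorption fractions) fixed;
  biofortified varieties differ in phytate, but without individual
  phytate data only the aggregate molar-ratio utility is offered.
* No EAR-based probability-of-inadequacy estimator; the 2/3-RNI cutoff
  classifier is what is implemented.
* Loadings are consumed as a fixture; re-deriving them by principal
  component analysis from raw FFQ data is out of scope, and explained
  variance of the original decomposition is a property of the original
  data, not reproducible here.
* The synthetic cohort is a validation instrument, not a forecast of any
  real population.
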