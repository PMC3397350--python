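# biofortsim

Simulation of dietary zinc intake under rice-biofortification scenarios,
stratified by dietary pattern.

## The problem

Zinc deficiency is widespread in populations whose staple is a refined
cereal. Breeding zinc-dense ("biofortified") rice is a candidate
intervention, and its likely impact can be estimated *before* any field
deployment by substituting biofortified rice into the observed diets of a
survey cohort. `biofortsim` implements that substitution analysis end to
end for an adult dietary survey of the kind run in rice-staple Chinese
provinces: per-subject zinc intake from 3-day recall data, dietary-pattern
scores from a factor-loading matrix, scenario substitution, adequacy
classification against the Chinese Dietary Reference Intakes (DRIs), and
population / quartile-stratified reporting. Because the individual-level
survey records are not public, the package also ships a seeded synthetic
cohort generator that reproduces the published marginal structure
(n = 2819 adults, 46.0% male, ~5% rice non-consumers, rice intake
250.1 ± 145.8 g/day, total zinc 12.0 ± 3.7 mg/day), so the whole pipeline
is testable and reproducible.

It is intended for nutrition epidemiologists and modellers evaluating
staple-crop fortification targets.

## The model

For subject *i* with observed zinc-from-rice intake *r_i* (mg/day) and
total zinc *z_i*, replacing rice of zinc density *c_old* (1.7 mg/100 g in
normal polished rice) with biofortified rice of density *c_new* gives

    r_i' = r_i · (c_new / c_old),      z_i' = z_i + r_i · (c_new / c_old − 1).

Adequacy is classified per the Chinese DRIs: insufficiency is intake below
2/3 of the age/sex RNI (cutoff 10.0 mg/day for men 18–49, 23/3 ≈ 7.67
otherwise), excess is intake above the tolerable upper level (45 mg/day
men 20–50, 37 otherwise), and absorbed zinc is 0.26 × intake for men and
0.34 × intake for women (IZiNCG mixed-diet fractions), inadequate below
2.69 / 1.86 mg/day.

A subject's score on dietary pattern *k* is

    S_ik = Σ_j L_jk · z_ij   over foods with |L_jk| ≥ 0.20,

where *z_ij* is the cohort-standardized weekly FFQ intake of food *j* and
*L* is the packaged loading matrix of the four adult patterns
(*traditional* — rice-centred; *macho* — animal foods and alcohol;
*sweet tooth* — cake, drinks, dairy; *healthy* — whole grains, fruit,
vegetables). Scores are split into population quartiles Q1–Q4, and trends
across quartiles are tested by covariate-adjusted least squares (intakes)
and a Cochran–Armitage score test (prevalences).

## Worked example

```python
from biofortsim import (DEFAULT_SCENARIOS, GeneratorConfig, generate_cohort,
                        load_dri, scenario_summary)
from biofortsim.report import render_scenario_markdown

cohort = generate_cohort(GeneratorConfig(seed=7)).subjects
summary = scenario_summary(cohort, list(DEFAULT_SCENARIOS), load_dri())
print(render_scenario_markdown(summary))
```

prints (abridged):

```
| Quantity                                | normal    | intermediate | high      |
|-----------------------------------------|-----------|--------------|-----------|
| Zinc concentration in rice (mg/100 g)   | 1.7       | 2.7          | 3.8       |
| Zinc intake from rice (mg/day)          | 4.3 ± 2.6 | 6.8 ± 4.1    | 9.5 ± 5.8 |
| % insufficiency of zinc intake          | 15.3      | 9.1          | 6.2       |
| Absorbed zinc (mg/day)                  | 3.6 ± 1.2 | 4.4 ± 1.6    | 5.2 ± 2.0 |
| % absorbed zinc inadequacy              | 16.3      | 9.6          | 6.3       |
```

Reading it: raising rice zinc from 1.7 to 3.8 mg/100 g roughly halves the
prevalence of insufficient intake in this synthetic population, and mean
zinc from rice scales exactly with the concentration ratio. The
`examples/` directory holds one short script per capability (cohort
generation, pattern scoring and factor recovery, scenario summaries,
quartile stratification, phytate:zinc ratios); each prints its results
with a note on what they mean. A thin CLI mirrors the stages:
`biofortsim simulate | score | biofortify | adequacy | report`.

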