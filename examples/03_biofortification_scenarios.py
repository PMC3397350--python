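"""Simulate rice biofortification and summarise the population impact.

Normal rice carries 1.7 mg zinc/100 g; the two published breeding targets
are 2.7 (intermediate) and 3.8 (high) mg/100 g. Substituting biofortified
rice scales each subject's zinc-from-rice by the concentration ratio.
"""

from biofortsim import (
    DEFAULT_SCENARIOS,
    GeneratorConfig,
    generate_cohort,
    load_dri,
    scenario_summary,
)
from biofortsim.report import render_scenario_markdown

cohort = generate_cohort(GeneratorConfig(seed=7)).subjects
dri = load_dri()

summary = scenario_summary(cohort, list(DEFAULT_SCENARIOS), dri)
print(render_scenario_markdown(summary))

# Reading the table: zinc from rice rises in proportion to the rice-zinc
# concentration (the SD scales by exactly the same ratio); the prevalence
# of insufficient intake (< 2/3 of the age/sex RNI) and of absorbed-zinc
# inadequacy fall monotonically; excess intake (> UL) stays rare. The
# paired-t and chi-square columns compare each scenario with normal rice.
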