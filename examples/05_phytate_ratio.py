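"""Phytate:zinc molar ratio of rice varieties.

Phytate binds zinc in the gut; the molar ratio of phytic acid to zinc is
the standard predictor of how well a food's zinc is absorbed (ratios below
~15 indicate reasonably available zinc).
"""

from biofortsim import phytate_zinc_molar_ratio

# a biofortified variety: 290 mg phytate and 3.8 mg zinc per 100 g
print(f"biofortified variety: {phytate_zinc_molar_ratio(290, 3.8):.1f}")

# average densities of common Chinese rice (115 mg phytate, 1.41 mg zinc)
print(f"ratio of average densities: {phytate_zinc_molar_ratio(115, 1.41):.1f}")

# Note the aggregation subtlety: the average of per-variety ratios is not
# the ratio of average densities, so the two summaries differ even over
# the same set of varieties.
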