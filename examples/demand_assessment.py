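"""Classify each indicator's demand category from mean/SD statistics.

Each indicator's initial-questionnaire mean and SD is compared with its
system part's pooled benchmark: low dispersion with an above-benchmark mean
is a positive demand, low dispersion below the benchmark is unactivated,
and high dispersion marks a potential demand regardless of the mean.
"""

import padcare as pc

codebook = pc.default_codebook()
stats = pc.published_demand_stats()

table, summary = pc.assess_from_stats(stats, codebook)

cols = ["indicator_code", "system_part", "mean", "sd", "gt_mean", "lt_sd", "category"]
print(table[cols].to_string(index=False))
print()
for cat in ("positive", "unactivated", "potential"):
    print(f"{cat:>12}: {summary['counts'][cat]:>2} indicators "
          f"({summary['percentages'][cat]}%)")
print(
    "\nPercentages are over the 18 indicators, rounded half-up to 1 decimal; "
    "positive demands dominate, meaning most touchpoints are used and endorsed."
)
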