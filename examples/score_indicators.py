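"""Score PAD and classify emotional tendencies for all 18 service indicators.

Loads the bundled item-mean matrix (12 bipolar items per indicator, averaged
over the respondent cohort), computes each indicator's pleasure/arousal/
dominance point, and assigns the nearest of the 8 benchmark emotions.
"""

import padcare as pc

codebook = pc.default_codebook()
benchmarks = pc.default_benchmarks()
item_means = pc.published_item_means()

results = pc.evaluate_all(item_means, codebook, benchmarks, require_complete=True)

cols = ["indicator_code", "P", "A", "D", "tendency", "polarity"]
print(results[cols].round(4).to_string(index=False))
print(
    f"\n{(results['polarity'] == 'positive').sum()} of {len(results)} indicators "
    "lean toward a positive benchmark emotion (Joy, Relaxation, Surprise or "
    "Reliance); the rest lean negative. Each row's PAD point is the signed "
    "mean of its four items per dimension, on the -4..+4 scale."
)
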