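"""Build and render the joined system report.

Combines the emotion-tendency table with the demand assessment and totals
the results per system part (smart devices, online software, offline
services) and overall.
"""

import padcare as pc

codebook = pc.default_codebook()
benchmarks = pc.default_benchmarks()

tendencies = pc.evaluate_all(pc.published_item_means(), codebook, benchmarks)
demands, _ = pc.assess_from_stats(pc.published_demand_stats(), codebook)

report = pc.build_report(tendencies, demands, codebook)
print(pc.render_report(report, "text"))
print(
    "Each line pairs an indicator's PAD point and nearest benchmark emotion "
    "with its demand category; the totals reproduce the headline counts "
    "(10 positive-polarity tendencies, 10/5/3 demand split)."
)
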