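"""The full study analysis: both batteries on one synthetic data set.

Runs the node-dimensionality battery (is one trait enough for the whole
scale?) and the fluency-split battery (do low- and high-fluency pools share
one quality trait?) and prints the Markdown reports.  Short chains keep the
example quick; for real analyses use the default sampler settings.
"""

from treequal import (
    AnalysisConfig,
    SamplerConfig,
    SyntheticConfig,
    generate_study,
    run_fluency_split_battery,
    run_node_dimensionality_battery,
)
from treequal.study_pipeline import render_fluency_battery, render_node_battery

table, _ = generate_study(SyntheticConfig(n_persons=100, seed=31))
config = AnalysisConfig(sampler=SamplerConfig(warmup_draws=250, kept_draws=250, seed=5))

node_report = run_node_dimensionality_battery(table, config)
print(render_node_battery(node_report))
# Instruction-specific blocks omit their data-starved node (no 5s under
# be-fluent, no 1s under be-creative) and show its correlations as NA.

fluency_report = run_fluency_split_battery(table, config)
print(render_fluency_battery(fluency_report))
# The generating model here is unidimensional, so the low/high-fluency
# correlation should sit near 1 and the two-trait model should not be
# decisively favored.
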