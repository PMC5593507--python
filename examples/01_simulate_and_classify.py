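"""Simulate a labeled DRG-neuron population and recover its subgroups.

Generates 800 synthetic neurons (a scaled-down mixed culture: ~17%
PS-sensitive, most of those inhibitor-sensitive), runs the classification
chain (baseline, smoothing, windowed amplitudes, neuron gate, responder
thresholds, inhibition statistic) and compares the recovered 2x2 subgroup
counts against the generator's ground-truth labels.
"""

import collections

from trpquant import (
    SyntheticPopulationConfig,
    classify_population,
    default_schedule,
    generate_population,
    subgroup_2x2,
)

config = SyntheticPopulationConfig(n_cells=800, seed=42)
schedule = default_schedule()
traces, labels = generate_population(config, schedule)
classifications = classify_population(traces, schedule)
groups, table = subgroup_2x2(classifications)

truth = collections.Counter()
for l in labels:
    if l.ps_sensitive:
        key = ("caps+" if l.caps_sensitive else "caps-") + (
            "/inh+" if l.inhibitor_sensitive else "/inh-"
        )
        truth[key] += 1

print(f"cells simulated: {config.n_cells}")
print(f"PS-sensitive neurons recovered: {sum(len(v) for v in groups.values())} "
      f"(ground truth {sum(truth.values())})")
print("\nsubgroup counts (capsaicin x DAMGO sensitivity), recovered vs truth:")
for key in ("caps+/inh+", "caps+/inh-", "caps-/inh+", "caps-/inh-"):
    print(f"  {key:11s} {len(groups[key]):4d}  vs {truth[key]:4d}")
print("\nEach count is the number of PS-responsive neurons falling in that")
print("capsaicin-sensitivity x inhibitor-sensitivity cell; close agreement")
print("with the generating labels shows the thresholds separate the")
print("subpopulations at this noise level (amplitude 0.5, noise SD 0.05).")
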