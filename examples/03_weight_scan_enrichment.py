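"""Multi-weight enrichment scan with planted DE-driven and DS-driven sets.

Reproduces the method's central point on synthetic data: a gene set driven
by expression changes is only visible near the DE-only end of the weight
grid, a splicing-driven set only near the DS-only end, and the union over
the 11-weight scan recovers both while either single analysis misses one.
"""

import seqgsea as sg
from seqgsea.gsea_engine import (
    LINEAR,
    saturation_analysis,
    scan_union,
    significant_sets,
    weight_scan,
)

cfg = sg.SimConfig(seed=7)  # 1,000 genes, 5v5, planted DE + DS sets
cd, truth, collection = sg.simulate(cfg)
cd = sg.attach_size_factors(sg.filter_low_expression(cd))
scored = sg.compute_scores(cd, n_perm=200, seed=8)

scan = weight_scan(scored, collection)  # Linear strategy, alpha = 0, 0.1, ..., 1

print("significant sets (FDR <= 0.05) per weight:")
for alpha in (0.0, 0.5, 1.0):
    print(f"  alpha={alpha:3}: {sorted(significant_sets(scan, LINEAR, alpha))}")
print(f"union over all 11 weights: {sorted(scan_union(scan, LINEAR))}")

sat = saturation_analysis(scan)
print("\nsaturation curve (weights added DE-only, DS-only, then inward):")
print(sat.to_string(index=False))

# alpha=1 weights only expression evidence and finds just the DE-driven
# set; alpha=0 only splicing evidence and finds just the DS-driven set.
# The cumulative-unique-set curve plateaus after the two extremes, showing
# a handful of weights saturates discovery on this dataset.
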