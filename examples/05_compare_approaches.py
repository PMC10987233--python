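"""Spatial vs spatio-temporal approach on the same synthetic region.

Runs both approaches over several taxa, then compares their relative pure
fractions per taxon with exact paired Wilcoxon tests and summarizes
environmental heterogeneity with PERMDISP.
"""

import warnings

import numpy as np

from pondvarpart import RunConfig, SimulationConfig, run

warnings.filterwarnings("ignore")

cfg = RunConfig(
    simulate=SimulationConfig(seed=3),
    n_taxa=3, approach="both", d_max=2, n_null=49, n_perm=499,
    seed=3, n_starts=2, out_dir="scratch/example_run",
)
result = run(cfg)

print("per-taxon totals (pooled vs mean per-period):")
for taxon, res3 in result.spatiotemporal.items():
    per_period = np.mean([r.total for r in result.spatial[taxon]])
    print(f"  {taxon}: E+S+T = {res3.total:.3f}  vs  mean per-period E+S = {per_period:.3f}")

print("\npaired Wilcoxon contrasts (spatial vs spatio-temporal relative fractions):")
print(result.comparison.to_string(index=False))

print("\nPERMDISP heterogeneity contrasts:")
print(result.permdisp.round(4).to_string(index=False))
# The pooled model typically explains more variation than any snapshot —
# the core argument for analysing space and time together.  With only 3
# taxa the Wilcoxon p cannot reach significance (the floor is 2/2^3); with
# the study-sized 7 taxa the floor is 0.016.
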