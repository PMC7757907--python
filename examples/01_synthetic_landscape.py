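"""Generate a synthetic landscape and inspect its structure.

Builds the default 100x100-cell scenario: 12 smooth bioclim-style
predictors (4 of them deliberately collinear), a known logistic truth
surface, presences sampled proportionally to it, and a host-area field.
"""

import numpy as np

from zonarisk import (
    SyntheticScenario,
    generate_host_raster,
    generate_predictor_stack,
    generate_true_suitability,
    sample_presences,
)

scenario = SyntheticScenario(seed=0)
stack = generate_predictor_stack(scenario)
truth = generate_true_suitability(
    stack, scenario.linear_coefficients, scenario.quadratic_coefficients,
    intercept=scenario.intercept,
)
occ = sample_presences(truth, scenario.presence_n, seed=scenario.seed + 1)
host = generate_host_raster(scenario)

print(f"stack: {len(stack)} layers on a {stack.transform.shape} grid "
      f"({scenario.cell_size} deg cells)")
names = stack.names
for i, j, r in scenario.collinear_pairs:
    emp = np.corrcoef(stack[names[i]].values.ravel(), stack[names[j]].values.ravel())[0, 1]
    print(f"  built-in collinearity {names[i]}~{names[j]}: target r={r}, empirical r={emp:.3f}")
print(f"truth surface: prevalence (mean suitability) = {truth.values.mean():.3f}")
print(f"presences: {len(occ)} points, mean truth at presences = "
      f"{truth.values[truth.transform.index_of(occ.lon, occ.lat)].mean():.3f}")
print(f"host field: min = {host.values.min():.0f} ha, max = {host.values.max():.0f} ha, "
      f"{(host.values == 0).mean():.0%} of cells grow no host crops")
# The collinear pairs give the pruning step real work; the gap between mean
# truth at presences and overall prevalence is the signal the model must find.
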