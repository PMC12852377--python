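"""Compare wavelength-selection methods on one simulated target.

Runs VIP, SPA and CARS (plus the no-selection baseline) on the NIR block
for the dominant blend component and reports subset sizes and
cross-validated errors.
"""

import numpy as np

from blendspec import (
    cars_select,
    no_selection,
    simulate_study,
    spa_select,
    vip_select,
)

_, nir, design = simulate_study(seed=2)
X, y = nir.values, design.proportions[:, 0]

results = [
    no_selection(X, y),
    vip_select(X, y, n_lv=10),
    spa_select(X, y, max_vars=15, start="scan"),
    cars_select(X, y, n_runs=50, seed=2),
]

print(f"{'method':<6} {'n_vars':>6} {'RMSECV':>9}")
for res in results:
    print(f"{res.method:<6} {res.selected_indices.size:>6} "
          f"{res.rmsecv_of_subset:>9.4f}")
# RMSECV is the leave-one-out (VIP/none), PRESS (SPA) or 5-fold (CARS)
# cross-validated error of a model on the kept variables; a small subset
# matching or beating the full 220-variable spectrum indicates the target
# signal is confined to a few absorption bands.
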