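"""How map noise degrades fold quality.

Adds Gaussian noise of increasing sigma to the true distance map and folds
from each, mimicking distance predictors of decreasing accuracy.
"""

import numpy as np

from distfold.fixtures import FixtureSpec, make_noisy_map, make_structure
from distfold.folder import fold, restraints_from_map
from distfold.metrics import tm_score

native = make_structure(FixtureSpec(L=40, topology="helix_bundle", seed=1))

print("sigma (Å)  median TM-score (5 seeds)")
for sigma in (0.0, 1.0, 2.0, 4.0):
    tms = []
    for rep in range(5):
        pred = make_noisy_map(native, noise_sigma=sigma, seed=100 + rep)
        r = fold(restraints_from_map(pred), seed=rep)
        tms.append(max(tm_score(r.model, native).tm_score,
                       tm_score(r.mirror_model, native).tm_score))
    print(f"{sigma:8.1f}  {np.median(tms):.3f}")
# TM-score >= 0.5 means the fold topology is still correct; accuracy decays
# smoothly with noise, and at sigma ~4 Å the map no longer pins the fold.
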