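"""Stepwise discriminant analysis on a matrix with planted structure.

SDA greedily adds the feature that most reduces Wilks' lambda (the
within-to-total scatter determinant ratio) and removes features whose
partial F drops below the removal threshold.  Only the two planted
discriminative columns should survive.
"""

import numpy as np

from subloc2l.features.base import LabeledFeatureSet
from subloc2l.selection import sda_select

rng = np.random.default_rng(0)
n_per = 30
y = np.repeat([1, 2, 3], n_per)
X = rng.normal(0, 1, (3 * n_per, 20))
X[:, 4] += 2.5 * y            # separates all three classes
X[:, 11] += 3.0 * (y == 2)    # separates class 2 from the rest

fs = LabeledFeatureSet(name="view1", matrix=X, labels=y)
sel = sda_select(fs, f_enter=3.84, f_remove=2.71, max_features=10)

print("selected columns:", sel.selected)
for (action, idx, F), lam in zip(sel.steps_log, sel.lambda_trace):
    print(f"  {action:<6} feature {idx:<3} partial F={F:8.2f}  lambda={lam:.4f}")
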