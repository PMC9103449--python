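"""Gaussian nearest-neighbor-interpolation augmentation.

Each of the 86 samples receives 20 synthetic neighbors drawn feature-wise
from N(x_ij, lambda * feature mean) with lambda = 0.1, growing the table to
86 * 21 = 1806 rows.
"""

import numpy as np

import nrsurrogate as nr

table = nr.generate_dataset(seed=0)
sigma2 = nr.feature_variance(table, 0.1)
print("interpolation variance per feature:",
      "  ".join(f"{n}={v:.4f}" for n, v in zip(table.feature_names, sigma2)))

augmented = nr.nni_augment(table, nr.AugmentationSpec(), seed=0)
print(f"rows: {table.n} -> {augmented.n}")
print("provenance counts:",
      {tag: int((augmented.provenance == tag).sum())
       for tag in ("original", "nni")})

# synthetics of one parent scatter around it with the prescribed spread
child = augmented.X[86:106]          # the 20 children of parent 0
print(f"parent 0 features:  {np.round(table.X[0], 3)}")
print(f"children mean:      {np.round(child.mean(axis=0), 3)}")
print(f"children std:       {np.round(child.std(axis=0, ddof=1), 3)} "
      f"(target {np.round(np.sqrt(sigma2), 3)})")
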