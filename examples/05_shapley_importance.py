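"""Exact Shapley feature attribution of the fitted surrogate.

Enumerates all 2^3 feature coalitions against a background sample of the
training table, giving exact interventional Shapley values; global
importance is the mean |phi| per feature.
"""

import numpy as np

import nrsurrogate as nr

table = nr.generate_dataset(seed=0)
augmented = nr.nni_augment(table, seed=0)
balanced = nr.smote_augment(augmented, nr.cluster(augmented, K=2, seed=0),
                            seed=0)
model = nr.fit_gbt(balanced, seed=0)

report = nr.explain_table(model, balanced, max_background=128, seed=0)
print(f"base value (mean background prediction): {report.base_value:.3f} MPa")
print(f"local accuracy max error: {report.local_accuracy_error():.2e} MPa")

print("\nglobal importance (mean |phi|):")
for name, val in report.ranking():
    print(f"  {name:7s} {val:.3f} MPa")
print("\neps_h > omega > eps_nh: hydrogen-bond strength dominates tensile"
      " stress, filler fraction is second, the non-hydrogen-bond term is"
      " nearly inert — the ordering planted in the generator.")

row = balanced.X[0]
phi = nr.exact_shapley(model.predict, balanced.X[:128], row)
print(f"\none sample {np.round(row, 3)} -> per-feature contributions "
      f"{np.round(phi, 3)} MPa")
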