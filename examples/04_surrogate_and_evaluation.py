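"""Fit the boosted-tree surrogate and evaluate its robustness.

Trains on the fully augmented table (NNI + SMOTE) with the tuned operating
point (55 trees, eta 0.16, depth 8, reg_lambda 120), then runs the repeated
random-split protocol at 99 splits and compares against the OLS baseline on
held-out original rows.
"""

import nrsurrogate as nr

table = nr.generate_dataset(seed=0)
augmented = nr.nni_augment(table, seed=0)
balanced = nr.smote_augment(augmented, nr.cluster(augmented, K=2, seed=0),
                            seed=0)

model = nr.fit_gbt(balanced, seed=0)
print(f"training R2 on {balanced.n} rows: "
      f"{nr.r2(balanced.y, model.predict(balanced.X)):.3f}")

report = nr.robustness(
    balanced,
    {"gbt": lambda t, s: nr.fit_gbt(t, seed=s),
     "mlr": lambda t, s: nr.fit_baseline(t, "mlr", seed=s)},
    nr.EvalSpec(n_splits=99, test_originals_only=True),
    seed=0,
)
print("\n99 random splits, test pool = original rows only:")
print(report.summary_text())
print("\nhigher min/mean R2 for gbt than mlr mirrors the boosted trees'"
      " advantage on the interacting surface; Cov is the fraction of"
      " predictions within twice sd(|y|).")
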