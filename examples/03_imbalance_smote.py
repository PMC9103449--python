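"""Imbalance correction: K-means clustering + Borderline-SMOTE.

The augmented table is clustered (K=2); the smaller cluster's boundary
("danger") rows seed SMOTE segments toward minority neighbors until the
clusters are balanced. Targets are interpolated with the same coefficient as
the features.
"""

import nrsurrogate as nr

table = nr.generate_dataset(seed=0)
augmented = nr.nni_augment(table, seed=0)

assignment = nr.cluster(augmented, K=2, seed=0)
print(f"cluster sizes after NNI: {assignment.sizes.tolist()} "
      f"(minority = cluster {assignment.minority_label()})")

danger = nr.danger_set(augmented, assignment)
print(f"danger (boundary) rows in the minority cluster: {danger.size}")

balanced = nr.smote_augment(augmented, assignment, seed=0)
n_new = balanced.n - augmented.n
print(f"SMOTE synthetics added: {n_new}  ({augmented.n} -> {balanced.n} rows)")
print("every synthetic lies on a segment between a danger row and one of its"
      " minority neighbors, with the target interpolated alongside.")
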