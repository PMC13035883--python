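"""Compare federated training under IID, realistically biased, and strict
median splits.

Runs the toy federated-averaging demonstrator on one shared synthetic
cohort and regression task: two clients, size-weighted model averaging,
deterministic full-batch gradient descent.  Expected qualitative pattern:
IID tracks the pooled optimum; the strict median split shrinks predictions
toward the pooled mean (mode collapse: low prediction-variance ratio) and
errs most; the realistically sampled bias lands in between.
"""

import numpy as np

from biasplit import studies

results = studies.federated_comparison(seed=3, n=1500)

print(f"{'scenario':10s} {'test MAE kg':>12s} {'test MAE cm':>12s} "
      f"{'pred-var ratio (weight)':>24s}")
for name in ("iid", "sampled", "median"):
    r = results[name]
    print(f"{name:10s} {r.test_mae[0]:12.2f} {r.test_mae[1]:12.2f} "
          f"{r.variance_ratio[0]:24.2f}")
print("\nMAE: mean absolute prediction error on the common held-out test set.")
print("pred-var ratio: Var(predictions)/Var(labels); values far below the")
print("IID row indicate mode collapse (predictions squeezed toward the mean).")
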