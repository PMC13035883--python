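"""Check which subgroup targets a pooled cohort can actually support.

Any partition of a pool (mean mu, variance sigma^2) into subsets obeys
exact mixture-moment identities, so shifted subgroup means force smaller
subgroup spreads.  feasible_sigma solves the variance identity for the
common subgroup SD; mixture_consistency reports the residuals of both
identities for hypothetical (or measured) subgroup moments.
"""

import numpy as np

import biasplit as b

global_weight = b.MomentSpec(mean=(79.9,), sd=(18.7,))

# Shifting two equal groups +/- 10 kg: what spread can each group keep?
sds = b.feasible_sigma(global_weight, [(69.9,), (89.9,)], [0.5, 0.5])
print(f"pooled weight 79.9 +/- 18.7 kg, targets +/- 10 kg:")
print(f"  feasible subgroup SD = {sds[0][0]:.2f} kg "
      "(sqrt(18.7^2 - 10^2): the mean shift consumes variance)")

# Naively keeping the global SD in both groups violates the identity:
r_mean, r_var = b.mixture_consistency(
    [1039, 1039],
    np.array([[69.9], [89.9]]),
    np.array([[18.7**2], [18.7**2]]),
    np.array([79.9]),
    np.array([18.7**2]),
)
print(f"  keeping SD 18.7 in both groups -> variance residual {r_var[0]:.1f} kg^2 "
      "(infeasible: no partition of this pool has those moments)")

# Asking for too wide a mean split fails outright:
try:
    b.feasible_sigma(global_weight, [(55.0,), (104.8,)], [0.5, 0.5])
except Exception as exc:
    print(f"  targets +/- ~25 kg -> {type(exc).__name__}: mean spread alone "
          "exceeds the pooled variance")
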