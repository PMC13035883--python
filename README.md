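# biasplit

Partition a pooled cohort with continuous labels into client-specific
subsets whose label distributions match prescribed targets — the
data-preparation step for realistic **non-IID federated-learning
pre-studies**.

Federated learning (FL) assumes client datasets are roughly identically
distributed, but real clinical sites differ demographically: average
weight and height vary by 20+ kg / 10+ cm across countries. Before
rolling out an FL system it is valuable to simulate such client bias from
a single pooled dataset. Naive splits are either unrealistic (a hard cut
at the median produces non-overlapping label supports) or uncontrolled
(random splits are IID by construction). `biasplit` samples subsets with
*specified means and standard deviations* from a pool, checks whether
those targets are feasible at all, quantifies the achieved approximation,
and demonstrates the downstream effect on federated training with a toy
regression task.

## Method

Given a pool of N samples with d-dimensional labels and M Gaussian
targets (μ_i, σ_i per dimension), the sampler shuffles the pool and
assigns samples one at a time to the group minimizing the cost

```
C = Σ_i χ²_i / (1 − Gini)²
χ²_i  = Σ_cells (O − E)²/E          (group i's histogram vs its target,
                                     E = group size × target cell probability)
Gini  = Σ_ij |s_i − s_j| / (2(M−1) Σ_i s_i)   (group-size imbalance, 0…1)
```

over a shared equal-width grid (default 20 bins per dimension, 1-D or
product grids in higher dimensions). The pass is repeated from 30 seeded
random permutations and the lowest-cost assignment is kept. A collapsed
split (Gini = 1) costs +∞ and is never selected while an alternative
exists.

Feasibility comes from the exact mixture-moment identities: any partition
obeys μ = (1/N) Σ n_i μ_i and σ² = (1/N) Σ n_i (σ_i² + (μ_i − μ)²), so
subgroup means shifted by Δ force subgroup SDs down to
√(σ² − Σ share_i Δ_i²). `feasible_sigma` solves this; `mixture_consistency`
reports the residuals of both identities for any proposed moments.

Split quality is scored by the binned **Bhattacharyya distance**
BD = −ln Σ √(p̂·q) between each group's empirical histogram and its
continuous target (0 = perfect overlap, disjoint supports → ∞).

## Worked example

`python examples/02_greedy_split.py` builds a 2078-sample pool as an
exact equal mixture of two weight targets 10 kg below/above the global
mean (79.9 kg, global SD 18.7 kg; feasible subgroup SD 15.80 kg) and runs
the greedy sampler:

```
1-D weight split (targets 69.9 kg and 89.9 kg, SD 15.80 kg each):
  group 0: n=1039, achieved mean 69.7 kg (target 69.9), BD to target 0.0015
  group 1: n=1039, achieved mean 90.5 kg (target 89.9), BD to target 0.0015
  worst-group BD 0.0015 (reference splits report up to 0.08 on this scenario)
  final cost C = 25.85 (chi2 13.9 + 12.0, Gini 0.000; won by restart 2)
```

Both groups hit their target means within a fraction of a kilogram at
exactly equal sizes, and the Bhattacharyya distances say each group's
histogram is nearly indistinguishable from its continuous target.

The other examples cover cohort generation and country presets (`01`),
feasibility checking (`03`), and the federated-averaging comparison of
IID / realistically sampled / strict median splits (`04`), where the
strict split shows the lowest prediction-variance ratio (mode collapse)
and the highest test error.

A thin CLI mirrors the library: `biasplit generate | sample |
split-median | split-random | evaluate | fedsim`, each with `--seed` and
`--out`; split manifests are schema-versioned JSON with full provenance
(seed, winning restart, cost breakdown).

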