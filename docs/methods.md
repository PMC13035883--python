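# Methods

## Problem setting

A pooled cohort of N samples carries a d-dimensional continuous label
vector per sample (here: patient weight in kg and height in cm). The goal
is to partition the pool into M client groups whose label distributions
approximate prescribed Gaussian targets — emulating demographically
biased clinical sites for federated-learning pre-studies — and to
quantify both the attainability of the targets and the quality of the
achieved approximation.

## Feasibility: the mixture-moment identities

For any partition into subsets of sizes n_i with subset means μ_i and
*population* (1/n) variances σ_i²,

    μ  = (1/N) Σ n_i μ_i
    σ² = (1/N) Σ n_i (σ_i² + (μ_i − μ)²)

hold exactly. These are identities, not approximations, so they constrain
which target moments any partition can realize. Solving the variance
identity under the symmetric assumption (all groups share one SD per
dimension) gives the feasible subgroup SD

    σ_g = sqrt(σ² − Σ_i share_i (μ_i − μ)²),

with a `FeasibilityError` when the radicand is negative. For the
reference scenarios (equal halves shifted ±10 kg around 79.9 kg with
global SD 18.7 kg, and ±5 cm around 171.6 cm with global SD 9.7 cm) this
yields σ_g ≈ 15.80 kg and ≈ 8.31 cm.

The population-variance convention is used throughout because the
identity is exact only under it; most library defaults (1/(n−1)) would
leave O(1/n) residuals. `mixture_consistency` reports the residuals of
both identities and is the universal regression check applied to every
partition the package produces.

## The sampling objective

Each group's match to its target is the chi-squared distance between its
observed histogram O and expected counts E on a shared equal-width grid:

    χ² = Σ_cells (O − E)² / E,     E_cell = n_group · p_cell,

where p are the target's cell probabilities from Gaussian CDF
differencing (exact bivariate rectangle probabilities when a correlation
matrix is supplied; independent marginals otherwise, which is the
default). E scales with the *current* group size, so χ² is meaningful
while groups grow during assignment. Size balance enters through the Gini
coefficient of the group sizes, and the combined cost is

    C = Σ_i χ²_i / (1 − Gini)²,

squared in the denominator to emphasize comparable sizes. Gini = 1 (total
collapse) maps to an infinite-cost sentinel rather than an exception, so
the optimizer simply never picks it while an alternative exists.

Numerical choices:

- **Grid**: equal-width, built once from the global cohort range widened
  by 0.1% per side, shared by all groups and restarts so χ² values are
  comparable. Default 20 bins per dimension (the bin count is a free
  parameter of the method; 20 gives ~100 samples per occupied bin at the
  reference cohort size). A constant label dimension degrades to a single
  bin with a warning.
- **Near-zero expected cells**: cells with target probability < 1e−12 are
  excluded from the χ² sum; an observed sample landing there adds a fixed
  10⁶ penalty instead of an infinite ratio. This keeps costs finite while
  strongly discouraging out-of-support placement.
- **Empty groups**: χ² of an empty group is 0; imbalance is penalized
  exclusively by the Gini term, keeping the two mechanisms orthogonal.

## The greedy multi-restart sampler

One pass shuffles the pool (seeded permutation) and assigns each sample
to the group whose tentative placement minimizes C, ties broken toward
the lowest group index (deterministic given the permutation). The pass is
repeated for a configurable number of restarts (default 30), each with a
fresh child seed spawned from the master seed, and the lowest final cost
wins; the per-restart best-cost trajectory is recorded in the assignment
provenance, so keep-best behavior is auditable.

χ² admits the closed form χ² = A/n − 2·n_in + n·P_in + 10⁶·n_out with
A = Σ O_c²/p_c over counted cells, so a tentative placement updates one
cell and evaluates in O(1) per candidate group; the full pass costs
O(N·M) cost evaluations. The incremental value is identical to direct
evaluation (asserted to 1e−9 against a from-scratch recomputation). The
greedy scheme is a heuristic: on exhaustively enumerable instances its
cost is bounded below by the true optimum and, empirically, above by the
median random assignment.

Baselines: a strict median split (threshold one label at its median —
non-overlapping supports, degenerate under heavy ties) and a uniform IID
random split.

## Evaluation

Achieved-vs-target overlap uses the binned Bhattacharyya distance
BD = −ln Σ √(p̂·q) on the sampler's own grid by default (comparability
with the objective); a finer 100-bins-per-dimension evaluation-only grid
is available because finite-sample BD carries an upward bias of roughly
(occupied cells)/(8n) even for a perfect match. Disjoint supports report
an ∞ sentinel. Against a closed-form oracle, the binned estimate for two
unit-variance Gaussians one σ apart converges to (Δμ)²/8σ² = 0.125 within
5% at 100 bins and n = 10⁵.

## Synthetic cohorts

The generator draws from a (optionally truncated, optionally correlated)
multivariate Gaussian. The packaged "paper-like" spec reproduces the
pooled clinical statistics the toolkit was designed around — N = 2078,
weight 79.9 ± 18.7 kg, height 171.6 ± 9.7 cm — with truncation to the
source studies' inclusion ranges (45–120 kg, 140–200 cm) and a default
weight–height correlation of ρ = 0.5. ρ is a documented knob, not an
empirical reproduction: the original cohort's correlation is unpublished,
and 0.5 is a plausible adult-population value. Truncation uses rejection
sampling with a resample cap (100 passes), never clipping, which would
create boundary atoms the histograms would mistake for structure.
Truncation also shrinks the realized moments slightly (e.g. weight SD
16.3 instead of 18.7); the truncated cohort is *not* Gaussian, which is
deliberate — real cohorts aren't either.

Mixture pools (`generate_mixture_cohort`) draw exact component counts via
largest-remainder rounding, so an "equal mixture" of two targets is
exactly balanced; these pools make prescribed targets exactly attainable
and are the parameter-recovery ground truth.

What the generator does **not** emulate: non-Gaussian shapes beyond
truncation, measurement error, site-level covariate shift, or any image
content. Passing tests therefore demonstrate correctness of the
partitioning machinery under Gaussian-mixture conditions, not performance
on any particular real cohort.

Country presets ship the published mean weights/heights (men/women for
Germany, USA, Japan, Nigeria, Brazil; heights stored in metres as
published and converted to cm on load). The source table prints no SDs,
so presets carry `sd=None` and callers supply spreads directly or derive
them with the feasibility solver.

## Reference study scenarios

`biasplit.studies` packages the three desk-scale scenarios used for
reproduction: 1-D weight (targets ±10 kg), 1-D height (±5 cm) — both on
exact mixture pools — and the 2-D joint case, where the pool is a single
truncated correlated Gaussian and the shifted independent-marginal
targets are only approximately attainable, making it the hard case. Each
runs 2 groups × 30 restarts × 20 bins on n = 2078 and reports the larger
per-group BD, summarized as the median over 5 master seeds. Problem sizes
match the reference cohort; a full three-study run takes seconds.

## Federated demonstrator

The FL module exists to exercise the splits, not to model a particular
network: clients train linear regressors by deterministic full-batch
gradient descent and the server averages parameters weighted by client
size. Features are a seeded random linear map of the standardized labels
plus Gaussian noise (default SD 1.5 on the standardized scale, 4
features). With that noise level the task is a genuinely noisy inverse
problem, so each client's optimal predictor regresses toward *its own*
label mean and shrinks with its own label variance — which is exactly how
client bias should manifest: IID clients track the pooled optimum, strict
median splits halve the within-client label variance and the averaged
model compresses predictions toward the pooled mean (mode collapse:
prediction-variance ratio well below the IID run, errors growing toward
the label extremes), and realistically sampled biases land in between.
The final-error ordering IID ≤ sampled ≤ strict holds in the large
majority of seeds but not universally — the effects are stochastic at
desk scale, hence the majority-of-5-seeds framing.

Default comparison schedule: 20 rounds × 10 local epochs at learning rate
0.05 with an 80/20 client-local train/validation split (validation logged
only; no early stopping, keeping runs exactly seed-reproducible). The
schedule object defaults to 50 rounds × 20 epochs for standalone use.

## Known limitations

- Gaussian targets only; other families are out of scope.
- Greedy + restarts is not a global optimizer; no sample dropping is
  supported (all data are always assigned).
- The optional hard size-share constraint is intentionally absent:
  balance is governed solely by the Gini term.
- The 2-D expected distribution defaults to independent marginals; the
  bivariate-correlated path exists but is opt-in per target.
- Mean placement accuracy is limited by the histogram resolution (the χ²
  objective is bin-level), roughly half a bin width in the worst case.
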