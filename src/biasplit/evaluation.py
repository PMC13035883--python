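"""Split-quality metrics and mixture-moment feasibility checks.

Any partition of a cohort of size N into M subsets of sizes n_i with
subset means mu_i and (population) variances sigma_i^2 satisfies the exact
mixture identities

    mu      = (1/N) sum_i n_i mu_i,
    sigma^2 = (1/N) sum_i n_i (sigma_i^2 + (mu_i - mu)^2),

so prescribed subgroup targets are only attainable when these hold at
least approximately: target distributions cannot be derived arbitrarily
from a given pool.  :func:`mixture_consistency` reports the residuals of
both identities for a candidate set of group moments, and
:func:`feasible_sigma` inverts the variance identity to find the common
subgroup SD compatible with given target means and the pooled moments.

Distributional overlap between an achieved subset and its continuous
target is quantified by the binned Bhattacharyya distance
``BD = -ln sum_cells sqrt(p_hat * q)``: 0 means perfect overlap, and
disjoint supports go to infinity (reported as an ``inf`` sentinel).

Note: population (1/n) variances are used throughout — the variance
identity above is exact only under that convention, unlike the 1/(n-1)
default of most libraries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort_synth import Cohort, ConfigurationError, MomentSpec
from .histogram_cost import (
    ExpectedProbabilities,
    HistogramGrid,
    ObservedCounts,
    chi_squared,
    expected_probabilities,
    gini,
)
from .sampler import Assignment

__all__ = [
    "EvaluationReport",
    "GroupReport",
    "FeasibilityError",
    "bhattacharyya_binned",
    "mixture_consistency",
    "feasible_sigma",
    "evaluate",
    "EVAL_BINS_PER_DIM",
]

EVAL_BINS_PER_DIM = 100  # finer evaluation-only grid option


class FeasibilityError(ValueError):
    """Target moments incompatible with the pooled cohort's moments."""


def bhattacharyya_binned(
    group: ObservedCounts, target: ExpectedProbabilities
) -> float:
    """Binned Bhattacharyya distance between a group's empirical cell
    frequencies and the target's cell probabilities on a shared grid."""
    if group.total == 0:
        raise ValueError("Bhattacharyya distance of an empty group is undefined")
    p_hat = group.counts / group.total
    coeff = float(np.sum(np.sqrt(p_hat * target.probabilities)))
    if coeff <= 0.0:
        return math.inf
    return -math.log(coeff)


def _population_moments(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = labels.mean(axis=0)
    var = labels.var(axis=0)  # ddof=0: population convention
    return mean, var


def mixture_consistency(
    sizes: Sequence[int],
    group_means: np.ndarray,
    group_vars: np.ndarray,
    global_mean: np.ndarray,
    global_var: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals of the mixture-moment identities, per label dimension.

    Returns ``(mu - (1/N) sum n_i mu_i, sigma^2 - (1/N) sum n_i (sigma_i^2
    + (mu_i - mu)^2))``.  Both vanish (to rounding) for moments measured on
    any true partition; non-zero values flag hypothetical targets that no
    partition of the pool can realize.
    """
    sizes_arr = np.asarray(sizes, dtype=float)
    mu_i = np.atleast_2d(np.asarray(group_means, dtype=float))
    var_i = np.atleast_2d(np.asarray(group_vars, dtype=float))
    mu = np.atleast_1d(np.asarray(global_mean, dtype=float))
    var = np.atleast_1d(np.asarray(global_var, dtype=float))
    if sizes_arr.shape[0] != mu_i.shape[0] or mu_i.shape != var_i.shape:
        raise ValueError("sizes and group moment arrays are inconsistent")
    n_total = sizes_arr.sum()
    if n_total <= 0:
        raise ValueError("total size must be positive")
    mean_resid = mu - (sizes_arr @ mu_i) / n_total
    var_resid = var - (sizes_arr @ (var_i + (mu_i - mu) ** 2)) / n_total
    return mean_resid, var_resid


def feasible_sigma(
    global_spec: MomentSpec,
    target_means: Sequence[Sequence[float]],
    size_shares: Sequence[float],
) -> np.ndarray:
    """Common per-group SDs making the variance identity hold exactly.

    Assuming all groups share one SD per dimension (the symmetric case),
    solving the variance identity gives

        sigma_g = sqrt(sigma^2 - sum_i share_i (mu_i - mu)^2).

    Returns an (M, d) array (rows identical).  Raises
    :class:`FeasibilityError` when the radicand is negative, i.e. the mean
    spread alone already exceeds the pooled variance.
    """
    shares = np.asarray(size_shares, dtype=float)
    if not np.isclose(shares.sum(), 1.0):
        raise ConfigurationError("size shares must sum to 1")
    means = np.atleast_2d(np.asarray(target_means, dtype=float))
    if means.shape[0] != shares.size:
        raise ConfigurationError("one mean vector per share required")
    mu = np.asarray(global_spec.mean)
    sigma = np.asarray(global_spec.require_sd())
    radicand = sigma**2 - shares @ (means - mu) ** 2
    bad = radicand < 0
    if np.any(bad):
        dims = [i for i in range(means.shape[1]) if bad[i]]
        raise FeasibilityError(
            f"target means spread wider than the pooled variance allows in "
            f"dimension(s) {dims}; no subgroup SD can satisfy the mixture "
            f"identity"
        )
    sd = np.sqrt(radicand)
    return np.tile(sd, (shares.size, 1))


@dataclass(frozen=True)
class GroupReport:
    size: int
    target_mean: tuple[float, ...] | None
    target_sd: tuple[float, ...] | None
    achieved_mean: tuple[float, ...]
    achieved_sd: tuple[float, ...]
    chi2: float
    bhattacharyya: float

    def to_json(self) -> dict:
        return {
            "size": self.size,
            "target_mean": self.target_mean,
            "target_sd": self.target_sd,
            "achieved_mean": list(self.achieved_mean),
            "achieved_sd": list(self.achieved_sd),
            "chi2": self.chi2,
            "bhattacharyya": self.bhattacharyya,
        }


@dataclass(frozen=True)
class EvaluationReport:
    """Per-group achieved moments and distances plus mixture residuals."""

    per_group: tuple[GroupReport, ...]
    global_size: int
    global_mean: tuple[float, ...]
    global_sd: tuple[float, ...]
    gini: float
    eq_residual_mean: tuple[float, ...]
    eq_residual_var: tuple[float, ...]

    def to_json(self) -> dict:
        return {
            "global": {
                "size": self.global_size,
                "mean": list(self.global_mean),
                "sd": list(self.global_sd),
            },
            "gini": self.gini,
            "mixture_residual_mean": list(self.eq_residual_mean),
            "mixture_residual_var": list(self.eq_residual_var),
            "groups": [g.to_json() for g in self.per_group],
        }


def evaluate(
    cohort: Cohort,
    assignment: Assignment,
    targets: Sequence[MomentSpec] | None,
    grid: HistogramGrid,
) -> EvaluationReport:
    """Assemble the full split-quality report for a partition.

    ``targets`` may be ``None`` (moments and residuals only), or one
    Gaussian spec per group, in which case each group's chi-squared and
    Bhattacharyya distances to its target are computed on ``grid``.  The
    distances use the sampler's own grid by default for comparability with
    the optimization objective; pass a finer grid for evaluation-only use.
    """
    groups = assignment.groups(cohort)
    if targets is not None and len(targets) != assignment.n_groups:
        raise ValueError("one target per group required")

    expected = None
    if targets is not None:
        expected = [expected_probabilities(grid, t) for t in targets]

    global_mean, global_var = _population_moments(cohort.labels)
    sizes = [len(g) for g in groups]
    reports = []
    means = np.zeros((assignment.n_groups, cohort.d))
    variances = np.zeros_like(means)
    for g, idx in enumerate(groups):
        labels = cohort.labels[idx]
        if len(idx):
            means[g], variances[g] = _population_moments(labels)
        observed = ObservedCounts.from_labels(labels, grid) if len(idx) else None
        chi2 = math.nan
        bd = math.nan
        if expected is not None and observed is not None:
            chi2 = chi_squared(observed, expected[g])
            bd = bhattacharyya_binned(observed, expected[g])
        target = targets[g] if targets is not None else None
        reports.append(
            GroupReport(
                size=sizes[g],
                target_mean=list(target.mean) if target else None,
                target_sd=list(target.sd) if target and target.sd else None,
                achieved_mean=tuple(means[g]),
                achieved_sd=tuple(np.sqrt(variances[g])),
                chi2=chi2,
                bhattacharyya=bd,
            )
        )

    mean_resid, var_resid = mixture_consistency(
        sizes, means, variances, global_mean, global_var
    )
    return EvaluationReport(
        per_group=tuple(reports),
        global_size=cohort.n,
        global_mean=tuple(global_mean),
        global_sd=tuple(np.sqrt(global_var)),
        gini=gini(sizes) if len(sizes) >= 2 else 0.0,
        eq_residual_mean=tuple(mean_resid),
        eq_residual_var=tuple(var_resid),
    )
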