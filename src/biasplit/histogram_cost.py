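"""Histogram binning and the greedy sampler's cost function.

The grouping objective compares each group's observed label histogram O to
the expected counts E under its Gaussian target via the chi-squared
distance

    chi2 = sum_cells (O - E)^2 / E,        E_cell = group_size * p_cell,

in one dimension or over a product grid in several, and trades histogram
fidelity against group-size balance through the Gini coefficient of the
group sizes:

    C = sum_i chi2_i / (1 - Gini)^2,
    Gini = sum_ij |s_i - s_j| / (2 (M-1) sum_i s_i).

Equal group sizes give Gini = 0 (cost is just the chi-squared sum); a
fully collapsed split gives Gini = 1 and an infinite-cost sentinel.

Expected cell probabilities come from Gaussian CDF differencing on a grid
built once from the *global* cohort range and shared by every group, so
chi-squared values are comparable across groups.  Cells whose target
probability is below ``PROB_FLOOR`` are excluded from the chi-squared sum;
observed samples landing there incur a fixed large out-of-support penalty
instead of producing an infinite ratio.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort_synth import Cohort, ConfigurationError, MomentSpec

__all__ = [
    "HistogramGrid",
    "ObservedCounts",
    "ExpectedProbabilities",
    "CostBreakdown",
    "build_grid",
    "expected_probabilities",
    "chi_squared",
    "gini",
    "total_cost",
    "PROB_FLOOR",
    "OUT_OF_SUPPORT_PENALTY",
    "DEFAULT_BINS_PER_DIM",
]

PROB_FLOOR = 1e-12
OUT_OF_SUPPORT_PENALTY = 1e6  # per observed sample in a ~zero-probability cell
DEFAULT_BINS_PER_DIM = 20
_PAD_FRACTION = 1e-3  # widen the global range by 0.1% per side


@dataclass(frozen=True)
class HistogramGrid:
    """Per-dimension bin edges over a fixed shared support."""

    edges: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        edges = tuple(np.asarray(e, dtype=float) for e in self.edges)
        for e in edges:
            if e.ndim != 1 or e.size < 2 or not np.all(np.diff(e) > 0):
                raise ValueError("edges must be strictly increasing, >= 2 values")
        object.__setattr__(self, "edges", edges)

    @property
    def d(self) -> int:
        return len(self.edges)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(e) - 1 for e in self.edges)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def cell_indices(self, labels: np.ndarray) -> np.ndarray:
        """Flat (row-major) cell index per sample; outside values clamp to
        the boundary bins (the grid is built to cover the cohort)."""
        labels = np.atleast_2d(np.asarray(labels, dtype=float))
        if labels.shape[1] != self.d:
            raise ValueError("label dimensionality does not match grid")
        per_dim = []
        for j, e in enumerate(self.edges):
            idx = np.searchsorted(e, labels[:, j], side="right") - 1
            per_dim.append(np.clip(idx, 0, len(e) - 2))
        return np.ravel_multi_index(tuple(per_dim), self.shape)

    def centers(self) -> tuple[np.ndarray, ...]:
        return tuple((e[:-1] + e[1:]) / 2.0 for e in self.edges)

    def to_json(self) -> dict:
        return {"edges": [e.tolist() for e in self.edges]}

    @classmethod
    def from_json(cls, payload: dict) -> "HistogramGrid":
        return cls(edges=tuple(np.asarray(e) for e in payload["edges"]))


@dataclass(frozen=True)
class ObservedCounts:
    """Flat row-major cell counts for one group on a shared grid."""

    counts: np.ndarray
    grid: HistogramGrid

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64).ravel()
        if counts.size != self.grid.n_cells:
            raise ValueError("counts do not match grid cells")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_labels(cls, labels: np.ndarray, grid: HistogramGrid) -> "ObservedCounts":
        counts = np.bincount(grid.cell_indices(labels), minlength=grid.n_cells)
        return cls(counts=counts, grid=grid)


@dataclass(frozen=True)
class ExpectedProbabilities:
    """Target cell probabilities on a grid, normalized to sum to 1."""

    probabilities: np.ndarray
    grid: HistogramGrid

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float).ravel()
        if p.size != self.grid.n_cells:
            raise ValueError("probabilities do not match grid cells")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "probabilities", p)

    def to_json(self) -> dict:
        return {
            "grid": self.grid.to_json(),
            "probabilities": self.probabilities.tolist(),
        }

    @classmethod
    def from_json(cls, payload: dict) -> "ExpectedProbabilities":
        return cls(
            probabilities=np.asarray(payload["probabilities"]),
            grid=HistogramGrid.from_json(payload["grid"]),
        )


@dataclass(frozen=True)
class CostBreakdown:
    """Chi-squared per group, Gini of the sizes, and the combined cost."""

    chi2_per_group: tuple[float, ...]
    gini: float
    total_cost: float
    group_sizes: tuple[int, ...]

    def to_json(self) -> dict:
        return {
            "chi2_per_group": list(self.chi2_per_group),
            "gini": self.gini,
            "total_cost": self.total_cost,
            "group_sizes": list(self.group_sizes),
        }


def build_grid(cohort: Cohort, bins_per_dim: int | Sequence[int] = DEFAULT_BINS_PER_DIM) -> HistogramGrid:
    """Equal-width grid spanning the cohort's per-dimension range, widened
    by 0.1% per side so extreme samples fall strictly inside.

    A constant label column degenerates to a single bin with a warning.
    """
    if cohort.n == 0:
        raise ConfigurationError("cannot build a grid from an empty cohort")
    if np.isscalar(bins_per_dim):
        bins = [int(bins_per_dim)] * cohort.d
    else:
        bins = [int(b) for b in bins_per_dim]
    if len(bins) != cohort.d or any(b < 1 for b in bins):
        raise ConfigurationError("bins_per_dim must be positive, one per dimension")
    edges = []
    for j in range(cohort.d):
        lo = float(cohort.labels[:, j].min())
        hi = float(cohort.labels[:, j].max())
        if lo == hi:
            warnings.warn(
                f"dimension {cohort.dims[j]!r} is constant; using a single bin",
                RuntimeWarning,
                stacklevel=2,
            )
            pad = max(abs(lo), 1.0) * _PAD_FRACTION
            edges.append(np.array([lo - pad, hi + pad]))
            continue
        pad = (hi - lo) * _PAD_FRACTION
        edges.append(np.linspace(lo - pad, hi + pad, bins[j] + 1))
    return HistogramGrid(edges=tuple(edges))


def _bivariate_rectangle_probs(grid: HistogramGrid, target: MomentSpec) -> np.ndarray:
    """Rectangle probabilities of a correlated bivariate Gaussian via the
    inclusion-exclusion of the joint CDF at the cell corners."""
    mean = np.asarray(target.mean)
    cov = target.covariance()
    mvn = stats.multivariate_normal(mean=mean, cov=cov)
    ex, ey = grid.edges
    gx, gy = np.meshgrid(ex, ey, indexing="ij")
    corner = mvn.cdf(np.stack([gx.ravel(), gy.ravel()], axis=1)).reshape(gx.shape)
    rect = corner[1:, 1:] - corner[:-1, 1:] - corner[1:, :-1] + corner[:-1, :-1]
    return np.maximum(rect, 0.0).ravel()


def expected_probabilities(grid: HistogramGrid, target: MomentSpec) -> ExpectedProbabilities:
    """Cell probabilities of the Gaussian target on the grid.

    Independent marginals (product of per-dimension CDF differences) unless
    the target carries a correlation matrix, in which case 2-D grids use
    exact bivariate rectangle probabilities.  Renormalized to sum to 1 over
    the grid support.
    """
    if grid.d != target.d:
        raise ConfigurationError("grid and target dimensionality differ")
    sd = target.require_sd()
    if target.correlation is not None and grid.d == 2 and not np.allclose(
        target.correlation, np.eye(2)
    ):
        p = _bivariate_rectangle_probs(grid, target)
    else:
        per_dim = []
        for j, e in enumerate(grid.edges):
            cdf = stats.norm.cdf(e, loc=target.mean[j], scale=sd[j])
            per_dim.append(np.diff(cdf))
        p = per_dim[0]
        for q in per_dim[1:]:
            p = np.multiply.outer(p, q)
        p = p.ravel()
    mass = p.sum()
    if mass <= 0:
        raise ConfigurationError(
            "target distribution has no mass on the grid support; the target "
            "lies far outside the cohort's label range"
        )
    return ExpectedProbabilities(probabilities=p / mass, grid=grid)


def chi_squared(observed: ObservedCounts, expected: ExpectedProbabilities) -> float:
    """Chi-squared distance between a group histogram and its target.

    ``E_cell = group_size * p_cell`` with the group's *current* size, so the
    statistic scales sensibly as groups grow during greedy assignment.
    Cells below the probability floor are excluded; observed samples there
    add ``OUT_OF_SUPPORT_PENALTY`` each.  An empty group has distance 0.
    """
    if observed.grid is not expected.grid and observed.grid.to_json() != expected.grid.to_json():
        raise ValueError("observed and expected use different grids")
    n = observed.total
    if n == 0:
        return 0.0
    p = expected.probabilities
    counted = p >= PROB_FLOOR
    e = n * p[counted]
    o = observed.counts[counted]
    value = float(np.sum((o - e) ** 2 / e))
    n_out = int(observed.counts[~counted].sum())
    return value + OUT_OF_SUPPORT_PENALTY * n_out


def gini(sizes: Sequence[int]) -> float:
    """Gini coefficient of the group sizes: mean absolute size difference
    normalized so equal sizes give 0 and total collapse gives 1."""
    s = np.asarray(sizes, dtype=float)
    if s.size < 2:
        raise ValueError("gini requires at least two groups")
    if np.any(s < 0):
        raise ValueError("sizes must be non-negative")
    total = s.sum()
    if total == 0:
        raise ValueError("at least one group size must be positive")
    diff_sum = float(np.abs(s[:, None] - s[None, :]).sum())
    return float(diff_sum / (2.0 * (s.size - 1) * total))


def total_cost(chi2_per_group: Sequence[float], sizes: Sequence[int]) -> float:
    """Combined cost C = sum(chi2_i) / (1 - Gini)^2; ``inf`` when one group
    holds all samples (Gini = 1), never a numeric division by zero."""
    chi2s = np.asarray(chi2_per_group, dtype=float)
    if chi2s.size != len(sizes) or chi2s.size < 2:
        raise ValueError("chi2 and size vectors must have equal length M >= 2")
    if np.any(chi2s < 0):
        raise ValueError("chi-squared values must be non-negative")
    g = gini(sizes)
    if g >= 1.0:
        return math.inf
    return float(chi2s.sum() / (1.0 - g) ** 2)


def cost_breakdown(
    counts_per_group: Sequence[ObservedCounts],
    expected_per_group: Sequence[ExpectedProbabilities],
) -> CostBreakdown:
    """Full cost evaluation from per-group histograms (non-incremental)."""
    chi2s = tuple(
        chi_squared(o, e) for o, e in zip(counts_per_group, expected_per_group)
    )
    sizes = tuple(o.total for o in counts_per_group)
    return CostBreakdown(
        chi2_per_group=chi2s,
        gini=gini(sizes),
        total_cost=total_cost(chi2s, sizes),
        group_sizes=sizes,
    )


def grid_tables_to_json(expected: Sequence[ExpectedProbabilities]) -> str:
    """Serialize the shared grid and per-group probability tables (audit)."""
    payload = {
        "grid": expected[0].grid.to_json(),
        "groups": [e.probabilities.tolist() for e in expected],
    }
    return json.dumps(payload)
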