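"""Synthetic cohort generation and split protocol helpers.

A *cohort* is an ordered collection of samples, each carrying a unique id
and a d-dimensional continuous label vector (e.g. weight in kg, height in
cm).  The generator draws labels from a (optionally truncated, optionally
correlated) multivariate Gaussian described by a :class:`MomentSpec`, so
that pooled cohorts with realistic anthropometric statistics can be built
without access to clinical data.  Packaged presets carry published
country-level mean weight/height values for quick what-if scenarios.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "Cohort",
    "MomentSpec",
    "ConfigurationError",
    "generate_cohort",
    "generate_mixture_cohort",
    "preset_targets",
    "available_presets",
    "holdout_split",
    "train_val_split",
    "paper_like_spec",
    "GLOBAL_WEIGHT_MEAN_KG",
    "GLOBAL_WEIGHT_SD_KG",
    "GLOBAL_HEIGHT_MEAN_CM",
    "GLOBAL_HEIGHT_SD_CM",
    "GLOBAL_COHORT_SIZE",
]

# Global label statistics of the pooled clinical cohort the synthetic
# generator emulates (weight/height of 2078 European patients).
GLOBAL_COHORT_SIZE = 2078
GLOBAL_WEIGHT_MEAN_KG = 79.9
GLOBAL_WEIGHT_SD_KG = 18.7
GLOBAL_HEIGHT_MEAN_CM = 171.6
GLOBAL_HEIGHT_SD_CM = 9.7

# Inclusion ranges of the source studies; used as default truncation for
# the packaged "paper-like" cohort spec.
WEIGHT_RANGE_KG = (45.0, 120.0)
HEIGHT_RANGE_CM = (140.0, 200.0)


class ConfigurationError(ValueError):
    """Raised for invalid generator / split configuration."""


@dataclass(frozen=True)
class Cohort:
    """Ordered sample collection with unique ids and numeric label vectors.

    Parameters
    ----------
    ids
        One opaque unique token per sample.
    labels
        Array of shape ``(n, d)``; all values finite.
    dims
        Per-dimension names with unit tags, e.g. ``("weight_kg", "height_cm")``.
    """

    ids: tuple[str, ...]
    labels: np.ndarray
    dims: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=float)
        if labels.ndim == 1:
            labels = labels[:, None]
        object.__setattr__(self, "labels", labels)
        if len(self.ids) != labels.shape[0]:
            raise ValueError("ids and labels length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sample ids must be unique")
        if labels.shape[1] != len(self.dims):
            raise ValueError("label dimensionality does not match dims")
        if labels.size and not np.all(np.isfinite(labels)):
            raise ValueError("label values must be finite")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def d(self) -> int:
        return len(self.dims)

    def subset(self, index: Sequence[int]) -> "Cohort":
        idx = np.asarray(index, dtype=int)
        return Cohort(
            ids=tuple(self.ids[i] for i in idx),
            labels=self.labels[idx],
            dims=self.dims,
        )

    def index_of(self) -> dict[str, int]:
        return {sid: i for i, sid in enumerate(self.ids)}


@dataclass(frozen=True)
class MomentSpec:
    """Parametric (Gaussian) label distribution: per-dimension mean/SD,
    optional correlation matrix and per-dimension truncation bounds.

    ``sd`` may be ``None`` for presets that only publish means; operations
    that need a spread reject such specs.
    """

    mean: tuple[float, ...]
    sd: tuple[float, ...] | None = None
    correlation: np.ndarray | None = None
    truncation: tuple[tuple[float, float] | None, ...] | None = None
    share: float | None = None  # desired size share, optional

    def __post_init__(self) -> None:
        mean = tuple(float(m) for m in np.atleast_1d(self.mean))
        object.__setattr__(self, "mean", mean)
        if self.sd is not None:
            sd = tuple(float(s) for s in np.atleast_1d(self.sd))
            if len(sd) != len(mean):
                raise ConfigurationError("sd and mean dimensionality differ")
            if any(s <= 0 for s in sd):
                raise ConfigurationError("sd must be positive per dimension")
            object.__setattr__(self, "sd", sd)
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            if corr.shape != (len(mean), len(mean)):
                raise ConfigurationError("correlation matrix shape mismatch")
            if not np.allclose(corr, corr.T):
                raise ConfigurationError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(corr), 1.0):
                raise ConfigurationError("correlation diagonal must be 1")
            eigvals = np.linalg.eigvalsh(corr)
            if np.min(eigvals) <= 0:
                raise ConfigurationError("correlation matrix must be positive definite")
            object.__setattr__(self, "correlation", corr)
        if self.truncation is not None:
            trunc = tuple(
                None if b is None else (float(b[0]), float(b[1]))
                for b in self.truncation
            )
            if len(trunc) != len(mean):
                raise ConfigurationError("truncation bounds dimensionality mismatch")
            for b in trunc:
                if b is not None and not b[0] < b[1]:
                    raise ConfigurationError("empty truncation interval")
            object.__setattr__(self, "truncation", trunc)

    @property
    def d(self) -> int:
        return len(self.mean)

    def require_sd(self) -> tuple[float, ...]:
        if self.sd is None:
            raise ConfigurationError(
                "MomentSpec has no standard deviations; supply them explicitly "
                "or derive them with the mixture-feasibility solver"
            )
        return self.sd

    def covariance(self) -> np.ndarray:
        sd = np.asarray(self.require_sd())
        if self.correlation is None:
            return np.diag(sd**2)
        return self.correlation * np.outer(sd, sd)

    def with_sd(self, sd: Sequence[float]) -> "MomentSpec":
        return replace(self, sd=tuple(float(s) for s in sd))


def paper_like_spec(correlation: float = 0.5, truncated: bool = True) -> MomentSpec:
    """Bivariate weight/height spec with the pooled cohort's global moments.

    Weight-height correlation defaults to 0.5 (a plausible adult value; the
    empirical correlation of the original cohort is unpublished, so this is
    an explicit knob, not a reproduction).  Truncation defaults to the
    source studies' inclusion ranges, 45-120 kg and 140-200 cm.
    """
    corr = np.array([[1.0, correlation], [correlation, 1.0]])
    return MomentSpec(
        mean=(GLOBAL_WEIGHT_MEAN_KG, GLOBAL_HEIGHT_MEAN_CM),
        sd=(GLOBAL_WEIGHT_SD_KG, GLOBAL_HEIGHT_SD_CM),
        correlation=corr,
        truncation=(WEIGHT_RANGE_KG, HEIGHT_RANGE_CM) if truncated else None,
    )


_DEFAULT_DIMS_BY_D = {1: ("label",), 2: ("weight_kg", "height_cm")}

_REJECTION_PASSES = 100


def _draw(n: int, spec: MomentSpec, rng: np.random.Generator) -> np.ndarray:
    mean = np.asarray(spec.mean)
    cov = spec.covariance()
    return rng.multivariate_normal(mean, cov, size=n, method="cholesky")


def generate_cohort(
    n: int,
    spec: MomentSpec,
    seed: int,
    dims: Sequence[str] | None = None,
    id_prefix: str = "s",
) -> Cohort:
    """Draw ``n`` samples from the Gaussian defined by ``spec``.

    Truncation is enforced by rejection sampling (up to 100 refill passes),
    never by clipping, so bounds do not create artificial boundary atoms in
    downstream histograms.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    spec.require_sd()
    rng = np.random.default_rng(seed)
    draws = _draw(n, spec, rng)
    if spec.truncation is not None:
        lows = np.array(
            [-np.inf if b is None else b[0] for b in spec.truncation]
        )
        highs = np.array(
            [np.inf if b is None else b[1] for b in spec.truncation]
        )
        ok = np.all((draws >= lows) & (draws <= highs), axis=1)
        kept = draws[ok]
        passes = 0
        while kept.shape[0] < n:
            passes += 1
            if passes > _REJECTION_PASSES:
                raise ConfigurationError(
                    "rejection sampling exceeded the resample cap; the "
                    "truncation interval captures too little probability mass"
                )
            refill = _draw(n, spec, rng)
            ok = np.all((refill >= lows) & (refill <= highs), axis=1)
            kept = np.vstack([kept, refill[ok]])
        draws = kept[:n]
    if dims is None:
        dims = _DEFAULT_DIMS_BY_D.get(spec.d) or tuple(
            f"label{i}" for i in range(spec.d)
        )
    ids = tuple(f"{id_prefix}{i:06d}" for i in range(n))
    return Cohort(ids=ids, labels=draws, dims=tuple(dims))


def generate_mixture_cohort(
    n: int,
    specs: Sequence[MomentSpec],
    seed: int,
    shares: Sequence[float] | None = None,
    dims: Sequence[str] | None = None,
    shuffle: bool = True,
) -> Cohort:
    """Pool drawn as an exact finite mixture of Gaussian components.

    Component sample counts are ``round(share * n)`` (largest-remainder fix
    so they sum to ``n``); with the default equal shares and even ``n`` the
    mixture is exactly balanced.  Used to build pools from which prescribed
    subgroup targets are exactly recoverable.
    """
    if not specs:
        raise ConfigurationError("at least one mixture component required")
    m = len(specs)
    if shares is None:
        shares = [1.0 / m] * m
    shares_arr = np.asarray(shares, dtype=float)
    if shares_arr.shape != (m,) or not np.isclose(shares_arr.sum(), 1.0):
        raise ConfigurationError("shares must match specs and sum to 1")
    raw = shares_arr * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    rng = np.random.default_rng(seed)
    parts = []
    for i, (spec, cnt) in enumerate(zip(specs, counts)):
        if cnt == 0:
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        part = generate_cohort(
            cnt, spec, seed=sub_seed, dims=dims, id_prefix=f"c{i}_"
        )
        parts.append(part)
    ids = tuple(sid for p in parts for sid in p.ids)
    labels = np.vstack([p.labels for p in parts])
    if shuffle:
        perm = rng.permutation(len(ids))
        ids = tuple(ids[i] for i in perm)
        labels = labels[perm]
    return Cohort(ids=ids, labels=labels, dims=parts[0].dims)


def _load_preset_table() -> dict:
    text = resources.files("biasplit.data").joinpath("country_presets.json").read_text()
    return json.loads(text)


def available_presets() -> list[tuple[str, str]]:
    """(country, sex) keys of the packaged demographic presets."""
    table = _load_preset_table()
    return [(c, s) for c in table["countries"] for s in ("men", "women")]


def preset_targets(region: str, sex: str = "men") -> MomentSpec:
    """Published mean weight (kg) and height (converted to cm) for a
    country/sex group.

    The published table carries means only, so the returned spec has
    ``sd=None``; callers supply SDs directly or derive feasible ones with
    :func:`biasplit.evaluation.feasible_sigma`.
    """
    table = _load_preset_table()
    entry = table["countries"].get(region)
    if entry is None:
        raise KeyError(
            f"unknown region {region!r}; available: {sorted(table['countries'])}"
        )
    if sex not in ("men", "women"):
        raise KeyError("sex must be 'men' or 'women'")
    weight_kg = entry[f"weight_kg_{sex}"]
    height_cm = entry[f"height_m_{sex}"] * 100.0  # table prints metres
    return MomentSpec(mean=(weight_kg, height_cm))


def holdout_split(cohort: Cohort, fraction: float, seed: int) -> tuple[Cohort, Cohort]:
    """Uniform random (train, test) partition with test size ``round(f*N)``.

    The held-out part preserves the pooled statistics in expectation and
    stays untouched by any subsequent grouping.
    """
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError("holdout fraction must lie in (0, 1)")
    if cohort.n == 0:
        raise ConfigurationError("cohort is empty")
    n_test = int(np.rint(fraction * cohort.n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(cohort.n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return cohort.subset(train_idx), cohort.subset(test_idx)


def train_val_split(
    cohort: Cohort, seed: int, val_fraction: float = 0.2
) -> tuple[Cohort, Cohort]:
    """Client-local train/validation split (default 80/20)."""
    return holdout_split(cohort, val_fraction, seed)
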