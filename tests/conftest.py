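import numpy as np
import pytest

import biasplit as b

GLOBAL_WEIGHT = b.MomentSpec(mean=(79.9,), sd=(18.7,))
GLOBAL_HEIGHT = b.MomentSpec(mean=(171.6,), sd=(9.7,))
GLOBAL_JOINT = b.MomentSpec(mean=(79.9, 171.6), sd=(18.7, 9.7))


def shifted_targets(global_spec, deltas, shares=(0.5, 0.5)):
    """Two symmetric target specs at mean +/- delta with feasibility-derived
    common SDs (the variance identity solved for the subgroup spread)."""
    mu = np.asarray(global_spec.mean)
    d = np.asarray(deltas, dtype=float)
    means = [tuple(mu - d), tuple(mu + d)]
    sds = b.feasible_sigma(global_spec, means, list(shares))
    return [b.MomentSpec(mean=m, sd=tuple(s)) for m, s in zip(means, sds)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def weight_mixture_pool():
    """1-D pool that is an exact equal mixture of the two weight targets."""
    targets = shifted_targets(GLOBAL_WEIGHT, [10.0])
    pool = b.generate_mixture_cohort(2000, targets, seed=42, dims=("weight_kg",))
    return pool, targets


@pytest.fixture(scope="session")
def joint_pool():
    """Bivariate truncated correlated weight/height cohort (pooled stats)."""
    return b.generate_cohort(2078, b.paper_like_spec(), seed=7)


def tiny_cohort(values, dims=("weight_kg",)):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != len(dims):
        values = values.T
    ids = tuple(f"p{i}" for i in range(values.shape[0]))
    return b.Cohort(ids=ids, labels=values, dims=dims)
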