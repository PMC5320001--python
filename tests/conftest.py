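import io

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from skbio import TreeNode

import horseshoe as h

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def read_newick_string(newick: str) -> TreeNode:
    tree = TreeNode.read(io.StringIO(newick))
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    return tree


@pytest.fixture(scope="session")
def band30():
    """The default 30-sample, band-size-10 band table and its gradient."""
    return h.band_table(h.BandSpec(n_samples=30, band_size=10, shift=1))


@pytest.fixture(scope="session")
def niche_default():
    """Deep Gaussian-niche table with known optima (fixed seed)."""
    spec = h.NicheSpec(n_samples=50, n_features=100, sigma=1.0, depth=1e4, seed=0)
    table, meta, optima = h.niche_table(spec)
    return spec, table, meta, optima


def random_proportions(rng, n_features, n_samples):
    vals = rng.random((n_features, n_samples)) + 1e-3
    vals /= vals.sum(axis=0)
    return h.FeatureTable(
        vals,
        [f"f{i}" for i in range(n_features)],
        [f"s{j}" for j in range(n_samples)],
        proportions=True,
    )


def random_counts(rng, n_features, n_samples, density=0.5, scale=20):
    vals = rng.poisson(scale, size=(n_features, n_samples)).astype(float)
    vals *= rng.random((n_features, n_samples)) < density
    # avoid degenerate all-zero samples
    for j in range(n_samples):
        if vals[:, j].sum() == 0:
            vals[rng.integers(n_features), j] = 1.0
    return h.FeatureTable(
        vals, [f"f{i}" for i in range(n_features)], [f"s{j}" for j in range(n_samples)]
    )
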