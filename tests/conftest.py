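"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from foldrate.models import GBTConfig
from foldrate.synthetic import SyntheticSpec, generate_dataset, generate_toy_structure

#: small tree config so the suite stays fast
FAST = GBTConfig(n_estimators=40, per_class=30, seed=0)


@pytest.fixture(scope="session")
def small_synth():
    """120 variants over 4 proteins with the default planted signal."""
    return generate_dataset(
        SyntheticSpec(n_proteins=4, n_variants=120, seed=11)
    )


@pytest.fixture(scope="session")
def helix_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("pdb") / "helix.pdb"
    generate_toy_structure(20, path)
    return path


@pytest.fixture(scope="session")
def blobs3():
    """Separable three-class problem with 8 features."""
    rng = np.random.default_rng(42)
    n = 400
    X = rng.normal(0, 1, (n, 8))
    y = np.array(["decrease", "no_effect", "increase"])[rng.integers(0, 3, n)]
    for i, cls in enumerate(("decrease", "no_effect", "increase")):
        X[y == cls, 0] += 3.0 * i
        X[y == cls, 1] -= 1.5 * i
    return X, y


def random_confusion(rng, k=3, n=60):
    """A random K x K confusion matrix with all marginals positive."""
    while True:
        z = rng.multinomial(n, rng.dirichlet(np.ones(k * k))).reshape(k, k)
        if (z.sum(axis=0) > 0).all() and (z.sum(axis=1) > 0).all():
            return z.astype(float)
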