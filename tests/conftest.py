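"""Shared fixtures: small phantom cases and feature tables.

Everything is generated programmatically at fixed seeds; session scope
amortizes the expensive extractions across test modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rectomics.features import FeatureTable
from rectomics.phantom import PhantomParams, generate_phantom_case


@pytest.fixture(scope="session")
def params() -> PhantomParams:
    return PhantomParams()


@pytest.fixture(scope="session")
def case_high(params):
    """A ypT3-4 phantom case (thick, heterogeneous wall)."""
    return generate_phantom_case(params, "ypT3-4", 42)


@pytest.fixture(scope="session")
def case_low(params):
    return generate_phantom_case(params, "ypT0-2", 43)


def make_gaussian_table(n_per_class=20, n_features=10, effect=None,
                        seed=0) -> FeatureTable:
    """Synthetic two-class Gaussian feature table; ``effect`` maps feature
    index -> mean shift (in SD units) for the ypT0-2 class."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(size=(n, n_features))
    labels = np.array(["ypT0-2"] * n_per_class + ["ypT3-4"] * n_per_class)
    for j, d in (effect or {}).items():
        X[:n_per_class, j] += d
    cols = [f"f{j:02d}" for j in range(n_features)]
    ids = [f"c{i:03d}" for i in range(n)]
    data = pd.DataFrame(X, index=ids, columns=cols)
    meta = pd.DataFrame({
        "ypT_group": labels,
        "institution": ["inst1"] * n,
        "field_T": [3.0] * n,
        "sex": ["M"] * n,
        "cohort": ["discovery"] * n,
    }, index=ids)
    return FeatureTable(data, meta)


@pytest.fixture()
def gaussian_table():
    return make_gaussian_table(effect={0: 2.0, 1: 2.0}, seed=1)
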