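"""Shared fixtures: one default synthetic family and its fitted energy
model are reused across the suite (session scope) to keep runtime down."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import domstab as ds
from domstab.energy import FamilyEnergyRegressor, encode_family

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def family():
    """Default synthetic family: 12 homologues x 40 columns, seed 1."""
    return ds.simulate_family(12, 40, seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def encoding(family):
    return encode_family(family.alignment, family.variants)


@pytest.fixture(scope="session")
def fitted_model(encoding):
    return FamilyEnergyRegressor(random_state=1).fit(encoding)


@pytest.fixture(scope="session")
def scores(family):
    return ds.simulate_evolutionary_scores(
        family.truth, family.variants, family.config, seed=DEFAULT_SEED + 100
    )


@pytest.fixture(scope="session")
def normalized(family):
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for dom in family.domains.values():
            out.extend(ds.normalize_fitness(dom, family.variants))
    return out


@pytest.fixture(scope="session")
def annotations(family):
    return ds.simulate_clinical_labels(
        family.truth, family.variants, family.config, seed=DEFAULT_SEED + 3
    )


@pytest.fixture(scope="session")
def small_family():
    """Small family for cheap structural tests: 4 homologues x 12 columns."""
    return ds.simulate_family(4, 12, seed=3)


def observed_feature_mask(encoding) -> np.ndarray:
    mask = np.zeros(encoding.n_columns * 20, dtype=bool)
    mask[np.unique(encoding.mut_feat[encoding.mut_feat >= 0])] = True
    return mask
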