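"""Shared fixtures: small hand-built grids and scaled-down synthetic studies."""

import numpy as np
import pytest

from morphme import (
    DigitizationDataset,
    LandmarkConfiguration,
    SpecimenMeta,
    default_params,
    generate_dataset,
)


def build_dataset(coords, sexes, day_offsets=None):
    """Construct a dataset from {(individual, rep): (L, 2) array}.

    *sexes* maps individual -> "F"/"M"; *day_offsets* maps rep -> int
    (defaults to enumeration order).
    """
    reps = sorted({rep for _, rep in coords})
    if day_offsets is None:
        day_offsets = {rep: i + 1 for i, rep in enumerate(reps)}
    records = []
    for (ind, rep), xy in coords.items():
        meta = SpecimenMeta(
            individual_id=ind, sex=sexes[ind], rep_label=rep,
            day_offset=day_offsets[rep],
        )
        records.append((meta, LandmarkConfiguration(coords=np.asarray(xy, float))))
    return DigitizationDataset(records)


@pytest.fixture(scope="session")
def small_params():
    """A scaled-down study: 8 individuals, 8 landmarks, 8 REPs."""
    return default_params(n_individuals=8, sex_counts=(4, 4), n_landmarks=8, seed=0)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    dataset, truth = generate_dataset(small_params, seed=42)
    return dataset, truth


@pytest.fixture(scope="session")
def study_dataset():
    """One full-size (58 x 8 x 26) synthetic study with default parameters."""
    params = default_params(seed=7)
    dataset, truth = generate_dataset(params, seed=7)
    return dataset, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240401)
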