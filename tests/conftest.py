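import warnings

import numpy as np
import pytest

from killzones import (
    PointPattern,
    StudyRegion,
    generate_habitat_fields,
    generate_island,
)


@pytest.fixture(scope="session")
def square_region() -> StudyRegion:
    """1 km x 1 km square window (no lakes)."""
    ring = np.array([[0.0, 0.0], [1000.0, 0.0], [1000.0, 1000.0], [0.0, 1000.0]])
    return StudyRegion(boundary=ring)


@pytest.fixture(scope="session")
def island() -> StudyRegion:
    """Small synthetic island (~60 km²) shared across tests."""
    return generate_island(3, 60e6)


@pytest.fixture(scope="session")
def full_island() -> StudyRegion:
    """Study-scale island (544 km²)."""
    return generate_island(3, 544e6)


@pytest.fixture(scope="session")
def island_fields(island):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_habitat_fields(island, cell_size=100.0, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_pattern(points, region, label="generic") -> PointPattern:
    return PointPattern.unlabelled(np.asarray(points, float), region, label)
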