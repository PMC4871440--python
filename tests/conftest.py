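"""Shared fixtures: one planted-signal cohort (the package's default study
design at the default seed) reused across module tests, plus small helpers."""

import numpy as np
import pytest

from ortcva import CohortConfig, cohort, derive_composite, generate_cohort, prep


@pytest.fixture(scope="session")
def planted_config():
    return CohortConfig(seed=0)


@pytest.fixture(scope="session")
def true_pattern(planted_config):
    cfg = planted_config
    return cohort.make_true_pattern(
        cfg.grid_shape, cfg.voxel_size_mm,
        cohort.default_clusters(cfg.grid_shape, cfg.voxel_size_mm))


@pytest.fixture(scope="session")
def planted_cohort(planted_config, true_pattern):
    return generate_cohort(planted_config, true_pattern)


@pytest.fixture(scope="session")
def planted_prepped(planted_cohort):
    scans, _ = planted_cohort
    return prep.preprocess(scans)


@pytest.fixture(scope="session")
def planted_dm(planted_prepped):
    return prep.subtraction_matrix(planted_prepped, group="pHD")


@pytest.fixture(scope="session")
def planted_composite(planted_dm, planted_cohort):
    _, table = planted_cohort
    return derive_composite(planted_dm, table)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
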