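"""Shared fixtures: small phantom cohorts and prepared data matrices.

Session-scoped where generation is costly; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from ssmpca.preprocess import build_brain_mask, build_data_matrix
from ssmpca.synthetic_cohort import (
    INTRINSICALLY_NORMALISED,
    PhantomConfig,
    generate_cohort,
)


def make_config(**overrides) -> PhantomConfig:
    """A small, fast phantom configuration; override per test."""
    base = dict(
        grid_shape=(16, 16, 16),
        n_reference=8,
        n_target=8,
        effect_amplitude=2.0,  # 10 x noise_sd: overwhelming effect
        loading_sd=0.3,
        noise_sd=0.2,
        n_blobs=4,
        modalities={"qmap": INTRINSICALLY_NORMALISED},
        lesion_count_range=(0, 2),
        seed=11,
    )
    base.update(overrides)
    return PhantomConfig(**base)


def cohort_data(config: PhantomConfig, modality: str = "qmap"):
    """Generate a cohort and return (cohort, mask, DataMatrix) for one modality."""
    cohort = generate_cohort(config)
    mask = build_brain_mask(
        [s.gm for s in cohort.subjects], [s.wm for s in cohort.subjects]
    )
    return cohort, mask, build_data_matrix(cohort, modality, mask)


@pytest.fixture(scope="session")
def strong_effect_data():
    """16³ cohort, 8/8 subjects, effect 10× noise — separable by construction."""
    return cohort_data(make_config())


@pytest.fixture(scope="session")
def null_data():
    """Same geometry with zero group effect."""
    return cohort_data(make_config(effect_amplitude=0.0, seed=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
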