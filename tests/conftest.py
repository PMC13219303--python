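"""Shared fixtures: designs, small simulated studies, and replicate banks.

Everything is generated programmatically; the heavier replicate banks are
session-scoped so that several tests can share one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from carescreen.design import ResponseMatrix, SurveyDesign, recode_reverse
from carescreen.simulate import (
    SimConfig,
    assemble_study,
    default_sdas_config,
    default_sdas_design,
)


@pytest.fixture(scope="session")
def sdas_design() -> SurveyDesign:
    return default_sdas_design(include_criteria=True)


@pytest.fixture(scope="session")
def sdas_design_focal() -> SurveyDesign:
    return default_sdas_design(include_criteria=False)


@pytest.fixture
def minimal_design() -> SurveyDesign:
    return SurveyDesign(
        item_ids=("a", "b"),
        factor_map={"a": "f", "b": "f"},
        reverse_set=frozenset(),
        instructed_item=None,
        required_category=None,
        scale_min=1,
        scale_max=5,
    )


@pytest.fixture(scope="session")
def one_factor_config() -> SimConfig:
    """Six congeneric items, one factor, loading 0.7, no attention check."""
    items = tuple(f"q{j}" for j in range(1, 7))
    design = SurveyDesign(
        item_ids=items,
        factor_map={i: "g" for i in items},
        scale_min=1,
        scale_max=5,
    )
    return SimConfig(
        design=design,
        n_respondents=5000,
        prevalence=0.0,
        loadings={i: 0.7 for i in items},
        factor_corr=np.array([[1.0]]),
        item_intercept=0.0,  # the symmetric-threshold oracle condition
        seed=424242,
    )


@pytest.fixture(scope="session")
def small_study():
    """A default-condition study at reduced n for fast structural tests."""
    cfg = default_sdas_config(seed=99, n_respondents=400, prevalence=0.1133)
    return assemble_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """One full-size study under the default conditions."""
    cfg = default_sdas_config(seed=2025)
    return assemble_study(cfg)


@pytest.fixture(scope="session")
def recoded_default(default_study):
    return recode_reverse(default_study.matrix, default_study.design)
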