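"""Shared fixtures: synthetic libraries and cohorts at study-like sizes.

Session scope keeps the suite fast — fixtures are read-only for tests.
"""

import numpy as np
import pandas as pd
import pytest

import glycardio as gc
from glycardio import synthetic_data as sd


@pytest.fixture(scope="session")
def tissue_library() -> pd.DataFrame:
    """155-structure whole-tissue-profile library (study-scale)."""
    return sd.generate_library(155, sd.TISSUE_CLASS_MIX, seed=11)


@pytest.fixture(scope="session")
def cm_library() -> pd.DataFrame:
    """Cardiomyocyte-profile library (high-mannose dominated)."""
    return sd.generate_library(120, sd.CARDIOMYOCYTE_CLASS_MIX, seed=7)


@pytest.fixture(scope="session")
def small_structures(tissue_library) -> list:
    return sd.library_table(tissue_library)[:50]


@pytest.fixture(scope="session")
def default_cohort(tissue_library):
    """One default cohort (paucimannose down, 16/18 samples)."""
    spec = sd.EffectSpec(seed=21)
    areas, meta, truth = sd.generate_cohort(tissue_library, spec)
    return areas, meta, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_metadata() -> pd.DataFrame:
    n = 12
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "group": ["negative"] * 6 + ["positive"] * 6,
        "age": [60, 62, 58, 70, 65, 61, 66, 59, 72, 64, 63, 68],
        "sex": ["M", "F"] * 6,
        "hypertension": [0, 1, 0, 1, 1, 0, 1, 1, 0, 1, 0, 1],
    }).set_index("sample_id", drop=False)
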