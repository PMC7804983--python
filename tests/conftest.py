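"""Shared fixtures: phantoms and atlas databases, built once per session."""

import numpy as np
import pytest

import flairvol as fv


@pytest.fixture(scope="session")
def case_3t():
    """Default 3T phantom with lesions."""
    return fv.generate_phantom(fv.PhantomSpec(seed=1, field_strength="3T"))


@pytest.fixture(scope="session")
def case_15t():
    """Default 1.5T phantom with lesions."""
    return fv.generate_phantom(fv.PhantomSpec(seed=1, field_strength="1.5T"))


@pytest.fixture(scope="session")
def lesion_free_case():
    return fv.generate_phantom(fv.PhantomSpec(seed=8, lesion_count=0))


@pytest.fixture(scope="session")
def high_load_case():
    """High lesion load (~4 ml, ~15% of WM) — the desk-scale 'top decile'."""
    return fv.generate_phantom(
        fv.PhantomSpec(seed=3, lesion_count=8, lesion_diameter_range_mm=(8, 12))
    )


@pytest.fixture(scope="session")
def atlas_db5():
    """Small 5-subject synthetic atlas database."""
    return fv.generate_atlas_database(
        5, fv.PhantomSpec(seed=42, lesion_count=0), deform_scale=2.0
    )


@pytest.fixture(scope="session")
def atlas_db10():
    """The default-sized 10-subject database used by the pipeline."""
    return fv.generate_atlas_database(
        10, fv.PhantomSpec(seed=42, lesion_count=0), deform_scale=2.0
    )


@pytest.fixture(scope="session")
def fitted_model_3t(case_3t):
    return fv.fit_mixture(case_3t.flair, case_3t.truth_tissue)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
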